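"""Synthetic multi-tissue cohort generator.

Emits blood + adjacent-kidney + one/two-tumor trios with planted
predisposition modes, per-tissue mosaic fractions, tumor purity mixing,
probe-level beta noise, planted shared/private noncoding somatic variants,
and triage-compatible germline annotations, alongside a ground-truth record
that the pipeline never reads.  Every draw comes from a single seeded
generator, so output is byte-identical across runs with the same seed.

Distribution defaults are anchors, not claims about any real cohort; all
are exposed on :class:`CohortConfig`.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigError
from .imprinting import H19_ICR1, KCNQ1OT1_ICR2, expected_observed_beta
from .io import (
    CNV_COLUMNS,
    GERMLINE_COLUMNS,
    SOMATIC_CODING_COLUMNS,
    SOMATIC_NONCODING_COLUMNS,
    ProbeBetaMatrix,
    validate_sample_sheet,
    write_cnv_segments,
    write_json_report,
    write_sample_sheet,
)

MODE_GERMLINE = "germline"
MODE_MOSAIC_LOI = "mosaic_loi"
MODE_OTHER = "other"

_CTNNB1_EXON3_CHANGES = ("p.S45F", "p.S45P", "p.S45del", "p.T41A")
_BASES = ("A", "C", "G", "T")


@dataclass
class CohortConfig:
    n_patients: int = 20
    #: mode mixture approximating the printed cohort fractions
    mode_mixture: dict = field(default_factory=lambda: {
        MODE_GERMLINE: 0.41, MODE_MOSAIC_LOI: 0.45, MODE_OTHER: 0.14,
    })
    p_paired: float = 0.8
    kidney_fraction_beta: tuple = (6.0, 4.0)   # mean ~0.6
    blood_fraction_beta: tuple = (1.0, 19.0)   # mean ~0.05
    purity_range: tuple = (0.5, 1.0)
    probe_noise_sd: float = 0.02
    n_probes_h19: int = 10
    n_probes_icr2: int = 5
    n_background_probes: int = 500
    shared_noncoding_lam: float = 2.0          # truncated >= 1 per LOI pair
    private_noncoding_lam: float = 80.0
    ctnnb1_prob: float = 0.714
    normal_h19: float = 0.5
    normal_icr2: float = 0.5

    def __post_init__(self) -> None:
        total = sum(self.mode_mixture.values())
        if abs(total - 1.0) > 1e-9:
            raise ConfigError(f"mode mixture sums to {total}, expected 1")
        if any(v < 0 for v in self.mode_mixture.values()):
            raise ConfigError("mode mixture weights must be >= 0")
        for name in ("p_paired", "probe_noise_sd", "shared_noncoding_lam",
                     "private_noncoding_lam", "ctnnb1_prob"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        lo, hi = self.purity_range
        if not (0 <= lo <= hi <= 1):
            raise ConfigError(f"invalid purity range {self.purity_range}")


@dataclass
class SyntheticCohort:
    beta: ProbeBetaMatrix
    samples: pd.DataFrame
    germline: pd.DataFrame
    somatic_coding: pd.DataFrame
    somatic_noncoding: pd.DataFrame
    cnv: pd.DataFrame
    ground_truth: dict

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.beta.write(outdir / "beta_matrix.tsv")
        write_sample_sheet(self.samples, outdir / "samples.tsv")
        self.germline.to_csv(outdir / "germline_variants.tsv", sep="\t", index=False)
        self.somatic_coding.to_csv(outdir / "somatic_coding.tsv", sep="\t", index=False)
        self.somatic_noncoding.to_csv(outdir / "somatic_noncoding.tsv", sep="\t", index=False)
        write_cnv_segments(self.cnv, outdir / "cnv_segments.tsv")
        write_json_report(self.ground_truth, outdir / "ground_truth.json")


def _probe_map(config: CohortConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Probe ids/coordinates: ICR windows plus genome-wide background probes."""
    rows = []
    h19_pos = np.linspace(H19_ICR1.start, H19_ICR1.end, config.n_probes_h19).astype(np.int64)
    for k, pos in enumerate(h19_pos):
        rows.append(("cg_h19_%02d" % k, "chr11", int(pos), "h19"))
    icr2_pos = np.linspace(KCNQ1OT1_ICR2.start, KCNQ1OT1_ICR2.end,
                           config.n_probes_icr2).astype(np.int64)
    for k, pos in enumerate(icr2_pos):
        rows.append(("cg_icr2_%02d" % k, "chr11", int(pos), "icr2"))
    n_bg = config.n_background_probes
    chrom_pool = [f"chr{c}" for c in range(1, 23)] + ["chrX", "chrY"]
    weights = np.asarray([1.0] * 22 + [0.5, 0.25])
    chroms = rng.choice(chrom_pool, size=n_bg, p=weights / weights.sum())
    # one global position draw keeps (chrom, pos) unique without bookkeeping
    positions = rng.choice(
        np.arange(1_000_000, 200_000_000, 1_000, dtype=np.int64), size=n_bg, replace=False
    )
    for k in range(n_bg):
        rows.append(("cg_bg_%04d" % k, str(chroms[k]), int(positions[k]), "background"))
    return pd.DataFrame(rows, columns=["probe_id", "chrom", "pos", "role"]).set_index("probe_id")


def generate_cohort(config: CohortConfig | None = None, seed: int = 0) -> SyntheticCohort:
    """Generate a full synthetic cohort; deterministic given (config, seed)."""
    config = config or CohortConfig()
    rng = np.random.default_rng(seed)

    probes = _probe_map(config, rng)
    bg_mask = (probes["role"] == "background").to_numpy()
    bg_mean = rng.uniform(0.05, 0.95, size=int(bg_mask.sum()))
    bg_sd = rng.uniform(0.005, 0.08, size=int(bg_mask.sum()))

    modes = list(config.mode_mixture)
    probs = np.asarray([config.mode_mixture[m] for m in modes], dtype=float)

    sample_rows, latent = [], {}
    germline_rows, coding_rows, noncoding_rows, cnv_rows = [], [], [], []
    truth: dict[str, dict] = {}

    for i in range(config.n_patients):
        pid = f"SYN{i:04d}"
        mode = str(rng.choice(modes, p=probs))
        paired = bool(rng.random() < config.p_paired)
        tumor_ids = [f"{pid}_tumorR", f"{pid}_tumorL"] if paired else [f"{pid}_tumorR"]
        lateralities = ["right", "left"] if paired else ["right"]
        purities = rng.uniform(*config.purity_range, size=len(tumor_ids))

        fk = fb = 0.0
        if mode == MODE_MOSAIC_LOI:
            fk = float(rng.beta(*config.kidney_fraction_beta))
            fb = float(rng.beta(*config.blood_fraction_beta))
        tumor_state = {MODE_GERMLINE: "LOH", MODE_MOSAIC_LOI: "LOI",
                       MODE_OTHER: "ROI"}[mode]

        nh, ni = config.normal_h19, config.normal_icr2
        latent[f"{pid}_blood"] = (nh + fb * (1.0 - nh), ni)
        latent[f"{pid}_kidney"] = (nh + fk * (1.0 - nh), ni)
        sample_rows.append((f"{pid}_blood", pid, "blood", "unknown", np.nan, "synthetic"))
        sample_rows.append((f"{pid}_kidney", pid, "kidney", "unknown", np.nan, "synthetic"))
        for sid, lat, purity in zip(tumor_ids, lateralities, purities):
            latent[sid] = expected_observed_beta(
                float(purity), tumor_state, normal_h19=nh, normal_icr2=ni)
            sample_rows.append((sid, pid, "tumor", lat, float(purity), "synthetic"))
            # neutral whole-chr1 segment so every tumor has a CNV profile
            cnv_rows.append((sid, "chr1", 1, 240_000_000, 0.0, False))

        germline_labels = []
        if mode == MODE_GERMLINE:
            germline_rows.append((pid, "WT1", "nonsense", "p.R362*", "pathogenic",
                                  "missing", "missing", 30, 30, 10, 50))
            germline_labels.append(("WT1", True))
            for sid, purity in zip(tumor_ids, purities):
                # cnLOH over 11p with breakpoints drawn independently per tumor
                start = int(rng.integers(1, 500_000))
                end = int(rng.integers(30_000_000, 48_000_000))
                cnv_rows.append((sid, "chr11", start, end, 0.0, True))
                if rng.random() < config.ctnnb1_prob:
                    change = str(rng.choice(_CTNNB1_EXON3_CHANGES))
                    coding_rows.append((sid, "CTNNB1", change))
        elif rng.random() < 0.3:
            # occasional benign panel variant so triage has negatives to exclude
            germline_rows.append((pid, "TP53", "missense", "p.P72R", "benign",
                                  "neutral", "benign", 40, 38, 41, 37))
            germline_labels.append(("TP53", False))

        n_shared = 0
        if mode == MODE_MOSAIC_LOI and paired:
            n_shared = max(1, int(rng.poisson(config.shared_noncoding_lam)))
        n_private = rng.poisson(config.private_noncoding_lam, size=len(tumor_ids))
        total = n_shared + int(n_private.sum())
        # rejection-sample unique positions; collisions are vanishingly rare
        # over this span, so the loop almost always runs once
        seen: set[int] = set()
        pos_list: list[int] = []
        while len(pos_list) < total:
            for v in rng.integers(10_000_000, 150_000_000,
                                  size=total - len(pos_list)):
                if int(v) not in seen:
                    seen.add(int(v))
                    pos_list.append(int(v))
        pool = np.asarray(pos_list, dtype=np.int64)
        refs = rng.choice(_BASES, size=total)
        alts = np.array([_BASES[(_BASES.index(r) + 1 + int(k)) % 4]
                         for r, k in zip(refs, rng.integers(0, 3, size=total))])
        cursor = 0
        shared_slice = slice(cursor, cursor + n_shared)
        cursor += n_shared
        for sid, n_priv in zip(tumor_ids, n_private):
            for idx in list(range(*shared_slice.indices(total))) + \
                    list(range(cursor, cursor + int(n_priv))):
                noncoding_rows.append((sid, "chr2", int(pool[idx]),
                                       str(refs[idx]), str(alts[idx])))
            cursor += int(n_priv)

        truth[pid] = {
            "mode": mode,
            "paired": paired,
            "tumor_state": tumor_state,
            "kidney_fraction": fk,
            "blood_fraction": fb,
            "purity": {sid: float(p) for sid, p in zip(tumor_ids, purities)},
            "n_shared_noncoding": int(n_shared) if paired else None,
            "germline_labels": germline_labels,
        }

    sample_ids = [r[0] for r in sample_rows]
    n_probes = len(probes)
    beta = np.empty((n_probes, len(sample_ids)))
    icr_roles = probes["role"].to_numpy()
    h19_mask = icr_roles == "h19"
    icr2_mask = icr_roles == "icr2"
    for j, sid in enumerate(sample_ids):
        h19_latent, icr2_latent = latent[sid]
        col = np.empty(n_probes)
        col[h19_mask] = h19_latent + rng.normal(0, config.probe_noise_sd,
                                                int(h19_mask.sum()))
        col[icr2_mask] = icr2_latent + rng.normal(0, config.probe_noise_sd,
                                                  int(icr2_mask.sum()))
        col[bg_mask] = bg_mean + rng.normal(0, 1, int(bg_mask.sum())) * bg_sd
        beta[:, j] = np.clip(col, 0.0, 1.0)

    matrix = ProbeBetaMatrix(
        probes[["chrom", "pos"]],
        pd.DataFrame(beta, index=probes.index, columns=sample_ids),
    )
    samples = validate_sample_sheet(pd.DataFrame(
        sample_rows, columns=["sample_id", "patient_id", "tissue", "laterality",
                              "purity", "cohort"]))
    germline = pd.DataFrame(germline_rows, columns=GERMLINE_COLUMNS)
    coding = pd.DataFrame(coding_rows, columns=SOMATIC_CODING_COLUMNS)
    noncoding = pd.DataFrame(noncoding_rows, columns=SOMATIC_NONCODING_COLUMNS)
    cnv = pd.DataFrame(cnv_rows, columns=CNV_COLUMNS)

    ground_truth = {"seed": int(seed), "config": _jsonable(asdict(config)),
                    "patients": truth}
    return SyntheticCohort(matrix, samples, germline, coding, noncoding, cnv,
                           ground_truth)


def generate_control_blood(n: int, mean: float = 0.499, sd: float = 0.0248,
                           seed: int | None = None,
                           rng: np.random.Generator | None = None) -> np.ndarray:
    """Healthy-control blood H19 betas: Normal draws truncated to [0, 1]."""
    if n < 2:
        raise ConfigError("need n >= 2 control draws")
    rng = rng if rng is not None else np.random.default_rng(seed)
    return np.clip(rng.normal(mean, sd, size=n), 0.0, 1.0)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj
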