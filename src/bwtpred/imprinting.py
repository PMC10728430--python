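"""11p15.5 imprinting-status classification and mosaicism estimation.

The two imprinting control regions at chromosome 11p15.5 are summarised by
the arithmetic mean beta over the probes falling inside each window
(1-based, end-inclusive, GRCh38).  Classification operates on raw observed
region means exactly as measured — purity is never used to pre-correct the
betas; :func:`expected_observed_beta` exists as a diagnostic so that likely
false-ROI calls in low-purity samples can be inspected.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import (
    EmptyRegionError,
    InsufficientControlsError,
    MissingInputError,
    ValidationError,
)
from .io import ProbeBetaMatrix

# categorical imprinting statuses
ROI = "ROI"
LOI = "LOI"
LOH = "LOH"
INDETERMINATE = "INDETERMINATE"
STATUSES = (ROI, LOI, LOH, INDETERMINATE)

PURE_STATE_BETA = {"ROI": (0.5, 0.5), "LOI": (1.0, 0.5), "LOH": (1.0, 0.0)}


@dataclass(frozen=True)
class IcrRegion:
    """A fixed genomic window summarised by its mean probe beta."""

    name: str
    chrom: str
    start: int
    end: int

    def __post_init__(self):
        if self.start >= self.end:
            raise ValidationError(f"region {self.name}: start must be < end")

    def contains(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start <= pos <= self.end


H19_ICR1 = IcrRegion("H19_ICR1", "chr11", 2_019_974, 2_024_738)
KCNQ1OT1_ICR2 = IcrRegion("KCNQ1OT1_ICR2", "chr11", 2_721_228, 2_722_228)

#: chr11 window spanning both ICRs; a cnLOH segment overlapping this window
#: counts as an 11p15.5 event.
P11_WINDOW = IcrRegion("11p15.5", "chr11", H19_ICR1.start, KCNQ1OT1_ICR2.end)


@dataclass(frozen=True)
class ControlCohortStats:
    """Healthy-control blood H19/ICR1 beta summary and the derived cutoff."""

    mean_beta: float
    sd_beta: float
    n: int
    multiplier: float = 2.0

    @property
    def gom_threshold(self) -> float:
        return self.mean_beta + self.multiplier * self.sd_beta

    @classmethod
    def from_summary(cls, mean_beta: float, sd_beta: float, n: int,
                     multiplier: float = 2.0) -> "ControlCohortStats":
        return cls(float(mean_beta), float(sd_beta), int(n), float(multiplier))


@dataclass(frozen=True)
class MosaicEstimate:
    fraction: float
    state: str
    basis: str


@dataclass
class IcrCall:
    sample_id: str
    h19_beta: float
    icr2_beta: float
    n_probes_h19: int
    n_probes_icr2: int
    cnloh_override: bool
    status: str


def region_mean_beta(matrix: ProbeBetaMatrix, sample_id: str,
                     region: IcrRegion) -> tuple[float, int]:
    """Mean beta over probes with ``region.start <= pos <= region.end``.

    Returns ``(mean, n_probes)``; raises :class:`EmptyRegionError` when no
    probe with a non-missing beta falls inside the window (an empty region
    is an error, never beta = 0).
    """
    if sample_id not in matrix.beta.columns:
        raise MissingInputError(f"sample {sample_id!r} not in beta matrix")
    probes = matrix.probes
    in_region = (probes["chrom"] == region.chrom) & \
        probes["pos"].between(region.start, region.end)
    vals = matrix.beta.loc[in_region.to_numpy(), sample_id].dropna()
    if vals.empty:
        raise EmptyRegionError(
            f"no probes in {region.name} ({region.chrom}:{region.start}-{region.end}) "
            f"for sample {sample_id!r}"
        )
    return float(vals.mean()), int(len(vals))


def beta_to_m(beta, eps: float = 1e-6):
    """Convert beta to M = log2(beta / (1 - beta)), clipping to [eps, 1-eps]."""
    b = np.clip(np.asarray(beta, dtype=float), eps, 1.0 - eps)
    m = np.log2(b / (1.0 - b))
    return float(m) if np.isscalar(beta) or np.ndim(beta) == 0 else m


def classify_icr_status(h19_beta, icr2_beta, cnloh_override: bool = False,
                        h19_threshold: float = 0.7,
                        icr2_threshold: float = 0.3) -> str:
    """Threshold classifier for 11p15.5 imprinting status.

    Strict inequalities on both thresholds; a region mean landing exactly on
    a threshold falls in no cell and yields INDETERMINATE with a warning.
    A cnLOH override (segmental evidence from sequencing) forces LOH.
    """
    if cnloh_override:
        return LOH
    if h19_beta is None or icr2_beta is None or \
            (isinstance(h19_beta, float) and np.isnan(h19_beta)) or \
            (isinstance(icr2_beta, float) and np.isnan(icr2_beta)):
        raise MissingInputError("both H19/ICR1 and ICR2 betas are required")
    h19, icr2 = float(h19_beta), float(icr2_beta)
    if h19 < h19_threshold and icr2 > icr2_threshold:
        return ROI
    if h19 > h19_threshold and icr2 > icr2_threshold:
        return LOI
    if h19 > h19_threshold and icr2 < icr2_threshold:
        return LOH
    if h19 == h19_threshold or icr2 == icr2_threshold:
        warnings.warn(
            f"region beta exactly at a classification threshold "
            f"(h19={h19}, icr2={icr2}); returning INDETERMINATE",
            stacklevel=2,
        )
    return INDETERMINATE


def expected_observed_beta(purity: float, state: str,
                           normal_h19: float = 0.5, normal_icr2: float = 0.5,
                           pure_state_beta: dict | None = None) -> tuple[float, float]:
    """Linear purity mixture: beta_obs = p * beta_state + (1 - p) * beta_normal."""
    table = PURE_STATE_BETA if pure_state_beta is None else pure_state_beta
    if state not in table:
        raise ValidationError(f"unknown imprinting state {state!r}")
    if not 0.0 <= purity <= 1.0:
        raise ValidationError(f"purity {purity} outside [0, 1]")
    pure_h19, pure_icr2 = table[state]
    h19 = purity * pure_h19 + (1.0 - purity) * normal_h19
    icr2 = purity * pure_icr2 + (1.0 - purity) * normal_icr2
    return h19, icr2


def estimate_mosaic_fraction(obs_h19: float, obs_icr2: float, state: str,
                             normal_h19: float = 0.5,
                             normal_icr2: float = 0.5) -> MosaicEstimate:
    """Closed-form inversion of the mixture model for the altered-cell fraction.

    LOI uses the H19 shift only; LOH averages the H19 gain and ICR2 loss
    signals.  The estimate is clipped to [0, 1] so measurement noise cannot
    push it out of range.
    """
    if state not in (LOI, LOH):
        raise ValidationError(f"mosaic fraction defined for LOI/LOH only, got {state!r}")
    f_h19 = (float(obs_h19) - normal_h19) / (1.0 - normal_h19)
    if state == LOI:
        f, basis = f_h19, "h19"
    else:
        f_icr2 = (normal_icr2 - float(obs_icr2)) / normal_icr2
        f, basis = (f_h19 + f_icr2) / 2.0, "h19+icr2"
    return MosaicEstimate(fraction=float(np.clip(f, 0.0, 1.0)), state=state, basis=basis)


def gom_threshold(control_betas, multiplier: float = 2.0) -> ControlCohortStats:
    """Mean + multiplier * sample SD (ddof=1) of the control blood betas."""
    vals = np.asarray(control_betas, dtype=float)
    vals = vals[~np.isnan(vals)]
    if vals.size < 2:
        raise InsufficientControlsError(
            f"need >= 2 control betas to estimate an SD, got {vals.size}"
        )
    return ControlCohortStats(
        mean_beta=float(vals.mean()),
        sd_beta=float(vals.std(ddof=1)),
        n=int(vals.size),
        multiplier=float(multiplier),
    )


def call_low_level_gom(blood_h19_beta: float, stats: ControlCohortStats) -> bool:
    """True iff the blood H19/ICR1 beta strictly exceeds the control cutoff."""
    return float(blood_h19_beta) > stats.gom_threshold


def select_top_variable_probes(matrix: ProbeBetaMatrix, n: int = 10_000,
                               exclude_chroms=("chrX", "chrY"),
                               use_m: bool = False,
                               eps: float = 1e-6) -> ProbeBetaMatrix:
    """Retain the ``n`` most variable probes, excluding sex chromosomes.

    Variance is computed across samples on the beta scale (or M scale when
    ``use_m``).  If fewer than ``n`` probes remain after exclusion, all are
    returned with a warning.
    """
    keep = ~matrix.probes["chrom"].isin(set(exclude_chroms))
    probes = matrix.probes.loc[keep.to_numpy()]
    beta = matrix.beta.loc[keep.to_numpy()]
    values = pd.DataFrame(beta_to_m(beta.to_numpy(), eps=eps),
                          index=beta.index, columns=beta.columns) if use_m else beta
    variances = values.var(axis=1, ddof=1)
    if len(probes) <= n:
        if len(probes) < n:
            warnings.warn(
                f"only {len(probes)} probes available after exclusion (requested {n})",
                stacklevel=2,
            )
        order = variances.sort_values(ascending=False, kind="stable").index
        return ProbeBetaMatrix(probes.loc[order], beta.loc[order])
    top = variances.sort_values(ascending=False, kind="stable").index[:n]
    return ProbeBetaMatrix(probes.loc[top], beta.loc[top])


def sample_has_11p_cnloh(cnv_df: pd.DataFrame, sample_id: str,
                         window: IcrRegion = P11_WINDOW) -> bool:
    """True when the sample has a cnLOH segment overlapping the 11p15.5 window."""
    if cnv_df is None:
        return False
    segs = cnv_df[(cnv_df["sample_id"] == sample_id) & cnv_df["cnloh"]]
    if segs.empty:
        return False
    on_chrom = segs[segs["chrom"] == window.chrom]
    return bool(((on_chrom["start"] <= window.end) & (on_chrom["end"] >= window.start)).any())


def call_samples(matrix: ProbeBetaMatrix, samples: pd.DataFrame,
                 cnv_df: pd.DataFrame | None = None,
                 h19_region: IcrRegion = H19_ICR1,
                 icr2_region: IcrRegion = KCNQ1OT1_ICR2,
                 h19_threshold: float = 0.7,
                 icr2_threshold: float = 0.3) -> pd.DataFrame:
    """Per-sample region means, cnLOH overrides and imprinting status.

    Returns one row per sample-sheet entry present in the beta matrix, with
    columns sample_id, patient_id, tissue, h19_beta, icr2_beta,
    n_probes_h19, n_probes_icr2, cnloh_override, status.
    """
    rows = []
    present = set(matrix.samples)
    for rec in samples.itertuples(index=False):
        if rec.sample_id not in present:
            continue
        h19, n_h19 = region_mean_beta(matrix, rec.sample_id, h19_region)
        icr2, n_icr2 = region_mean_beta(matrix, rec.sample_id, icr2_region)
        override = sample_has_11p_cnloh(cnv_df, rec.sample_id) if cnv_df is not None else False
        status = classify_icr_status(h19, icr2, cnloh_override=override,
                                     h19_threshold=h19_threshold,
                                     icr2_threshold=icr2_threshold)
        rows.append({
            "sample_id": rec.sample_id,
            "patient_id": rec.patient_id,
            "tissue": rec.tissue,
            "h19_beta": h19,
            "icr2_beta": icr2,
            "n_probes_h19": n_h19,
            "n_probes_icr2": n_icr2,
            "cnloh_override": override,
            "status": status,
        })
    return pd.DataFrame(rows)
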