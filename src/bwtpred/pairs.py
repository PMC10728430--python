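"""Concordance analysis of the two tumors in a synchronous bilateral pair.

Shared somatic variants place the pair's last common ancestor cell before
the right/left kidney primordia separate in the embryo; a large shared
burden together with a near-identical copy-number profile is instead more
consistent with two samples of a multifocal tumor from one kidney.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError
from .imprinting import IcrRegion, P11_WINDOW

INDEPENDENT = "independent"
SHARED_EARLY_CLONE = "shared_early_clone"
SUSPECTED_SAME_KIDNEY_MULTIFOCAL = "suspected_same_kidney_multifocal"

GAIN = "gain"
LOSS = "loss"
LOW_GAIN = "low_gain"
LOW_LOSS = "low_loss"
NEUTRAL = "neutral"


@dataclass
class PairConcordance:
    patient_id: str
    shared_coding: list = field(default_factory=list)
    n_shared_noncoding: int = 0
    icr_concordant: bool | None = None
    cnv_similarity: float | None = None
    breakpoints_11p_identical: bool | None = None
    origin_call: str | None = None


def shared_coding(set_a, set_b) -> list:
    """Coding variants present in both tumors, keyed on (gene, protein change).

    Distinct protein changes in the same gene do NOT match.
    """
    a = {(g.upper(), p) for g, p in set_a}
    b = {(g.upper(), p) for g, p in set_b}
    return sorted(a & b, key=lambda t: (t[0], t[1] or ""))


def count_shared_noncoding(set_a, set_b) -> int:
    """Size of the intersection keyed on exact (chrom, pos, ref, alt)."""
    return len(set(map(tuple, set_a)) & set(map(tuple, set_b)))


def classify_cnv_value(value: float) -> str:
    """Bucket a log2-ratio copy-number score into gain/loss categories."""
    v = float(value)
    if not np.isfinite(v):
        raise ValidationError(f"non-finite CNV value {value!r}")
    if v >= 0.5:
        return GAIN
    if v <= -0.5:
        return LOSS
    if v >= 0.1:
        return LOW_GAIN
    if v <= -0.1:
        return LOW_LOSS
    return NEUTRAL


def _bin_profile(segs: pd.DataFrame, grid: dict) -> np.ndarray:
    """Per-bin copy-number values on a shared genome grid (0 where uncovered)."""
    chunks = []
    for chrom, edges in grid.items():
        vals = np.zeros(len(edges), dtype=float)
        on_chrom = segs[segs["chrom"] == chrom]
        mids = edges  # bin midpoints precomputed in the grid
        for seg in on_chrom.itertuples(index=False):
            covered = (mids >= seg.start) & (mids <= seg.end)
            vals[covered] = seg.value
        chunks.append(vals)
    return np.concatenate(chunks) if chunks else np.array([])


def cnv_profile_similarity(segs_a: pd.DataFrame, segs_b: pd.DataFrame,
                           bin_size: int = 1_000_000) -> float:
    """Pearson correlation of binned copy-number profiles.

    The genome extent is the union of both profiles' segment spans per
    chromosome; bins take the value of the covering segment (0 where
    uncovered).  If either bin vector is constant, similarity is defined as
    1.0 when the vectors are equal and 0.0 otherwise.
    """
    if segs_a.empty or segs_b.empty:
        raise ValidationError("empty copy-number profile")
    grid: dict[str, np.ndarray] = {}
    both = pd.concat([segs_a, segs_b])
    for chrom, grp in both.groupby("chrom", sort=True):
        lo, hi = int(grp["start"].min()), int(grp["end"].max())
        # bin midpoints at lo + bin_size/2, lo + 3*bin_size/2, ...
        n_bins = max(1, int(np.ceil((hi - lo + 1) / bin_size)))
        grid[chrom] = lo + bin_size / 2 + bin_size * np.arange(n_bins)
    va = _bin_profile(segs_a, grid)
    vb = _bin_profile(segs_b, grid)
    if va.size < 1:
        raise ValidationError("profiles cover no bins")
    if np.std(va) == 0.0 or np.std(vb) == 0.0:
        return 1.0 if np.array_equal(va, vb) else 0.0
    return float(np.corrcoef(va, vb)[0, 1])


def _cnloh_11p_segment(segs: pd.DataFrame, window: IcrRegion) -> pd.Series | None:
    cand = segs[
        segs["cnloh"]
        & (segs["chrom"] == window.chrom)
        & (segs["start"] <= window.end)
        & (segs["end"] >= window.start)
    ]
    if cand.empty:
        return None
    # widest overlapping segment wins if several touch the window
    spans = cand["end"] - cand["start"]
    return cand.loc[spans.idxmax()]


def compare_11p_breakpoints(segs_a: pd.DataFrame, segs_b: pd.DataFrame,
                            tol_bp: int = 10_000,
                            window: IcrRegion = P11_WINDOW) -> bool | None:
    """Whether both tumors' 11p cnLOH segments share breakpoints within tol_bp.

    Returns None (missing, not False) when either tumor lacks a cnLOH
    segment overlapping the 11p15.5 window.
    """
    seg_a = _cnloh_11p_segment(segs_a, window)
    seg_b = _cnloh_11p_segment(segs_b, window)
    if seg_a is None or seg_b is None:
        return None
    return bool(abs(int(seg_a["start"]) - int(seg_b["start"])) <= tol_bp
                and abs(int(seg_a["end"]) - int(seg_b["end"])) <= tol_bp)


def classify_pair_origin(pc: PairConcordance,
                         atypical_shared_count: int = 20,
                         atypical_cnv_similarity: float = 0.9) -> str:
    """Categorical embryonic-origin call for a tumor pair.

    A pair with an atypically large shared noncoding burden and (when a
    copy-number similarity is available) a near-identical profile is flagged
    as suspected multifocal disease from one kidney; any sharing at all
    implies a shared early clone; otherwise the tumors are independent.
    """
    atypical_count = pc.n_shared_noncoding >= atypical_shared_count
    sim_ok = pc.cnv_similarity is None or pc.cnv_similarity >= atypical_cnv_similarity
    if atypical_count and sim_ok:
        return SUSPECTED_SAME_KIDNEY_MULTIFOCAL
    if pc.n_shared_noncoding >= 1 or pc.shared_coding:
        return SHARED_EARLY_CLONE
    return INDEPENDENT


def analyze_pair(patient_id: str,
                 coding_a, coding_b,
                 noncoding_a, noncoding_b,
                 icr_status_a: str | None = None,
                 icr_status_b: str | None = None,
                 segs_a: pd.DataFrame | None = None,
                 segs_b: pd.DataFrame | None = None,
                 bin_size: int = 1_000_000,
                 tol_bp: int = 10_000,
                 atypical_shared_count: int = 20,
                 atypical_cnv_similarity: float = 0.9) -> PairConcordance:
    """Full concordance summary for one synchronous pair."""
    pc = PairConcordance(
        patient_id=patient_id,
        shared_coding=shared_coding(coding_a, coding_b),
        n_shared_noncoding=count_shared_noncoding(noncoding_a, noncoding_b),
    )
    if icr_status_a is not None and icr_status_b is not None:
        pc.icr_concordant = icr_status_a == icr_status_b
    have_segs = (segs_a is not None and segs_b is not None
                 and not segs_a.empty and not segs_b.empty)
    if have_segs:
        pc.cnv_similarity = cnv_profile_similarity(segs_a, segs_b, bin_size=bin_size)
        pc.breakpoints_11p_identical = compare_11p_breakpoints(segs_a, segs_b, tol_bp=tol_bp)
    pc.origin_call = classify_pair_origin(
        pc, atypical_shared_count=atypical_shared_count,
        atypical_cnv_similarity=atypical_cnv_similarity)
    return pc
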