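"""Per-patient predisposition mode assignment and cohort-level statistics.

The integrated report distinguishes two predominant predisposition modes:
a germline genetic variant detectable in blood (often followed by 11p15.5
LOH in the tumor), or post-zygotic mosaic H19/ICR1 hypermethylation (LOI)
that may only be detectable across multiple tissues.  Patients with both a
germline hit and tumor LOI are labelled germline with an LOI co-annotation.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    DegenerateTableError,
    MissingInputError,
    UndefinedCorrelationError,
    ValidationError,
)
from .imprinting import (
    INDETERMINATE,
    LOH,
    LOI,
    ROI,
    STATUSES,
    ControlCohortStats,
    call_low_level_gom,
)

GERMLINE_GENETIC = "GERMLINE_GENETIC"
POSTZYGOTIC_MOSAIC_LOI = "POSTZYGOTIC_MOSAIC_LOI"
UNCLASSIFIED = "UNCLASSIFIED"

TIER_NONE = "none"
TIER_TUMOR_ONLY = "tumor_only"
TIER_TUMOR_KIDNEY = "tumor_plus_kidney"
TIER_TUMOR_KIDNEY_BLOOD = "tumor_kidney_blood"
TIERS = (TIER_NONE, TIER_TUMOR_ONLY, TIER_TUMOR_KIDNEY, TIER_TUMOR_KIDNEY_BLOOD)


@dataclass
class PatientReport:
    patient_id: str
    germline_positive: bool
    germline_genes: list = field(default_factory=list)
    tumor_icr_statuses: list = field(default_factory=list)
    kidney_icr_status: str | None = None
    blood_h19_beta: float | None = None
    blood_gom: bool | None = None
    blood_cnloh_mosaic: bool | None = None
    mode: str = UNCLASSIFIED
    mosaic_tier: str = TIER_NONE
    loi_co_annotation: bool = False

    def to_dict(self) -> dict:
        return asdict(self)


def assign_mode(patient_id: str,
                tumor_icr_statuses,
                germline_positive: bool,
                germline_genes=(),
                kidney_icr_status: str | None = None,
                blood_h19_beta: float | None = None,
                control_stats: ControlCohortStats | None = None,
                blood_cnloh_mosaic: bool | None = None) -> PatientReport:
    """Integrate per-tissue evidence into a predisposition mode and tier.

    Mode: a germline include wins (tumor imprinting recorded as a secondary
    event); otherwise any tumor LOI implies post-zygotic mosaic LOI;
    otherwise unclassified.  The mosaicism evidence tier escalates tumor ->
    tumor+kidney -> tumor+kidney+blood; blood evidence (low-level GOM or a
    mosaic cnLOH flag) only raises the tier when the kidney is also
    involved.
    """
    statuses = list(tumor_icr_statuses)
    if not statuses:
        raise MissingInputError(f"patient {patient_id!r} has no tumor ICR call")
    bad = set(statuses) - set(STATUSES)
    if bad:
        raise ValidationError(f"unknown ICR statuses: {sorted(bad)}")

    blood_gom = None
    if blood_h19_beta is not None and control_stats is not None:
        blood_gom = call_low_level_gom(blood_h19_beta, control_stats)

    any_loi = any(s == LOI for s in statuses)
    if germline_positive:
        mode = GERMLINE_GENETIC
    elif any_loi:
        mode = POSTZYGOTIC_MOSAIC_LOI
    else:
        mode = UNCLASSIFIED

    tier = TIER_NONE
    if any(s in (LOI, LOH) for s in statuses):
        tier = TIER_TUMOR_ONLY
        if kidney_icr_status in (LOI, LOH):
            tier = TIER_TUMOR_KIDNEY
            if bool(blood_gom) or bool(blood_cnloh_mosaic):
                tier = TIER_TUMOR_KIDNEY_BLOOD

    return PatientReport(
        patient_id=patient_id,
        germline_positive=germline_positive,
        germline_genes=sorted(set(germline_genes)),
        tumor_icr_statuses=statuses,
        kidney_icr_status=kidney_icr_status,
        blood_h19_beta=blood_h19_beta,
        blood_gom=blood_gom,
        blood_cnloh_mosaic=blood_cnloh_mosaic,
        mode=mode,
        mosaic_tier=tier,
        loi_co_annotation=bool(germline_positive and any_loi),
    )


def cohort_reports(calls: pd.DataFrame,
                   patient_flags: pd.Series,
                   germline_genes_by_patient: dict | None = None,
                   control_stats: ControlCohortStats | None = None,
                   blood_cnloh_flags: dict | None = None) -> list[PatientReport]:
    """Build one :class:`PatientReport` per patient with >=1 tumor ICR call.

    ``calls`` is the per-sample table from :func:`bwtpred.imprinting.call_samples`;
    ``patient_flags`` the boolean series from triage (patients absent from it
    are treated as germline-negative).
    """
    germline_genes_by_patient = germline_genes_by_patient or {}
    blood_cnloh_flags = blood_cnloh_flags or {}
    reports = []
    for patient_id, grp in calls.groupby("patient_id", sort=True):
        tumors = grp[grp["tissue"] == "tumor"]
        if tumors.empty:
            continue
        kidney = grp[grp["tissue"] == "kidney"]
        blood = grp[grp["tissue"] == "blood"]
        reports.append(assign_mode(
            patient_id=patient_id,
            tumor_icr_statuses=tumors["status"].tolist(),
            germline_positive=bool(patient_flags.get(patient_id, False)),
            germline_genes=germline_genes_by_patient.get(patient_id, ()),
            kidney_icr_status=None if kidney.empty else kidney["status"].iloc[0],
            blood_h19_beta=None if blood.empty else float(blood["h19_beta"].iloc[0]),
            control_stats=control_stats,
            blood_cnloh_mosaic=blood_cnloh_flags.get(patient_id),
        ))
    return reports


def icr_status_fractions(calls) -> pd.DataFrame:
    """Counts and fractions of ICR statuses over a list of calls."""
    statuses = list(calls)
    if not statuses:
        raise MissingInputError("no ICR calls supplied")
    counts = pd.Series(statuses).value_counts()
    out = pd.DataFrame({
        "count": [int(counts.get(s, 0)) for s in STATUSES],
        "fraction": [counts.get(s, 0) / len(statuses) for s in STATUSES],
    }, index=list(STATUSES))
    out["percent"] = (100 * out["fraction"]).round(1)
    return out


def germline_icr_association(germline_flags, icr_statuses) -> tuple[float, float, pd.DataFrame]:
    """Pearson chi-square on the {germline yes/no} x {ROI, LOI, LOH} table.

    Per-tumor INDETERMINATE calls are dropped (with a count in the returned
    table's attrs).  Returns (statistic, p, contingency_table).
    """
    df = pd.DataFrame({"germline": list(germline_flags), "status": list(icr_statuses)})
    n_dropped = int((df["status"] == INDETERMINATE).sum())
    df = df[df["status"] != INDETERMINATE]
    table = pd.crosstab(df["germline"], df["status"])
    table = table.loc[:, [c for c in (ROI, LOI, LOH) if c in table.columns]]
    if table.shape[0] < 2 or table.shape[1] < 2:
        raise DegenerateTableError(
            f"contingency table too small for a chi-square test: shape {table.shape}"
        )
    stat, p, _, _ = stats.chi2_contingency(table.to_numpy(), correction=False)
    table.attrs["n_indeterminate_dropped"] = n_dropped
    return float(stat), float(p), table


def blood_beta_group_comparison(groups: dict, correction: str = "holm") -> dict:
    """Compare blood region betas across patient groups.

    Two groups: Welch two-tailed t test.  Three or more: one-way ANOVA plus
    pairwise Welch t tests corrected for multiple comparisons (Holm by
    default; any ``statsmodels.stats.multitest`` method name is accepted).
    A per-group Kolmogorov-Smirnov normality check is reported as a
    diagnostic, not used as a gate.
    """
    from statsmodels.stats.multitest import multipletests

    if len(groups) < 2:
        raise ValidationError("need at least two groups")
    arrays = {}
    for name, vals in groups.items():
        a = np.asarray(vals, dtype=float)
        a = a[~np.isnan(a)]
        if a.size < 2:
            raise ValidationError(f"group {name!r} has n < 2")
        arrays[name] = a

    normality = {}
    for name, a in arrays.items():
        sd = a.std(ddof=1)
        if sd == 0:
            normality[name] = None
        else:
            _, ks_p = stats.kstest((a - a.mean()) / sd, "norm")
            normality[name] = float(ks_p)

    names = list(arrays)
    pairs, stats_t, pvals = [], [], []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            t, p = stats.ttest_ind(arrays[names[i]], arrays[names[j]], equal_var=False)
            pairs.append((names[i], names[j]))
            stats_t.append(float(t))
            pvals.append(float(p))

    result = {"normality_ks_p": normality, "anova_p": None}
    if len(names) >= 3:
        _, anova_p = stats.f_oneway(*arrays.values())
        result["anova_p"] = float(anova_p)
        adj = multipletests(pvals, method=correction)[1]
    else:
        adj = np.asarray(pvals)
    result["pairwise"] = pd.DataFrame({
        "group1": [a for a, _ in pairs],
        "group2": [b for _, b in pairs],
        "t": stats_t,
        "p_raw": pvals,
        "p_adj": adj,
    })
    return result


def purity_beta_correlation(purities, betas) -> tuple[float, float]:
    """Pearson r and two-sided p between tumor purity and region beta."""
    x = np.asarray(purities, dtype=float)
    y = np.asarray(betas, dtype=float)
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    if x.size < 3:
        raise ValidationError(f"need n >= 3 finite pairs, got {x.size}")
    if np.std(x) == 0 or np.std(y) == 0:
        raise UndefinedCorrelationError("constant input; correlation undefined")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)
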