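"""Germline predisposition variant triage.

A blood-derived candidate variant is counted as predisposing by an ordered
rule cascade: panel membership gates everything; indels and nonsense
variants are always included; a pathogenic/likely-pathogenic database
assertion includes, a benign/likely-benign assertion excludes; otherwise an
uncertain variant is included when either in-silico predictor calls it
damaging, or when its allele fraction is significantly enriched in the
matched tumor (consistent with retention of the mutated allele).

The enrichment test is a one-sided 2x2 exact test on read counts plus an
effect-size floor on the VAF difference; both knobs are configurable.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from scipy.stats import fisher_exact

from .errors import ValidationError

#: Wilms tumor predisposition genes named in the source gene panel; the full
#: 565-gene pediatric cancer list is accepted as a user-supplied file.
DEFAULT_PANEL = frozenset({
    "DICER1", "IGF2", "TP53", "WT1", "ASXL1", "BRCA2", "CDC73", "FBXW7",
    "PIK3CA", "BLM", "BUB1B", "CTR9", "DIS3L2", "GPC3", "KDM3B", "NYNRIN",
    "PALB2", "REST", "TRIP13", "TRIM28", "TRIM37",
})

VARIANT_CLASSES = frozenset({"indel", "nonsense", "missense", "splice", "other_snv"})
CLINVAR_CLASSES = frozenset({
    "benign", "likely_benign", "vus", "no_assertion", "unreported",
    "likely_pathogenic", "pathogenic",
})
# journal wording "probably pathogenic" maps onto the standard term
CLINVAR_ALIASES = {"probably_pathogenic": "likely_pathogenic"}
PROVEAN_CALLS = frozenset({"deleterious", "neutral", "missing"})
POLYPHEN_CALLS = frozenset({"benign", "possibly_damaging", "damaging", "missing"})

RULES = (
    "panel_miss", "indel_nonsense", "clinvar_pathogenic",
    "clinvar_benign_excluded", "predictor_damaging", "vaf_enrichment",
    "none_matched",
)
INCLUDE_RULES = frozenset({
    "indel_nonsense", "clinvar_pathogenic", "predictor_damaging", "vaf_enrichment",
})


@dataclass(frozen=True)
class TriageVerdict:
    include: bool
    rule_fired: str
    vaf_test_p: float | None = None

    def __post_init__(self):
        if self.include and self.rule_fired not in INCLUDE_RULES:
            raise ValidationError(
                f"include=True requires an including rule, got {self.rule_fired!r}"
            )


@dataclass(frozen=True)
class VafEnrichment:
    p_value: float | None
    enriched: bool
    delta_vaf: float | None


def load_panel(path) -> frozenset:
    """Read one gene symbol per line (case-insensitive, '#' comments allowed)."""
    genes = set()
    for line in open(path, encoding="utf-8"):
        line = line.strip()
        if line and not line.startswith("#"):
            genes.add(line.upper())
    if not genes:
        raise ValidationError(f"gene panel {path} is empty")
    return frozenset(genes)


def in_panel(gene: str, panel=DEFAULT_PANEL) -> bool:
    if not panel:
        raise ValidationError("gene panel is empty")
    return gene.upper() in {g.upper() for g in panel}


def vaf_enrichment_test(germline_ref: int, germline_alt: int,
                        tumor_ref: int, tumor_alt: int,
                        alpha: float = 0.05,
                        min_delta: float = 0.15) -> VafEnrichment:
    """One-sided exact test of alt-allele fraction being higher in tumor.

    Enriched requires both p < alpha and tumor VAF - germline VAF >=
    min_delta.  Zero depth in either tissue is untestable (not enriched,
    p missing).
    """
    for c in (germline_ref, germline_alt, tumor_ref, tumor_alt):
        if c < 0:
            raise ValidationError("read counts must be >= 0")
    g_depth = germline_ref + germline_alt
    t_depth = tumor_ref + tumor_alt
    if g_depth == 0 or t_depth == 0:
        return VafEnrichment(p_value=None, enriched=False, delta_vaf=None)
    # rows: tumor, germline; columns: alt, ref.  "greater" = tumor alt odds higher.
    _, p = fisher_exact([[tumor_alt, tumor_ref], [germline_alt, germline_ref]],
                        alternative="greater")
    delta = tumor_alt / t_depth - germline_alt / g_depth
    return VafEnrichment(p_value=float(p),
                         enriched=bool(p < alpha and delta >= min_delta),
                         delta_vaf=float(delta))


def _normalize(value: str, allowed: frozenset, aliases: dict | None = None,
               what: str = "value") -> str:
    v = str(value).strip().lower().replace(" ", "_")
    if aliases:
        v = aliases.get(v, v)
    if v not in allowed:
        raise ValidationError(f"unknown {what} {value!r}")
    return v


def triage_variant(variant, panel=DEFAULT_PANEL, alpha: float = 0.05,
                   min_delta: float = 0.15) -> TriageVerdict:
    """Apply the ordered rule cascade to one variant record.

    ``variant`` is any mapping or namedtuple-like object exposing the
    germline-variant table columns.  Exactly one rule fires per variant.
    """
    get = (variant.get if hasattr(variant, "get")
           else lambda k: getattr(variant, k))
    gene = str(get("gene")).upper()
    vclass = _normalize(get("variant_class"), VARIANT_CLASSES, what="variant class")
    clinvar = _normalize(get("clinvar"), CLINVAR_CLASSES, CLINVAR_ALIASES, "ClinVar class")
    provean = _normalize(get("provean") or "missing", PROVEAN_CALLS, what="PROVEAN call")
    polyphen = _normalize(get("polyphen") or "missing", POLYPHEN_CALLS, what="PolyPhen call")

    if not in_panel(gene, panel):
        return TriageVerdict(False, "panel_miss")
    if vclass in ("indel", "nonsense"):
        return TriageVerdict(True, "indel_nonsense")
    if clinvar in ("pathogenic", "likely_pathogenic"):
        return TriageVerdict(True, "clinvar_pathogenic")
    if clinvar in ("benign", "likely_benign"):
        return TriageVerdict(False, "clinvar_benign_excluded")
    if provean == "deleterious" or polyphen in ("possibly_damaging", "damaging"):
        return TriageVerdict(True, "predictor_damaging")
    res = vaf_enrichment_test(int(get("germline_ref")), int(get("germline_alt")),
                              int(get("tumor_ref")), int(get("tumor_alt")),
                              alpha=alpha, min_delta=min_delta)
    if res.enriched:
        return TriageVerdict(True, "vaf_enrichment", vaf_test_p=res.p_value)
    return TriageVerdict(False, "none_matched", vaf_test_p=res.p_value)


def triage_table(variants: pd.DataFrame, panel=DEFAULT_PANEL,
                 alpha: float = 0.05, min_delta: float = 0.15) -> pd.DataFrame:
    """Run :func:`triage_variant` over a germline variant table.

    Returns a copy of the table with appended ``include``, ``rule_fired``
    and ``vaf_test_p`` columns.
    """
    verdicts = [triage_variant(row, panel=panel, alpha=alpha, min_delta=min_delta)
                for row in variants.to_dict("records")]
    out = variants.copy()
    out["include"] = [v.include for v in verdicts]
    out["rule_fired"] = [v.rule_fired for v in verdicts]
    out["vaf_test_p"] = [v.vaf_test_p for v in verdicts]
    return out


def patients_with_predisposition(variants: pd.DataFrame, panel=DEFAULT_PANEL,
                                 alpha: float = 0.05, min_delta: float = 0.15,
                                 ) -> tuple[pd.Series, pd.Series, pd.DataFrame]:
    """Per-patient predisposition flag and per-gene included-variant tally.

    A patient is flagged iff they carry at least one included variant (a
    patient with two included variants counts once).  Returns
    ``(patient_flags, gene_counts, verdict_table)``.
    """
    verdicts = triage_table(variants, panel=panel, alpha=alpha, min_delta=min_delta)
    if verdicts.empty:
        return (pd.Series(dtype=bool, name="predisposed"),
                pd.Series(dtype="int64", name="n_included"),
                verdicts)
    flags = verdicts.groupby("patient_id")["include"].any().rename("predisposed")
    included = verdicts[verdicts["include"]]
    gene_counts = included.groupby("gene").size().rename("n_included").sort_index()
    return flags, gene_counts, verdicts
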