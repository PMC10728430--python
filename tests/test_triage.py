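import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bwtpred.errors import ValidationError
from bwtpred.triage import (
    DEFAULT_PANEL,
    INCLUDE_RULES,
    RULES,
    TriageVerdict,
    in_panel,
    patients_with_predisposition,
    triage_variant,
    vaf_enrichment_test,
)


def make_variant(**over):
    base = dict(
        patient_id="P1", gene="WT1", variant_class="missense",
        protein_change="p.A1B", clinvar="vus", provean="missing",
        polyphen="missing", germline_ref=50, germline_alt=50,
        tumor_ref=50, tumor_alt=50,
    )
    base.update(over)
    return base


def exact_test_oracle(g_ref, g_alt, t_ref, t_alt):
    """One-sided p by full hypergeometric enumeration with math.comb."""
    n_tumor = t_ref + t_alt
    n_germ = g_ref + g_alt
    total_alt = g_alt + t_alt
    total = n_tumor + n_germ
    denom = math.comb(total, total_alt)
    p = 0.0
    for k in range(t_alt, min(n_tumor, total_alt) + 1):
        if total_alt - k > n_germ:
            continue
        p += math.comb(n_tumor, k) * math.comb(n_germ, total_alt - k) / denom
    return p


class TestPanel:
    def test_wt1_in_default_panel(self):
        assert in_panel("WT1")

    def test_default_panel_has_21_genes(self):
        assert len(DEFAULT_PANEL) == 21

    def test_myh7_not_in_default_panel(self):
        assert not in_panel("MYH7")

    def test_case_insensitive(self):
        assert in_panel("wt1")
        assert in_panel("WT1", panel={"wt1"})

    def test_linear_scan_oracle(self, rng):
        genes = [f"G{i}" for i in range(30)]
        panel = frozenset(rng.choice(genes, size=10, replace=False))
        for g in genes:
            found = False
            for p in panel:
                if p.upper() == g.upper():
                    found = True
            assert in_panel(g, panel) == found

    def test_empty_panel_errors(self):
        with pytest.raises(ValidationError):
            in_panel("WT1", panel=frozenset())


class TestVafEnrichment:
    def test_clear_enrichment(self):
        res = vaf_enrichment_test(50, 50, 10, 90)
        assert res.enriched
        assert res.p_value < 0.05
        assert res.delta_vaf == pytest.approx(0.4)

    def test_identical_counts_not_enriched(self):
        res = vaf_enrichment_test(50, 50, 50, 50)
        assert not res.enriched

    def test_zero_effect_at_high_depth(self):
        res = vaf_enrichment_test(5000, 5000, 5000, 5000)
        assert not res.enriched  # no effect despite huge power

    def test_zero_depth_untestable(self):
        res = vaf_enrichment_test(0, 0, 10, 90)
        assert res.p_value is None
        assert not res.enriched

    def test_negative_counts_rejected(self):
        with pytest.raises(ValidationError):
            vaf_enrichment_test(-1, 5, 5, 5)

    @pytest.mark.parametrize("counts", [
        (50, 50, 10, 90), (20, 5, 10, 15), (30, 30, 25, 35), (8, 2, 3, 7),
    ])
    def test_enumeration_oracle(self, counts):
        g_ref, g_alt, t_ref, t_alt = counts
        res = vaf_enrichment_test(g_ref, g_alt, t_ref, t_alt)
        assert res.p_value == pytest.approx(exact_test_oracle(*counts), rel=1e-9)

    def test_effect_floor_blocks_tiny_shifts(self):
        # significant at huge depth but delta < 0.15 -> not enriched
        res = vaf_enrichment_test(5000, 5000, 4500, 5500)
        assert res.p_value < 0.05
        assert res.delta_vaf < 0.15
        assert not res.enriched


class TestTriageRules:
    def test_nonsense_included_rule2(self):
        v = make_variant(gene="WT1", variant_class="nonsense",
                         protein_change="p.Q253*")
        verdict = triage_variant(v)
        assert verdict.include and verdict.rule_fired == "indel_nonsense"

    def test_off_panel_excluded_first(self):
        v = make_variant(gene="MYH7", variant_class="nonsense")
        verdict = triage_variant(v)
        assert not verdict.include and verdict.rule_fired == "panel_miss"

    def test_missense_vus_with_damaging_predictor(self):
        # panel extended with BRCA1 (from the 565-gene list)
        v = make_variant(gene="BRCA1", protein_change="p.Q687P",
                         polyphen="possibly_damaging")
        verdict = triage_variant(v, panel=DEFAULT_PANEL | {"BRCA1"})
        assert verdict.include and verdict.rule_fired == "predictor_damaging"

    def test_benign_beats_predictor(self):
        v = make_variant(clinvar="benign", provean="deleterious")
        verdict = triage_variant(v)
        assert not verdict.include
        assert verdict.rule_fired == "clinvar_benign_excluded"

    def test_pathogenic_included(self):
        for cls in ("pathogenic", "likely_pathogenic", "probably pathogenic"):
            verdict = triage_variant(make_variant(clinvar=cls))
            assert verdict.include and verdict.rule_fired == "clinvar_pathogenic"

    def test_vaf_rescue_of_vus(self):
        v = make_variant(germline_ref=50, germline_alt=50,
                         tumor_ref=10, tumor_alt=90)
        verdict = triage_variant(v)
        assert verdict.include and verdict.rule_fired == "vaf_enrichment"
        assert verdict.vaf_test_p is not None

    def test_nothing_matches(self):
        verdict = triage_variant(make_variant())
        assert not verdict.include and verdict.rule_fired == "none_matched"

    def test_splice_vus_flows_through_uncertain_rules(self):
        v = make_variant(gene="DICER1", variant_class="splice",
                         provean="deleterious")
        verdict = triage_variant(v)
        assert verdict.include and verdict.rule_fired == "predictor_damaging"

    def test_unknown_enum_rejected(self):
        with pytest.raises(ValidationError):
            triage_variant(make_variant(variant_class="weird"))
        with pytest.raises(ValidationError):
            triage_variant(make_variant(clinvar="maybe"))

    def test_verdict_invariant(self):
        with pytest.raises(ValidationError):
            TriageVerdict(include=True, rule_fired="panel_miss")

    @given(
        gene=st.sampled_from(sorted(DEFAULT_PANEL) + ["MYH7", "ABC"]),
        vclass=st.sampled_from(["indel", "nonsense", "missense", "splice", "other_snv"]),
        clinvar=st.sampled_from(["benign", "likely_benign", "vus", "no_assertion",
                                 "unreported", "likely_pathogenic", "pathogenic"]),
        provean=st.sampled_from(["deleterious", "neutral", "missing"]),
        polyphen=st.sampled_from(["benign", "possibly_damaging", "damaging", "missing"]),
        g_alt=st.integers(0, 60),
        t_alt=st.integers(0, 60),
    )
    @settings(max_examples=200, deadline=None)
    def test_exactly_one_rule_fires(self, gene, vclass, clinvar, provean,
                                    polyphen, g_alt, t_alt):
        v = make_variant(gene=gene, variant_class=vclass, clinvar=clinvar,
                         provean=provean, polyphen=polyphen,
                         germline_alt=g_alt, tumor_alt=t_alt,
                         germline_ref=60 - g_alt, tumor_ref=60 - t_alt)
        verdict = triage_variant(v)
        assert verdict.rule_fired in RULES
        assert verdict.include == (verdict.rule_fired in INCLUDE_RULES)

    @given(
        vclass=st.sampled_from(["indel", "nonsense", "missense"]),
        clinvar=st.sampled_from(["benign", "vus", "pathogenic"]),
        provean=st.sampled_from(["deleterious", "neutral"]),
    )
    @settings(max_examples=60, deadline=None)
    def test_vaf_rule_never_flips_earlier_includes(self, vclass, clinvar, provean):
        # any include decided by rules 2-5 is identical with or without VAF data
        with_vaf = make_variant(variant_class=vclass, clinvar=clinvar,
                                provean=provean, tumor_ref=10, tumor_alt=90)
        no_vaf = make_variant(variant_class=vclass, clinvar=clinvar,
                              provean=provean, tumor_ref=50, tumor_alt=50)
        va, vb = triage_variant(with_vaf), triage_variant(no_vaf)
        if vb.rule_fired not in ("vaf_enrichment", "none_matched"):
            assert (va.include, va.rule_fired) == (vb.include, vb.rule_fired)


class TestCohortSummary:
    def _table(self, rows):
        return pd.DataFrame([make_variant(**r) for r in rows])

    def test_patient_with_two_includes_counted_once(self):
        df = self._table([
            dict(patient_id="P1", variant_class="nonsense"),
            dict(patient_id="P1", gene="TRIM28", clinvar="pathogenic"),
            dict(patient_id="P2"),
        ])
        flags, gene_counts, _ = patients_with_predisposition(df)
        assert int(flags.sum()) == 1
        assert flags["P1"] and not flags["P2"]
        assert gene_counts["WT1"] == 1 and gene_counts["TRIM28"] == 1

    def test_empty_table(self):
        flags, gene_counts, verdicts = patients_with_predisposition(
            pd.DataFrame(columns=list(make_variant().keys())))
        assert len(flags) == 0
        assert len(gene_counts) == 0

    def test_group_by_oracle(self, rng):
        rows = []
        for i in range(40):
            rows.append(dict(
                patient_id=f"P{rng.integers(0, 10)}",
                gene=str(rng.choice(["WT1", "TRIM28", "MYH7"])),
                variant_class=str(rng.choice(["nonsense", "missense"])),
                clinvar=str(rng.choice(["benign", "vus", "pathogenic"])),
            ))
        df = self._table(rows)
        flags, gene_counts, verdicts = patients_with_predisposition(df)
        # oracle: brute-force group-by over the verdict table
        expected_flags = {}
        expected_counts = {}
        for rec in verdicts.to_dict("records"):
            expected_flags.setdefault(rec["patient_id"], False)
            if rec["include"]:
                expected_flags[rec["patient_id"]] = True
                expected_counts[rec["gene"]] = expected_counts.get(rec["gene"], 0) + 1
        assert flags.to_dict() == expected_flags
        assert gene_counts.to_dict() == expected_counts

    def test_deterministic_label_recovery(self, rng):
        # labels planted consistently with the rules are recovered exactly
        rows, labels = [], []
        for i in range(30):
            if rng.random() < 0.5:
                rows.append(dict(patient_id=f"P{i}", variant_class="indel"))
                labels.append(True)
            else:
                rows.append(dict(patient_id=f"P{i}", clinvar="benign"))
                labels.append(False)
        _, _, verdicts = patients_with_predisposition(self._table(rows))
        assert verdicts["include"].tolist() == labels
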