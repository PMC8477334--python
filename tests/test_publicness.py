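import numpy as np
import pandas as pd
import pytest

from pmltcr.expansion import call_expansions, recurrent_expansion_test
from pmltcr.publicness import (
    annotate_databases,
    classify_public,
    db_enrichment_public_vs_private,
    public_among_expanded,
    sensitivity_without_public,
)
from pmltcr.repertoire_io import ClonotypeRecord, SampleMetadata, build_cohort
from pmltcr.synthetic_cohort import generate_annotation_db, generate_reference_set, scaled_config


@pytest.fixture
def mixed_cohort():
    records = [
        ClonotypeRecord("A", "CASSLGF", 1, chain="TRB"),  # P1+P2 -> public
        ClonotypeRecord("B", "CASSLGF", 1, chain="TRB"),
        ClonotypeRecord("A", "CASSQET", 1, chain="TRB"),  # P1 only, in reference -> public
        ClonotypeRecord("A", "CAVRDNF", 1, chain="TRA"),  # P1 only, TRA in reference -> private
        ClonotypeRecord("B", "CASSWET", 1, chain="TRB"),  # P2 only -> private
    ]
    metas = [
        SampleMetadata("A", "P1", "L1", 1),
        SampleMetadata("B", "P2", "L1", 1, sample_type="brush"),
    ]
    return build_cohort(records, metas)


class TestClassifyPublic:
    def test_multi_patient_clonotype_is_public(self, mixed_cohort):
        ann = classify_public(mixed_cohort).set_index("cdr3_aa")
        assert ann.loc["CASSLGF", "public"]
        assert ann.loc["CASSLGF", "n_patients"] == 2

    def test_beta_reference_rescues_singleton(self, mixed_cohort):
        ann = classify_public(mixed_cohort, reference_beta=["CASSQET", "CAVRDNF"]).set_index("cdr3_aa")
        assert ann.loc["CASSQET", "public"]
        # the healthy-donor reference is beta-chain only
        assert not ann.loc["CAVRDNF", "public"]

    def test_empty_reference_reduces_to_patient_rule(self, mixed_cohort):
        ann = classify_public(mixed_cohort).set_index("cdr3_aa")
        assert list(ann[ann["public"]].index) == ["CASSLGF"]

    def test_publicness_monotone_under_added_samples(self, mixed_cohort):
        ann_before = classify_public(mixed_cohort)
        extra = build_cohort(
            mixed_cohort.to_records()
            + [ClonotypeRecord("C", "CASSWET", 1, chain="TRB")],
            [
                SampleMetadata("A", "P1", "L1", 1),
                SampleMetadata("B", "P2", "L1", 1, sample_type="brush"),
                SampleMetadata("C", "P3", "L1", 1),
            ],
        )
        ann_after = classify_public(extra)
        before = set(ann_before.loc[ann_before["public"], "cdr3_aa"])
        after = set(ann_after.loc[ann_after["public"], "cdr3_aa"])
        assert before <= after


class TestAnnotateDatabases:
    def test_hit_in_both_databases_counted_twice(self, mixed_cohort):
        ann = classify_public(mixed_cohort)
        mcpas = pd.DataFrame(
            [{"CDR3.beta.aa": "CASSLGF", "CDR3.alpha.aa": None,
              "Pathology": "CMV", "Antigen.protein": "pp65"}]
        )
        vdjdb = pd.DataFrame(
            [{"cdr3": "CASSLGF", "gene": "TRB", "antigen.epitope": "pp65", "antigen.species": "CMV"}]
        )
        out = annotate_databases(ann, mcpas, vdjdb).set_index("cdr3_aa")
        assert out.loc["CASSLGF", "n_db_hits"] == 2
        assert {h[0] for h in out.loc["CASSLGF", "db_hits"]} == {"mcpas", "vdjdb"}

    def test_chain_aware_matching(self, mixed_cohort):
        ann = classify_public(mixed_cohort)
        vdjdb = pd.DataFrame(
            [{"cdr3": "CAVRDNF", "gene": "TRB", "antigen.epitope": "x", "antigen.species": "y"}]
        )
        out = annotate_databases(ann, None, vdjdb).set_index("cdr3_aa")
        assert out.loc["CAVRDNF", "n_db_hits"] == 0  # cohort clone is TRA

    def test_no_matches_leave_all_empty(self, mixed_cohort):
        ann = annotate_databases(classify_public(mixed_cohort), None, None)
        assert not ann["any_db_hit"].any()

    def test_malformed_rows_skipped(self, mixed_cohort):
        ann = classify_public(mixed_cohort)
        mcpas = pd.DataFrame(
            [
                {"CDR3.beta.aa": None, "CDR3.alpha.aa": None, "Pathology": "x", "Antigen.protein": "y"},
                {"CDR3.beta.aa": "CASSWET", "CDR3.alpha.aa": None, "Pathology": "flu", "Antigen.protein": "M1"},
            ]
        )
        out = annotate_databases(ann, mcpas, None).set_index("cdr3_aa")
        assert out.loc["CASSWET", "n_db_hits"] == 1


class TestDbEnrichment:
    def test_empty_class_rejected(self, mixed_cohort):
        ann = classify_public(mixed_cohort)
        ann["public"] = True
        ann["any_db_hit"] = True
        ann["n_db_hits"] = 1
        with pytest.raises(ValueError):
            db_enrichment_public_vs_private(ann)

    def test_generator_defaults_give_enrichment(self):
        cfg = scaled_config(seed=8)
        from pmltcr.synthetic_cohort import generate_cohort

        cohort, _, _ = generate_cohort(cfg)
        ann = annotate_databases(
            classify_public(cohort, generate_reference_set(cfg)), *generate_annotation_db(cfg)
        )
        res = db_enrichment_public_vs_private(ann)
        assert res.estimate > 2
        assert res.p_value < 0.01


class TestPublicAmongExpanded:
    def test_no_public_clones_gives_corrected_zero_or(self, mixed_cohort):
        ann = classify_public(mixed_cohort)
        ann["public"] = False
        calls = pd.DataFrame(
            {
                "sample_id": ["A"],
                "chain": ["TRB"],
                "cdr3_aa": ["CASSLGF"],
                "cpt": [500.0],
                "expanded": [True],
            }
        )
        res = public_among_expanded(ann, calls, mixed_cohort)
        # a cohort without public clones has an empty public column: the
        # odds ratio is uninformative and the table is flagged degenerate
        assert res.extra["degenerate_public_classes"]
        assert np.isfinite(res.estimate)

    def test_all_public_flags_degenerate(self, mixed_cohort):
        ann = classify_public(mixed_cohort)
        ann["public"] = True
        calls = pd.DataFrame(
            {
                "sample_id": ["A"],
                "chain": ["TRB"],
                "cdr3_aa": ["CASSLGF"],
                "cpt": [500.0],
                "expanded": [True],
            }
        )
        res = public_among_expanded(ann, calls, mixed_cohort)
        assert res.extra["degenerate_public_classes"]

    def test_requires_an_expanded_clone(self, mixed_cohort):
        ann = classify_public(mixed_cohort)
        calls = pd.DataFrame(
            {"sample_id": ["A"], "chain": ["TRB"], "cdr3_aa": ["CASSLGF"], "cpt": [1.0], "expanded": [False]}
        )
        with pytest.raises(ValueError):
            public_among_expanded(ann, calls, mixed_cohort)

    def test_generator_public_expansion_association(self):
        # public/shared clones get more chances to be expanded, so the OR
        # should exceed 1 in most replicates
        from pmltcr.synthetic_cohort import generate_cohort

        above = 0
        for seed in (1, 2, 3, 4, 5):
            cfg = scaled_config(seed=seed)
            cohort, _, _ = generate_cohort(cfg)
            ann = classify_public(cohort, generate_reference_set(cfg))
            _, calls = call_expansions(cohort)
            rec = recurrent_expansion_test(calls, cohort.samples, n_perm=50, seed=seed)
            res = public_among_expanded(ann, calls, cohort, recurrent=rec.recurrent)
            if res.estimate > 1:
                above += 1
        assert above >= 3


class TestSensitivityWithoutPublic:
    def test_conclusions_stable_on_private_only_cohort(self, small_cohort):
        cohort, _, scores = small_cohort
        cfg = scaled_config(seed=3)
        ann = classify_public(cohort, generate_reference_set(cfg))
        report = sensitivity_without_public(cohort, ann, scores=scores)
        full, priv = report["full"], report["private_only"]
        assert full["module_assoc_slope"] < 0 and priv["module_assoc_slope"] < 0
        assert full["module_assoc_p"] < 0.05 and priv["module_assoc_p"] < 0.05
        assert full["outcome_mean_cpk_regressive"] < full["outcome_mean_cpk_progressive"]
        assert priv["outcome_mean_cpk_regressive"] < priv["outcome_mean_cpk_progressive"]
        assert full["sharing_anova_p"] < 0.01 and priv["sharing_anova_p"] < 0.01

    def test_all_public_cohort_degrades_gracefully(self, mixed_cohort):
        ann = classify_public(mixed_cohort)
        ann["public"] = True
        report = sensitivity_without_public(mixed_cohort, ann)
        assert "error" in report["private_only"]
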