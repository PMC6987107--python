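"""Qualifying-variant filters: consequence/score logic, frequency, regions, singletons."""

import logging

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from raresweep import (
    CODING_TERMS,
    LOF_TERMS,
    DataError,
    QualifyingConfig,
    build_qualifying_sets,
    classify_model,
    is_singleton,
    passes_maf_filter,
    passes_region_filter,
)
from raresweep.errors import ConfigError
from raresweep.qualify import build_interval_tree


class TestClassifyModel:
    @pytest.mark.parametrize(
        "consequence, polyphen, sift, expected",
        [
            ("stop_gained", None, None, (True, True)),
            ("missense_variant", 0.10, 0.50, (False, False)),  # PolyPhen-benign
            ("missense_variant", 0.90, 0.01, (True, False)),  # damaging missense
            ("missense_variant", 0.90, 0.50, (False, False)),  # SIFT-benign (either rule)
            ("synonymous_variant", None, None, (False, False)),
            ("frameshift_variant", None, None, (True, True)),
            ("inframe_deletion", None, None, (True, False)),
            ("missense_variant", None, None, (True, False)),  # unscored retained
            ("splice_acceptor_variant", None, None, (True, True)),
        ],
    )
    def test_term_and_score_logic(self, consequence, polyphen, sift, expected):
        assert classify_model(consequence, polyphen, sift) == expected

    def test_unrecognized_term_warns_not_raises(self, caplog):
        with caplog.at_level(logging.WARNING):
            assert classify_model("made_up_term", None, None) == (False, False)
        assert any("unrecognized" in r.message for r in caplog.records)

    def test_both_tool_rule_requires_both_benign(self):
        cfg = QualifyingConfig(benign_rule="both")
        # benign by PolyPhen only: kept under the both-tool rule
        assert classify_model("missense_variant", 0.10, 0.01, cfg) == (True, False)
        assert classify_model("missense_variant", 0.10, 0.50, cfg) == (False, False)

    def test_score_boundaries_are_strict(self):
        # 0.15 is not below 0.15; 0.05 is not above 0.05 -> not benign
        assert classify_model("missense_variant", 0.15, 0.05) == (True, False)

    def test_lof_terms_subset_of_coding(self):
        assert LOF_TERMS <= CODING_TERMS


class TestMafFilter:
    def test_any_reference_population_at_or_above_cutoff_fails(self):
        assert not passes_maf_filter({"AFR": 0.002, "NFE": 0.0}, {"EUR": 5e-5})

    def test_absent_from_reference_passes(self):
        assert passes_maf_filter({}, {"EUR": 1.0 / (2 * 40_468)})

    def test_exact_cutoff_fails_strict(self):
        assert not passes_maf_filter({}, {"EUR": 0.001})

    def test_frequency_outside_unit_interval_raises(self):
        with pytest.raises(DataError):
            passes_maf_filter({"NFE": 1.2}, {})

    @given(
        afs=st.lists(st.floats(0, 1, allow_nan=False), max_size=6),
        cutoff=st.floats(1e-6, 0.5),
    )
    @settings(deadline=None)
    def test_passes_iff_all_below(self, afs, cutoff):
        ref = {f"p{i}": f for i, f in enumerate(afs)}
        assert passes_maf_filter(ref, {}, cutoff) == all(f < cutoff for f in afs)


class TestRegionFilter:
    def setup_method(self):
        self.cds = build_interval_tree([(100, 200)])
        self.hc = build_interval_tree([(0, 1000)])

    def test_inside_both(self):
        assert passes_region_filter(150, self.cds, self.hc)

    def test_half_open_convention(self):
        assert passes_region_filter(100, self.cds, self.hc)
        assert not passes_region_filter(200, self.cds, self.hc)

    def test_in_cds_outside_high_confidence(self):
        hc = build_interval_tree([(500, 1000)])
        assert not passes_region_filter(150, self.cds, hc)

    def test_malformed_interval_raises(self):
        with pytest.raises(DataError):
            build_interval_tree([(200, 100)])


class TestSingleton:
    @pytest.mark.parametrize(
        "dataset_ac, reference_ac, expected",
        [(1, 0, True), (1, 3, False), (2, 0, False), (0, 0, False)],
    )
    def test_definition(self, dataset_ac, reference_ac, expected):
        assert is_singleton(dataset_ac, reference_ac) is expected

    def test_negative_count_raises(self):
        with pytest.raises(DataError):
            is_singleton(-1, 0)


class TestBuildQualifyingSets:
    def _trees(self):
        return build_interval_tree([(0, 1000)]), build_interval_tree([(0, 1000)])

    def test_filter_composition(self, toy_variants):
        cds, hc = self._trees()
        qs = build_qualifying_sets(
            toy_variants, {"v1": 3, "v2": 1, "v3": 40}, QualifyingConfig(), "coding", cds, hc
        )
        assert qs.genes == {"G1": ["v2"]}
        assert qs.singleton["v2"] is True
        # count conservation: qualifying + rejected = input
        assert qs.n_qualifying + qs.n_rejected == qs.n_input == 3

    def test_lof_model_drops_missense_only_gene(self, toy_variants):
        cds, hc = self._trees()
        missense_only = toy_variants[toy_variants["consequence"] == "missense_variant"]
        qs = build_qualifying_sets(
            missense_only, {"v1": 3, "v3": 40}, QualifyingConfig(), "lof", cds, hc
        )
        assert "G1" not in qs.genes

    def test_non_pass_records_dropped(self, toy_variants):
        cds, hc = self._trees()
        v = toy_variants.copy()
        v["filter"] = ["PASS", "LowQual", "PASS"]
        qs = build_qualifying_sets(
            v, {"v1": 3, "v2": 1, "v3": 40}, QualifyingConfig(), "coding", cds, hc
        )
        assert qs.genes == {}

    def test_deterministic_and_ordered(self, small_cohort):
        qs1 = small_cohort["qualifying"]
        qs2 = build_qualifying_sets(
            small_cohort["pool"],
            small_cohort["genotypes"].allele_counts(),
            QualifyingConfig(),
            "coding",
            small_cohort["cds"],
            small_cohort["hc"],
        )
        assert qs1.genes == qs2.genes
        assert qs1.singleton == qs2.singleton

    def test_lof_subset_of_coding(self, small_cohort):
        qs_lof = build_qualifying_sets(
            small_cohort["pool"],
            small_cohort["genotypes"].allele_counts(),
            QualifyingConfig(),
            "lof",
            small_cohort["cds"],
            small_cohort["hc"],
        )
        coding = small_cohort["qualifying"].genes
        for gene, ids in qs_lof.genes.items():
            assert set(ids) <= set(coding.get(gene, []))

    @pytest.mark.parametrize("tighter, looser", [(5e-4, 1e-3), (1e-4, 1e-3)])
    def test_maf_monotonicity(self, small_cohort, tighter, looser):
        """Lowering the MAF cutoff never adds a variant to any qualifying set."""
        args = (
            small_cohort["pool"],
            small_cohort["genotypes"].allele_counts(),
        )
        trees = (small_cohort["cds"], small_cohort["hc"])
        qs_loose = build_qualifying_sets(
            *args, QualifyingConfig(maf_cutoff=looser), "coding", *trees
        )
        qs_tight = build_qualifying_sets(
            *args, QualifyingConfig(maf_cutoff=tighter), "coding", *trees
        )
        for gene, ids in qs_tight.genes.items():
            assert set(ids) <= set(qs_loose.genes.get(gene, []))

    def test_invalid_model_raises(self, toy_variants):
        cds, hc = self._trees()
        with pytest.raises(ConfigError):
            build_qualifying_sets(toy_variants, {}, QualifyingConfig(), "skat", cds, hc)


def test_config_validation():
    with pytest.raises(ConfigError):
        QualifyingConfig(maf_cutoff=0.0)
    with pytest.raises(ConfigError):
        QualifyingConfig(benign_rule="sometimes")
    with pytest.raises(ConfigError):
        QualifyingConfig(lof_terms=frozenset({"weird_term"}))
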