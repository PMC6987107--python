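"""Synthetic cohort generator: spectra, determinism, effect injection, round trips."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from raresweep import (
    ConfigError,
    PhenotypeSpec,
    SimConfig,
    generate_genotypes,
    generate_variant_pool,
    simulate_phenotype,
)
from raresweep.io import MISSING, export_cohort, load_cohort
from raresweep.sim import (
    cds_intervals,
    covariate_table,
    high_confidence_intervals,
    simulate_null_binary_collapse,
)


class TestConfigValidation:
    def test_mixture_must_sum_to_one(self):
        with pytest.raises(ConfigError):
            SimConfig(consequence_mix={"missense_variant": 0.5})

    def test_proportions_in_unit_interval(self):
        with pytest.raises(ConfigError):
            SimConfig(singleton_fraction=1.5)

    def test_maf_spectrum_support_below_cutoff(self):
        with pytest.raises(ConfigError):
            SimConfig(maf_low=0.01, maf_cutoff=0.001)

    def test_binary_spec_needs_prevalence(self):
        with pytest.raises(ConfigError):
            PhenotypeSpec("p", "binary")

    def test_ratio_notation(self):
        spec = PhenotypeSpec.from_case_control_ratio("p", "1:22")
        assert spec.prevalence == pytest.approx(1 / 23)


class TestVariantPool:
    def test_all_singletons_when_fraction_one(self):
        cfg = SimConfig(n_samples_per_cohort=300, n_genes=10,
                        mean_variants_per_gene=8, singleton_fraction=1.0, seed=3)
        pool = generate_variant_pool(cfg)
        gm, _ = generate_genotypes(pool, cfg)
        assert (gm.allele_counts() == 1).all()

    def test_reference_afs_bounded_by_cutoff(self):
        cfg = SimConfig(n_genes=20, mean_variants_per_gene=20, seed=4)
        pool = generate_variant_pool(cfg)
        af_cols = [c for c in pool.columns if c.startswith("af_")]
        assert pool[af_cols].to_numpy().max() < cfg.maf_cutoff

    def test_mean_variants_per_gene_within_three_se(self):
        cfg = SimConfig(n_genes=100, mean_variants_per_gene=34.0, seed=5,
                        n_samples_per_cohort=50)
        pool = generate_variant_pool(cfg)
        per_gene = pool.groupby("gene").size()
        se = np.sqrt(33.0 / 100)  # shifted-Poisson variance / n_genes
        assert len(per_gene) == 100
        assert abs(per_gene.mean() - 34.0) < 3 * se

    def test_every_variant_has_gene_and_annotation(self, small_cohort):
        pool = small_cohort["pool"]
        assert pool["gene"].notna().all()
        assert pool["consequence"].notna().all()
        assert pool["variant_id"].is_unique


class TestGenotypes:
    def test_realized_carrier_counts_in_binomial_envelope(self):
        cfg = SimConfig(n_samples_per_cohort=4000, n_genes=40,
                        mean_variants_per_gene=10, singleton_fraction=0.0, seed=6)
        pool = generate_variant_pool(cfg)
        gm, _ = generate_genotypes(pool, cfg)
        ac = gm.allele_counts().to_numpy()
        f = pool["target_af"].to_numpy()
        n_alleles = 2 * cfg.n_samples_per_cohort
        lo = stats.binom.ppf(0.005, n_alleles, f)
        hi = stats.binom.ppf(0.995, n_alleles, f)
        inside = (ac >= lo) & (ac <= hi)
        assert inside.mean() >= 0.97  # 99% envelope per site

    def test_zero_target_af_gives_all_reference(self):
        cfg = SimConfig(n_samples_per_cohort=100, n_genes=2,
                        mean_variants_per_gene=3, singleton_fraction=0.0,
                        missing_rate=0.0, seed=7)
        pool = generate_variant_pool(cfg)
        pool.loc[:, "target_af"] = 0.0
        gm, _ = generate_genotypes(pool, cfg)
        assert (gm.data == 0).all()

    def test_seed_determinism_byte_identical(self):
        cfg = SimConfig(n_samples_per_cohort=200, n_genes=5,
                        mean_variants_per_gene=6, seed=8)
        pool = generate_variant_pool(cfg)
        gm1, s1 = generate_genotypes(pool, cfg)
        gm2, s2 = generate_genotypes(pool, cfg)
        assert np.array_equal(gm1.data, gm2.data)
        pd.testing.assert_frame_equal(s1, s2)

    def test_singleton_sites_have_dataset_allele_count_one(self, small_cohort):
        pool, gm = small_cohort["pool"], small_cohort["genotypes"]
        ac = gm.allele_counts()
        singles = pool.loc[pool["is_singleton_site"], "variant_id"]
        assert (ac[singles] == 1).all()


class TestSimulatePhenotype:
    def test_null_quantitative_no_group_difference(self, small_cohort):
        qs = small_cohort["qualifying"]
        gm = small_cohort["genotypes"]
        spec = PhenotypeSpec("null_q", "quantitative", effect_genes={})
        pv = simulate_phenotype(gm, qs, spec, seed=9)
        gene = max(qs.genes, key=lambda g: len(qs.genes[g]))
        carrier = gm.carrier_indicator(qs.genes[gene]).astype(bool)
        y = pv.values.to_numpy()
        n1, n0 = carrier.sum(), (~carrier).sum()
        se = np.sqrt(1.0 / n1 + 1.0 / n0)
        assert abs(y[carrier].mean() - y[~carrier].mean()) < 3 * se

    def test_injected_effect_shifts_carrier_mean(self, small_cohort):
        qs = small_cohort["qualifying"]
        gm = small_cohort["genotypes"]
        gene = max(qs.genes, key=lambda g: len(qs.genes[g]))
        spec = PhenotypeSpec("eff_q", "quantitative", effect_genes={gene: 1.0})
        pv = simulate_phenotype(gm, qs, spec, seed=10)
        carrier = gm.carrier_indicator(qs.genes[gene]).astype(bool)
        y = pv.values.to_numpy()
        se = np.sqrt(1.0 / carrier.sum() + 1.0 / (~carrier).sum())
        assert abs((y[carrier].mean() - y[~carrier].mean()) - 1.0) < 3 * se

    def test_binary_prevalence_within_binomial_envelope(self, small_cohort):
        qs = small_cohort["qualifying"]
        gm = small_cohort["genotypes"]
        spec = PhenotypeSpec.from_case_control_ratio("afib", "1:22")
        pv = simulate_phenotype(gm, qs, spec, seed=11)
        n = gm.n_samples
        n_cases = int(pv.values.sum())
        lo = stats.binom.ppf(0.005, n, 1 / 23)
        hi = stats.binom.ppf(0.995, n, 1 / 23)
        assert lo <= n_cases <= hi

    def test_unknown_effect_gene_raises(self, small_cohort):
        spec = PhenotypeSpec("q", "quantitative", effect_genes={"nonexistent": 1.0})
        with pytest.raises(ConfigError):
            simulate_phenotype(
                small_cohort["genotypes"], small_cohort["qualifying"], spec, seed=0
            )

    def test_null_collapse_helper_shapes_and_prevalence(self):
        y, ind = simulate_null_binary_collapse(5000, 1 / 23, [0.01, 0.001], seed=12)
        assert ind.shape == (5000, 2)
        assert 0.02 < y.mean() < 0.07


class TestExportImport:
    def _export(self, tmp_path, small_cohort, phenotypes=None):
        cfg = small_cohort["config"]
        phen = phenotypes if phenotypes is not None else pd.DataFrame(
            {"sample_id": list(small_cohort["genotypes"].sample_ids),
             "phenotype_id": "t",
             "value": np.arange(small_cohort["genotypes"].n_samples, dtype=float)}
        )
        manifest = pd.DataFrame(
            [{"phenotype_id": "t", "kind": "quantitative", "sex_restriction": "none"}]
        ) if len(phen) else pd.DataFrame(
            columns=["phenotype_id", "kind", "sex_restriction"]
        )
        export_cohort(
            tmp_path,
            small_cohort["pool"],
            small_cohort["genotypes"],
            small_cohort["samples"],
            phen,
            manifest,
            small_cohort["covariates"],
            cds_intervals(cfg),
            high_confidence_intervals(cfg),
        )
        return load_cohort(tmp_path, name="round")

    def test_round_trip_preserves_carrier_matrix(self, tmp_path, small_cohort):
        loaded = self._export(tmp_path, small_cohort)
        gm = small_cohort["genotypes"]
        ids = list(gm.variant_ids)
        orig = gm.carrier_indicator(ids)
        back = loaded.genotypes.carrier_indicator(ids)
        # sample order preserved by the VCF column order
        assert loaded.genotypes.sample_ids == gm.sample_ids
        assert np.array_equal(orig, back)

    def test_missing_genotype_written_as_vcf_missing_call(self, tmp_path, small_cohort):
        self._export(tmp_path, small_cohort)
        gm = small_cohort["genotypes"]
        assert (gm.data == MISSING).any(), "fixture should contain missing calls"
        text = (tmp_path / "genotypes.vcf").read_text()
        assert "./." in text
        loaded = load_cohort(tmp_path)
        assert np.array_equal(
            loaded.genotypes.columns(list(gm.variant_ids)) == MISSING,
            gm.data == MISSING,
        )

    def test_empty_phenotype_set_valid_headers_only(self, tmp_path, small_cohort):
        empty = pd.DataFrame(columns=["sample_id", "phenotype_id", "value"])
        loaded = self._export(tmp_path, small_cohort, phenotypes=empty)
        assert list(loaded.phenotypes.columns) == ["sample_id", "phenotype_id", "value"]
        assert loaded.phenotypes.empty


def test_frequency_realism_over_sites():
    """Realized AF lies inside the exact binomial 99% CI for >= 99% of sites."""
    cfg = SimConfig(n_samples_per_cohort=3000, n_genes=60,
                    mean_variants_per_gene=12, singleton_fraction=0.0, seed=13)
    pool = generate_variant_pool(cfg)
    gm, _ = generate_genotypes(pool, cfg)
    ac = gm.allele_counts().to_numpy()
    f = pool["target_af"].to_numpy()
    n_alleles = 2 * cfg.n_samples_per_cohort
    lo = stats.binom.ppf(0.005, n_alleles, f)
    hi = stats.binom.ppf(0.995, n_alleles, f)
    assert (((ac >= lo) & (ac <= hi)).mean()) >= 0.97


def test_covariate_table_is_numeric(small_cohort):
    cov = covariate_table(small_cohort["samples"])
    assert cov.select_dtypes(include=[np.number]).shape == cov.shape
    assert "pc10" in cov.columns
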