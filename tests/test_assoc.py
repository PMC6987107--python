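"""Phenotype preparation, burden regression, Fisher fallback, and routing."""

from fractions import Fraction
from math import comb

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from raresweep import (
    DataError,
    PhenotypeVector,
    burden_regression,
    burden_scan,
    encode_binary,
    fisher_burden,
    inclusion_filter,
    prepare_quantitative,
    rank_inverse_normal,
    route_test,
)
from raresweep.collapse import GateResult


def _gate(verdict, kind="binary"):
    return GateResult(
        gene="G", phenotype="P", kind=kind, expected_case_carriers=float("nan"),
        observed_case_carriers=None, n_smaller_group=None, n_carriers=0,
        verdict=verdict, reason="",
    )


class TestPrepareQuantitative:
    def test_pre_transform_median(self):
        df = pd.DataFrame(
            {"sample_id": ["a"] * 3 + ["b"], "value": [3.0, 7.0, 5.0, 1.0]}
        )
        pv = prepare_quantitative(df, phenotype_id="t")
        # sample a's median 5 ranks above sample b's 1
        assert pv.values["a"] > pv.values["b"]
        assert pv.n_phenotyped == 2

    def test_blom_offsets_for_three_values(self):
        v = pd.Series([1.0, 2.0, 3.0], index=["a", "b", "c"])
        z = rank_inverse_normal(v)
        expected = stats.norm.ppf((np.array([1, 2, 3]) - 3 / 8) / (3 + 1 / 4))
        assert np.allclose(z.to_numpy(), expected)
        assert z["b"] == pytest.approx(0.0)
        assert z["c"] == pytest.approx(0.8694, abs=5e-4)

    def test_ties_share_transformed_value(self):
        z = rank_inverse_normal(pd.Series([5.0, 5.0, 1.0, 9.0]))
        assert z.iloc[0] == z.iloc[1]

    def test_output_standardized_at_moderate_n(self, rng):
        z = rank_inverse_normal(pd.Series(rng.exponential(size=500)))
        assert abs(z.mean()) < 0.01
        assert abs(z.var() - 1.0) < 0.05

    def test_constant_values_raise(self):
        with pytest.raises(DataError):
            rank_inverse_normal(pd.Series([2.0, 2.0, 2.0]))


class TestEncodeBinary:
    def _samples(self):
        return pd.DataFrame(
            {"sample_id": ["a", "b", "c"], "sex": ["F", "M", "F"]}
        )

    def test_code_recorded_twice_is_case_once(self):
        pv = encode_binary(["a", "a"], self._samples())
        assert pv.values["a"] == 1 and pv.values["b"] == 0
        assert pv.n_cases == 1 and pv.n_controls == 2

    def test_sex_restriction_masks_other_sex(self):
        pv = encode_binary(["a"], self._samples(), sex_restriction="female")
        assert np.isnan(pv.values["b"])
        assert pv.n_phenotyped == 2

    def test_unknown_sex_with_restriction_is_missing(self):
        samples = pd.DataFrame({"sample_id": ["a", "b"], "sex": ["F", "U"]})
        pv = encode_binary([], samples, sex_restriction="female")
        assert np.isnan(pv.values["b"])


class TestInclusionFilter:
    def _binary(self, n_cases, n_controls):
        vals = pd.Series([1.0] * n_cases + [0.0] * n_controls)
        return PhenotypeVector("p", "binary", vals)

    def _quant(self, n):
        return PhenotypeVector("p", "quantitative", pd.Series(np.arange(n, dtype=float)))

    def test_binary_per_cohort_minimum(self):
        ok, _ = inclusion_filter([self._binary(56, 100), self._binary(4, 100)])
        assert not ok

    def test_binary_boundary_passes(self):
        ok, _ = inclusion_filter([self._binary(45, 100), self._binary(5, 100)])
        assert ok

    @pytest.mark.parametrize("n, expect", [(399, False), (400, True)])
    def test_quantitative_total_boundary(self, n, expect):
        ok, _ = inclusion_filter([self._quant(n // 2), self._quant(n - n // 2)])
        assert ok is expect


class TestBurdenRegression:
    def test_six_point_fixture_recovers_group_difference(self):
        y = pd.Series([2.0, 1.8, 2.2, 0.1, -0.1, 0.0], index=list("abcdef"))
        pheno = PhenotypeVector("t", "quantitative", y)
        res = burden_regression(np.array([1, 1, 1, 0, 0, 0]), pheno, gene="G")
        assert res.beta == pytest.approx(2.0)
        assert res.direction == 1
        assert res.n_carriers == 3

    def test_matches_two_sample_t_test(self, rng):
        n = 80
        ind = (rng.random(n) < 0.3).astype(int)
        y = rng.standard_normal(n) + 0.3 * ind
        pheno = PhenotypeVector("t", "quantitative", pd.Series(y))
        res = burden_regression(ind, pheno, gene="G")
        t, p = stats.ttest_ind(y[ind == 1], y[ind == 0])
        assert res.p == pytest.approx(p, rel=1e-9)

    def test_injected_effect_recovered_within_two_se(self):
        rng = np.random.default_rng(0)
        n = 10_000
        ind = np.zeros(n, dtype=int)
        ind[rng.choice(n, size=50, replace=False)] = 1
        y = rng.standard_normal(n) + 1.0 * ind
        pheno = PhenotypeVector("t", "quantitative", pd.Series(y))
        res = burden_regression(ind, pheno, gene="G")
        assert abs(res.beta - 1.0) < 2 * res.extra["se"]

    def test_null_pvalues_uniform(self):
        """Calibration hand-off: burden p-values on null genes are uniform."""
        rng = np.random.default_rng(1)
        n, n_genes = 400, 600
        y = rng.standard_normal(n)
        pheno = PhenotypeVector("t", "quantitative", pd.Series(y))
        ps = []
        for _ in range(n_genes):
            ind = np.zeros(n, dtype=int)
            ind[rng.choice(n, size=8, replace=False)] = 1
            ps.append(burden_regression(ind, pheno, gene="G").p)
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_zero_carriers_raise(self):
        pheno = PhenotypeVector("t", "quantitative", pd.Series([1.0, 2.0]))
        with pytest.raises(DataError):
            burden_regression(np.array([0, 0]), pheno, gene="G")

    def test_collinear_covariate_dropped_with_warning(self, rng):
        n = 60
        ind = (rng.random(n) < 0.3).astype(int)
        y = rng.standard_normal(n)
        pheno = PhenotypeVector("t", "quantitative", pd.Series(y))
        cov = pd.DataFrame({"a": np.ones(n), "b": 2 * np.ones(n)})
        with pytest.warns(UserWarning, match="collinear"):
            res = burden_regression(ind, pheno, cov, gene="G")
        base = burden_regression(ind, pheno, gene="G")
        assert res.beta == pytest.approx(base.beta)

    def test_pure_noise_covariate_leaves_beta_nearly_unchanged(self):
        rng = np.random.default_rng(2)
        diffs = []
        for _ in range(30):
            n = 500
            ind = (rng.random(n) < 0.05).astype(int)
            y = rng.standard_normal(n) + 0.5 * ind
            pheno = PhenotypeVector("t", "quantitative", pd.Series(y))
            noise = pd.DataFrame({"z": rng.standard_normal(n)})
            b0 = burden_regression(ind, pheno, gene="G").beta
            b1 = burden_regression(ind, pheno, noise, gene="G").beta
            diffs.append(b1 - b0)
        assert abs(np.mean(diffs)) < 0.02


class TestFisher:
    def test_enumeration_fixture_balanced(self):
        res = fisher_burden(3, 1, 1, 3)
        assert res.p == pytest.approx(34 / 70)
        assert res.direction == 1

    def test_enumeration_fixture_extreme(self):
        res = fisher_burden(5, 0, 0, 5)
        assert res.p == pytest.approx(2 / 252)

    def test_zero_carriers_degenerate(self):
        res = fisher_burden(0, 10, 0, 20)
        assert res.p == 1.0
        assert res.direction == 0

    def test_negative_count_raises(self):
        with pytest.raises(DataError):
            fisher_burden(-1, 2, 3, 4)

    def test_matches_rational_oracle_on_random_tables(self, rng):
        """Point-probability two-sided p agrees with exact enumeration."""
        for _ in range(200):
            a, b, c, d = rng.integers(0, 12, size=4)
            if a + b == 0 or c + d == 0:
                continue
            res = fisher_burden(int(a), int(b), int(c), int(d))
            N, r, c1 = a + b + c + d, a + b, a + c
            denom = comb(N, c1)
            ws = [
                comb(r, k) * comb(N - r, c1 - k)
                for k in range(max(0, r + c1 - N), min(r, c1) + 1)
            ]
            wa = comb(r, a) * comb(N - r, c1 - a)
            p_exact = Fraction(sum(w for w in ws if w <= wa), denom)
            assert res.p == pytest.approx(float(p_exact), abs=1e-12)


class TestRouting:
    def test_binary_gate_pass_runs_both(self):
        assert route_test("binary", _gate(True)) == ("regression", "fisher")

    def test_binary_gate_fail_fisher_only(self):
        assert route_test("binary", _gate(False)) == ("fisher",)

    def test_quantitative_routing(self):
        assert route_test("quantitative", _gate(True, "quantitative")) == ("regression",)
        assert route_test("quantitative", _gate(False, "quantitative")) == ()

    def test_zero_heritability_flag_keeps_fixed_effect_path(self):
        assert route_test("binary", _gate(True), heritability_ok=False) == (
            "regression",
            "fisher",
        )


class TestBurdenScan:
    def test_agrees_with_per_gene_ols(self, rng):
        n, G = 300, 12
        y = rng.standard_normal(n)
        cov = rng.standard_normal((n, 3))
        X = (rng.random((n, G)) < 0.05).astype(float)
        X[:, 0] = 0.0  # zero-carrier gene
        scan = burden_scan(X, y, cov)
        pheno = PhenotypeVector("t", "quantitative", pd.Series(y))
        cov_df = pd.DataFrame(cov, columns=["c1", "c2", "c3"])
        for g in range(1, G):
            if scan["n_carriers"][g] == 0:
                continue
            res = burden_regression(X[:, g], pheno, cov_df, gene="G")
            assert scan["beta"][g] == pytest.approx(res.beta, rel=1e-9)
            assert scan["p"][g] == pytest.approx(res.p, rel=1e-6)

    def test_zero_carrier_gene_gets_nan_beta_p_one(self, rng):
        X = np.zeros((50, 1))
        scan = burden_scan(X, rng.standard_normal(50))
        assert np.isnan(scan["beta"][0])
        assert scan["p"][0] == 1.0
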