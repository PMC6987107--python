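"""Calibration experiments for the collapsing pipeline.

Self-contained simulation studies that exercise the pipeline's statistical
guarantees at the collapsed scale: the inflation-control behavior of the
expected-carrier gate under severe case:control imbalance, type-I error and
effect-size recovery of the gated burden regression, and the behavior of
singleton-removal and lead-variant conditioning on constructed signals.
These back the test suite and the reproduction script; each function returns
a plain dict of measured quantities.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .assoc import PhenotypeVector, burden_regression, burden_scan, fisher_burden
from .collapse import expected_case_carriers
from .diagnostics import genomic_lambda, tail_excess
from .io import GenotypeMatrix
from .sim import log_uniform, simulate_null_binary_collapse
from .varlevel import (
    VariantEffect,
    conditional_gene_test,
    select_lead_variant,
    singleton_sensitivity,
)


def _simple_covariates(n: int, rng) -> np.ndarray:
    """Age, sex and 10 PC-like columns, as the burden tests would adjust for."""
    return np.column_stack(
        [
            rng.uniform(40, 70, n),
            (rng.random(n) < 0.55).astype(float),
            rng.standard_normal((n, 10)),
        ]
    )


def inflation_experiment(
    n_samples: int = 20_000,
    prevalence: float = 1 / 23,
    n_genes: int = 2_000,
    carrier_freq_range: tuple = (5e-5, 5e-3),
    min_expected: float = 10.0,
    tail_threshold: float = 1e-4,
    seed: int = 0,
    chunk: int = 250,
) -> dict:
    """Null binary trait under case:control imbalance: gated vs ungated calibration.

    Simulates one null binary trait and per-gene carrier indicators with
    log-uniform carrier frequencies, then measures the genomic inflation
    lambda and the tail excess (p < ``tail_threshold``) of three analyses:
    the ungated burden regression over all genes with >= 1 carrier, the same
    regression restricted to genes passing the expected-carrier gate
    (lambda is NaN when no gene passes), and the Fisher's exact fallback
    over all genes.
    """
    rng = np.random.default_rng([seed, 10])
    cf = log_uniform(*carrier_freq_range, n_genes, seed=seed)
    y, indicators = simulate_null_binary_collapse(n_samples, prevalence, cf, seed=seed)
    n_cases = int(y.sum())
    n_smaller = min(n_cases, n_samples - n_cases)
    cov = _simple_covariates(n_samples, rng)

    parts = []
    for j0 in range(0, n_genes, chunk):
        parts.append(burden_scan(indicators[:, j0 : j0 + chunk], y, cov))
    scan = pd.concat(parts, ignore_index=True)

    cf_hat = indicators.mean(axis=0)
    expected = np.array([expected_case_carriers(f, n_smaller) for f in cf_hat])
    gated = expected >= min_expected
    tested = scan["n_carriers"].to_numpy() > 0

    p_fisher = np.empty(n_genes)
    for g in range(n_genes):
        carriers = indicators[:, g] > 0
        a = int((carriers & (y == 1)).sum())
        c = int(carriers.sum()) - a
        p_fisher[g] = fisher_burden(a, n_cases - a, c, (n_samples - n_cases) - c).p

    p_reg = scan["p"].to_numpy()
    out = {
        "n_cases": n_cases,
        "n_tested_ungated": int(tested.sum()),
        "n_gated": int(gated.sum()),
        "lambda_ungated": genomic_lambda(p_reg[tested]),
        "lambda_gated": (
            genomic_lambda(p_reg[gated & tested]) if (gated & tested).any() else float("nan")
        ),
        "lambda_fisher": genomic_lambda(p_fisher),
    }
    for label, p in (
        ("ungated", p_reg[tested]),
        ("gated", p_reg[gated & tested] if (gated & tested).any() else None),
        ("fisher", p_fisher),
    ):
        if p is None:
            out[f"tail_observed_{label}"], out[f"tail_expected_{label}"] = 0, 0.0
        else:
            obs, exp = tail_excess(p, tail_threshold)
            out[f"tail_observed_{label}"], out[f"tail_expected_{label}"] = obs, exp
    return out


def beta_recovery_experiment(
    n_samples: int = 10_000,
    n_carriers: int = 50,
    beta: float = 1.0,
    n_replicates: int = 200,
    seed: int = 0,
) -> dict:
    """How often the injected burden effect is recovered within 2 SE."""
    rng = np.random.default_rng([seed, 11])
    hits = 0
    estimates = []
    for _ in range(n_replicates):
        x = np.zeros(n_samples)
        x[rng.choice(n_samples, size=n_carriers, replace=False)] = 1.0
        y = rng.standard_normal(n_samples) + beta * x
        fit = burden_scan(x[:, None], y)
        b, se = float(fit["beta"][0]), float(fit["se"][0])
        estimates.append(b)
        hits += abs(b - beta) <= 2 * se
    return {
        "recovery_rate": hits / n_replicates,
        "mean_estimate": float(np.mean(estimates)),
        "n_replicates": n_replicates,
    }


def type1_error_experiment(
    n_samples: int = 2_000,
    n_genes: int = 4_000,
    carrier_freq_range: tuple = (5e-3, 5e-2),
    alpha: float = 0.05,
    min_carriers: int = 5,
    seed: int = 0,
    chunk: int = 500,
) -> dict:
    """Type-I error of the gated quantitative burden regression at nominal alpha."""
    rng = np.random.default_rng([seed, 12])
    cf = log_uniform(*carrier_freq_range, n_genes, seed=seed + 1)
    y = rng.standard_normal(n_samples)
    cov = _simple_covariates(n_samples, rng)
    indicators = (rng.random((n_samples, n_genes)) < cf[None, :]).astype(np.int8)
    parts = []
    for j0 in range(0, n_genes, chunk):
        parts.append(burden_scan(indicators[:, j0 : j0 + chunk], y, cov))
    scan = pd.concat(parts, ignore_index=True)
    gated = scan["n_carriers"].to_numpy() >= min_carriers
    p = scan["p"].to_numpy()[gated]
    return {
        "type1_rate": float((p < alpha).mean()),
        "n_gated": int(gated.sum()),
        "alpha": alpha,
    }


def _effect_gene_fixture(
    n_samples: int,
    singleton_carriers: int,
    recurrent_carriers: int,
    beta: float,
    rng,
    null_singletons: int = 0,
):
    """A gene of singleton variants plus one recurrent variant, with a burden effect.

    Returns ``(gm, variant_ids, singleton_flags, pheno)``. The effect applies
    to carriers of any causal variant; ``null_singletons`` extra singleton
    variants carry no effect (their carriers are ordinary samples).
    """
    cols = []
    flags = {}
    vids = []
    causal = np.zeros(n_samples, dtype=bool)
    pick = rng.choice(
        n_samples, size=singleton_carriers + recurrent_carriers + null_singletons, replace=False
    )
    k = 0
    for i in range(singleton_carriers):
        col = np.zeros(n_samples, dtype=np.int8)
        col[pick[k]] = 1
        causal[pick[k]] = True
        k += 1
        vid = f"s{i}"
        cols.append(col); vids.append(vid); flags[vid] = True
    if recurrent_carriers:
        col = np.zeros(n_samples, dtype=np.int8)
        idx = pick[k : k + recurrent_carriers]
        col[idx] = 1
        causal[idx] = True
        k += recurrent_carriers
        cols.append(col); vids.append("lead"); flags["lead"] = False
    for i in range(null_singletons):
        col = np.zeros(n_samples, dtype=np.int8)
        col[pick[k]] = 1
        k += 1
        vid = f"n{i}"
        cols.append(col); vids.append(vid); flags[vid] = True
    y = rng.standard_normal(n_samples) + beta * causal
    gm = GenotypeMatrix(
        data=np.column_stack(cols),
        sample_ids=tuple(f"s{i:05d}" for i in range(n_samples)),
        variant_ids=tuple(vids),
    )
    pheno = PhenotypeVector(
        "trait", "quantitative", pd.Series(y, index=list(gm.sample_ids))
    )
    return gm, vids, flags, pheno


def singleton_and_conditioning_experiment(
    n_samples: int = 4_000,
    beta: float = 1.8,
    seed: int = 0,
) -> dict:
    """Constructed signals probing singleton removal and lead-variant conditioning.

    Three genes: (a) a signal carried mostly (>= 80%) by singletons, re-tested
    without them; (b) a gene whose entire signal is one recurrent variant
    (plus a few null singletons), conditioned on its lead; (c) a signal
    spread over 20 singletons plus a recurrent lead, conditioned on the lead.
    """
    rng = np.random.default_rng([seed, 13])
    out = {}

    # (a) singleton-dominated signal: 21 of 25 carriers via singletons
    gm, vids, flags, pheno = _effect_gene_fixture(n_samples, 21, 4, beta, rng)
    sens = singleton_sensitivity(gm, vids, flags, pheno, gene="A")
    out["singleton_p_with"] = sens["p_with"]
    out["singleton_p_without"] = sens["p_without"]
    out["singleton_orders_worse"] = float(
        np.log10(sens["p_without"]) - np.log10(sens["p_with"])
    )

    # (b) single-recurrent-variant gene: 12 causal carriers on one variant
    gm, vids, flags, pheno = _effect_gene_fixture(
        n_samples, 0, 12, beta, rng, null_singletons=3
    )
    effects = _variant_effects(gm, vids, flags, pheno)
    lead = select_lead_variant(effects)
    assert lead == "lead"
    cond = conditional_gene_test(
        gm.carrier_indicator(vids), gm.column(lead), pheno,
        sample_ids=gm.sample_ids, gene="B",
    )
    out["recurrent_conditional_p"] = cond.p

    # (c) distributed signal: 20 causal singletons + one causal lead
    gm, vids, flags, pheno = _effect_gene_fixture(n_samples, 20, 8, beta, rng)
    effects = _variant_effects(gm, vids, flags, pheno)
    lead = select_lead_variant(effects)
    cond = conditional_gene_test(
        gm.carrier_indicator(vids), gm.column(lead), pheno,
        sample_ids=gm.sample_ids, gene="C",
    )
    out["distributed_conditional_p"] = cond.p
    out["distributed_lead"] = lead
    return out


def _variant_effects(gm, vids, flags, pheno):
    effects = []
    for j, vid in enumerate(vids):
        res = burden_regression(
            gm.column(vid), pheno, sample_ids=gm.sample_ids, gene="G"
        )
        effects.append(
            VariantEffect(
                variant_id=vid, gene="G", n_carriers=res.n_carriers,
                beta=res.beta, p=res.p, direction=res.direction, pos=j,
                singleton=flags[vid],
            )
        )
    return effects
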