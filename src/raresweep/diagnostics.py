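"""Inflation diagnostics and multiple-testing machinery.

The genomic inflation factor lambda is the median association chi-square
(one degree of freedom) divided by its null median 0.45494; lambda near 1
indicates a calibrated test. Because collapsing tests of rare binary traits
produce strongly discrete statistics, the median can understate tail
pathology, so a tail-excess count (observed vs expected p-values below a
small threshold) is reported alongside lambda.

Significance calling uses a Bonferroni threshold over genes x phenotypes x
models: alpha / ((n_coding_genes + n_lof_genes) * n_phenotypes).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import ConfigError, DataError

#: Median of the chi-square distribution with 1 degree of freedom.
CHI2_1_MEDIAN = float(stats.chi2.ppf(0.5, 1))


@dataclass
class InflationReport:
    label: str
    n_tests: int
    lam: float
    qq: np.ndarray  # (n, 2): expected and observed -log10 p
    tail_threshold: float = 1e-4
    tail_observed: int = 0
    tail_expected: float = 0.0


@dataclass
class SignificanceConfig:
    alpha: float = 0.05
    n_coding_genes: int = 1
    n_lof_genes: int = 0
    n_phenotypes: int = 1

    def __post_init__(self):
        if not (0.0 < self.alpha < 1.0):
            raise ConfigError(f"alpha must lie in (0, 1), got {self.alpha}")
        if self.n_coding_genes + self.n_lof_genes < 1 or self.n_phenotypes < 1:
            raise ConfigError("gene and phenotype counts must be positive")


def _validate_pvalues(pvalues) -> np.ndarray:
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise DataError("empty p-value array")
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise DataError("p-values must lie in [0, 1]")
    if np.any(p == 0):
        warnings.warn("p-values of exactly 0 clamped to smallest representable value")
        p = np.maximum(p, np.finfo(float).tiny)
    return p


def genomic_lambda(pvalues) -> float:
    """Median-based genomic inflation factor of 1-df association p-values."""
    p = _validate_pvalues(pvalues)
    return float(np.median(stats.chi2.isf(p, 1)) / CHI2_1_MEDIAN)


def qq_points(pvalues) -> np.ndarray:
    """QQ coordinates: sorted observed -log10 p against -log10(i / (n + 1))."""
    p = _validate_pvalues(pvalues)
    obs = -np.log10(np.sort(p))  # descending in -log10, smallest p first
    n = p.size
    exp = -np.log10(np.arange(1, n + 1) / (n + 1.0))
    return np.column_stack([exp, obs])


def tail_excess(pvalues, threshold: float = 1e-4) -> tuple[int, float]:
    """Observed vs expected count of p-values below ``threshold`` under the null."""
    p = _validate_pvalues(pvalues)
    return int((p < threshold).sum()), float(threshold * p.size)


def inflation_report(pvalues, label: str = "", tail_threshold: float = 1e-4) -> InflationReport:
    p = _validate_pvalues(pvalues)
    obs, exp = tail_excess(p, tail_threshold)
    return InflationReport(
        label=label,
        n_tests=p.size,
        lam=genomic_lambda(p),
        qq=qq_points(p),
        tail_threshold=tail_threshold,
        tail_observed=obs,
        tail_expected=exp,
    )


def bonferroni_threshold(cfg: SignificanceConfig) -> float:
    """alpha / ((n_coding_genes + n_lof_genes) * n_phenotypes)."""
    return cfg.alpha / ((cfg.n_coding_genes + cfg.n_lof_genes) * cfg.n_phenotypes)


def call_significant(results, threshold: float):
    """Flag results with p strictly below ``threshold``.

    ``results`` may be association results or meta results; a meta result is
    significant only when its qualification gates all passed. Returns the
    list of ``(result, significant)`` pairs.
    """
    if not (0.0 < threshold < 1.0):
        raise DataError(f"threshold must lie in (0, 1), got {threshold}")
    out = []
    for r in results:
        p = getattr(r, "combined_p", None)
        if p is not None:
            sig = p < threshold and bool(r.qualified)
        else:
            sig = r.p < threshold
        out.append((r, sig))
    return out


def save_qq_plot(report: InflationReport, path) -> None:
    """Export a QQ plot for one analysis (requires matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4, 4))
    ax.plot(report.qq[:, 0], report.qq[:, 1], ".", ms=3)
    lim = max(1.0, report.qq.max())
    ax.plot([0, lim], [0, lim], "k--", lw=0.8)
    ax.set_xlabel("expected $-\\log_{10} p$")
    ax.set_ylabel("observed $-\\log_{10} p$")
    ax.set_title(f"{report.label} (n={report.n_tests}, $\\lambda$={report.lam:.2f})")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
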