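"""Phenotype preparation and per-cohort burden association tests.

Quantitative traits are reduced to one value per sample (pre-transform
median) and rank-inverse-normal transformed (Blom offsets, average ranks for
ties) before regression. Binary traits are coded 1 if the diagnosis code was
ever recorded, with opposite-sex samples set to missing under a sex
restriction.

The burden test regresses the (transformed) phenotype on the gene carrier
indicator plus covariates by ordinary least squares; binary traits use the
same linear-on-{0,1} fit, the fixed-effect analogue of the linear mixed model
used at biobank scale. Gate-failing binary genes fall back to a two-sided
Fisher's exact test (point-probability convention) on the carrier x case 2x2
table, which stays calibrated with arbitrarily few carriers.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .collapse import GateResult
from .errors import DataError

logger = logging.getLogger(__name__)


@dataclass
class PhenotypeVector:
    """One analyzable phenotype: per-sample values with missingness.

    ``values`` is indexed by sample id; missing is NaN. Binary values are
    {0, 1}; quantitative values are the transformed trait.
    """

    phenotype_id: str
    kind: str  # binary | quantitative
    values: pd.Series
    sex_restriction: str = "none"

    @property
    def n_phenotyped(self) -> int:
        return int(self.values.notna().sum())

    @property
    def n_cases(self) -> int:
        if self.kind != "binary":
            raise DataError("n_cases defined for binary phenotypes only")
        return int((self.values == 1).sum())

    @property
    def n_controls(self) -> int:
        if self.kind != "binary":
            raise DataError("n_controls defined for binary phenotypes only")
        return int((self.values == 0).sum())


@dataclass
class AssociationResult:
    gene: str
    model: str
    phenotype: str
    cohort: str
    test: str  # regression | fisher
    beta: float
    p: float
    direction: int
    n: int
    n_carriers: int
    case_carriers: int | None = None
    control_carriers: int | None = None
    gate_verdict: bool | None = None
    extra: dict = field(default_factory=dict)


def rank_inverse_normal(values: pd.Series, offset: float = 3.0 / 8.0) -> pd.Series:
    """Blom rank-based inverse-normal transform over non-missing entries.

    z_i = Phi^{-1}((r_i - c) / (n + 1 - 2c)) with c = 3/8, ties sharing the
    average rank. Raises :class:`DataError` when all values are identical
    (the transform is undefined).
    """
    x = values.dropna()
    if x.nunique() <= 1:
        raise DataError(f"all values identical; rank-inverse-normal transform undefined")
    ranks = stats.rankdata(x.to_numpy(), method="average")
    n = len(x)
    z = stats.norm.ppf((ranks - offset) / (n + 1 - 2 * offset))
    out = pd.Series(np.nan, index=values.index, dtype=float)
    out.loc[x.index] = z
    return out


def prepare_quantitative(
    measurements: pd.DataFrame,
    phenotype_id: str = "",
    sample_col: str = "sample_id",
    value_col: str = "value",
) -> PhenotypeVector:
    """Median-then-transform preparation of a quantitative trait.

    ``measurements`` holds one row per measurement (a sample may appear
    several times); the per-sample median of the raw values is taken first,
    and the rank-inverse-normal transform is applied to the medians.
    """
    med = measurements.groupby(sample_col)[value_col].median()
    transformed = rank_inverse_normal(med)
    return PhenotypeVector(phenotype_id=phenotype_id, kind="quantitative", values=transformed)


def encode_binary(
    case_samples,
    samples: pd.DataFrame,
    phenotype_id: str = "",
    sex_restriction: str = "none",
    sex_col: str = "sex",
    sample_col: str = "sample_id",
) -> PhenotypeVector:
    """Code a diagnosis phenotype 1/0/missing over a sample table.

    A sample is a case iff its id appears in ``case_samples`` (any number of
    times — a code recorded at least once suffices). Under a sex restriction
    ("female"/"male"), samples of the other sex — and samples with unknown
    sex — are set to missing.
    """
    case_set = set(case_samples)
    idx = samples[sample_col]
    values = pd.Series(
        np.where(idx.isin(case_set), 1.0, 0.0), index=idx.to_numpy(), dtype=float
    )
    if sex_restriction not in ("none", "female", "male"):
        raise DataError(f"unknown sex_restriction {sex_restriction!r}")
    if sex_restriction != "none":
        allowed = {"female": "F", "male": "M"}[sex_restriction]
        sex = samples.set_index(sample_col)[sex_col]
        values[sex.reindex(values.index) != allowed] = np.nan
    return PhenotypeVector(
        phenotype_id=phenotype_id, kind="binary", values=values, sex_restriction=sex_restriction
    )


def inclusion_filter(
    per_cohort: list,
    min_cases_total: int = 50,
    min_cases_per_cohort: int = 5,
    min_quantitative_total: int = 400,
) -> tuple[bool, str]:
    """Phenotype inclusion across cohorts.

    Binary: at least ``min_cases_total`` cases overall with at least
    ``min_cases_per_cohort`` in each cohort. Quantitative: at least
    ``min_quantitative_total`` phenotyped individuals combined.
    """
    kinds = {p.kind for p in per_cohort}
    if len(kinds) != 1:
        raise DataError("mixed phenotype kinds across cohorts")
    kind = kinds.pop()
    if kind == "binary":
        cases = [p.n_cases for p in per_cohort]
        if sum(cases) < min_cases_total:
            return False, f"total cases {sum(cases)} < {min_cases_total}"
        if min(cases) < min_cases_per_cohort:
            return False, f"cohort with {min(cases)} cases < {min_cases_per_cohort}"
        return True, "pass"
    total = sum(p.n_phenotyped for p in per_cohort)
    if total < min_quantitative_total:
        return False, f"phenotyped {total} < {min_quantitative_total}"
    return True, "pass"


# ---------------------------------------------------------------------------
# Tests


def _design_matrix(covariates: pd.DataFrame | None, index) -> pd.DataFrame:
    """Intercept + covariates aligned to ``index``; drops collinear columns."""
    if covariates is None:
        X = pd.DataFrame({"const": 1.0}, index=index)
    else:
        X = covariates.reindex(index).astype(float).copy()
        X.insert(0, "const", 1.0)
    arr = X.to_numpy()
    # Greedy rank check: drop columns that do not increase matrix rank.
    keep = []
    rank = 0
    for j in range(arr.shape[1]):
        r = np.linalg.matrix_rank(arr[:, keep + [j]])
        if r > rank:
            keep.append(j)
            rank = r
        else:
            warnings.warn(f"dropping collinear covariate {X.columns[j]!r}")
    return X.iloc[:, keep]


def burden_regression(
    indicator: np.ndarray,
    pheno: PhenotypeVector,
    covariates: pd.DataFrame | None = None,
    sample_ids=None,
    gene: str = "",
    model: str = "",
    cohort: str = "",
) -> AssociationResult:
    """OLS of the phenotype on the carrier indicator plus covariates.

    The indicator coefficient supplies the effect size (beta) and a two-sided
    p-value. Binary phenotypes are fit with the same linear model on their
    {0,1} coding. Requires at least one carrier among phenotyped samples.
    """
    import statsmodels.api as sm

    values = pheno.values
    if sample_ids is not None:
        ind = pd.Series(np.asarray(indicator, dtype=float), index=list(sample_ids))
    else:
        ind = pd.Series(np.asarray(indicator, dtype=float), index=values.index)
    common = values.dropna().index.intersection(ind.index)
    y = values.loc[common].to_numpy()
    x = ind.loc[common]
    n_carriers = int((x > 0).sum())
    if n_carriers == 0:
        raise DataError(f"gene {gene!r}: zero carriers among phenotyped samples")
    X = _design_matrix(covariates, common)
    X["carrier"] = x
    fit = sm.OLS(y, X.to_numpy()).fit()
    j = X.columns.get_loc("carrier")
    beta = float(fit.params[j])
    p = float(fit.pvalues[j])
    res = AssociationResult(
        gene=gene,
        model=model,
        phenotype=pheno.phenotype_id,
        cohort=cohort,
        test="regression",
        beta=beta,
        p=max(p, np.finfo(float).tiny),
        direction=int(np.sign(beta)),
        n=len(common),
        n_carriers=n_carriers,
        extra={"se": float(fit.bse[j])},
    )
    if pheno.kind == "binary":
        carriers = x > 0
        res.case_carriers = int(((y == 1) & carriers).sum())
        res.control_carriers = int(((y == 0) & carriers).sum())
    return res


def fisher_burden(
    case_carriers: int,
    case_noncarriers: int,
    control_carriers: int,
    control_noncarriers: int,
    gene: str = "",
    model: str = "",
    phenotype: str = "",
    cohort: str = "",
) -> AssociationResult:
    """Two-sided Fisher's exact test on the carrier x case/control 2x2 table.

    Two-sidedness follows the point-probability ("minimum likelihood")
    convention: the p-value sums all tables with point probability no larger
    than the observed table's. The direction comes from the sign of the
    sample odds ratio; degenerate margins give p = 1 and direction 0.
    """
    a, b, c, d = case_carriers, case_noncarriers, control_carriers, control_noncarriers
    if min(a, b, c, d) < 0:
        raise DataError("negative cell count")
    if a + b < 1 or c + d < 1:
        raise DataError("each phenotype group needs at least one sample")
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    cross = a * d - b * c
    direction = 0 if cross == 0 else int(np.sign(cross))
    log_or = np.nan
    if min(a, b, c, d) > 0:
        log_or = float(np.log(a * d / (b * c)))
    return AssociationResult(
        gene=gene,
        model=model,
        phenotype=phenotype,
        cohort=cohort,
        test="fisher",
        beta=log_or,
        p=float(p),
        direction=direction,
        n=a + b + c + d,
        n_carriers=a + c,
        case_carriers=a,
        control_carriers=c,
    )


def route_test(kind: str, gate: GateResult, heritability_ok: bool = True) -> tuple:
    """Which tests to run for one gene x phenotype given its gate verdict.

    Binary traits always receive the Fisher fallback; the regression runs
    only when the expected-carrier gate passes. Quantitative traits run the
    regression when the carrier gate passes and are otherwise excluded. A
    phenotype flagged as zero-heritability (the mixed model cannot be fit)
    routes to the unrelated-samples regression/Fisher path — which is the
    fixed-effect path implemented here, so the plan is unchanged.
    """
    if kind == "binary":
        return ("regression", "fisher") if gate.verdict else ("fisher",)
    if kind == "quantitative":
        return ("regression",) if gate.verdict else ()
    raise DataError(f"unknown phenotype kind {kind!r}")


# ---------------------------------------------------------------------------
# Vectorized scan (Frisch-Waugh residualization)


def burden_scan(
    indicators: np.ndarray,
    y: np.ndarray,
    covariates: np.ndarray | None = None,
) -> pd.DataFrame:
    """OLS burden tests for many genes sharing one phenotype and covariate set.

    ``indicators`` is (n_samples, n_genes). Residualizes the phenotype and
    every indicator on the covariates once (QR), then performs the per-gene
    simple regressions vectorized; algebraically identical to per-gene OLS
    with the covariates included. Genes with zero carriers or a carrier
    column absorbed by the covariates get beta = NaN, p = 1.

    Returns a DataFrame with columns ``beta, se, t, p, n_carriers``.
    """
    y = np.asarray(y, dtype=float)
    n = y.shape[0]
    X = np.asarray(indicators, dtype=float)
    if X.ndim != 2 or X.shape[0] != n:
        raise DataError("indicators must be (n_samples, n_genes)")
    if covariates is None:
        C = np.ones((n, 1))
    else:
        C = np.column_stack([np.ones(n), np.asarray(covariates, dtype=float)])
    Q, _ = np.linalg.qr(C)
    k = np.linalg.matrix_rank(C)
    yr = y - Q @ (Q.T @ y)
    yy = float(yr @ yr)
    n_carriers = (X > 0).sum(axis=0).astype(int)
    Xr = X - Q @ (Q.T @ X)
    xx = np.einsum("ij,ij->j", Xr, Xr)
    xy = Xr.T @ yr
    df = n - k - 1
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = np.where(xx > 1e-12, xy / np.where(xx > 0, xx, 1.0), np.nan)
        ssr = yy - beta**2 * xx
        se = np.sqrt(np.maximum(ssr, 0.0) / df / np.where(xx > 0, xx, np.nan))
        t = beta / se
    p = np.where(np.isfinite(t), 2 * stats.t.sf(np.abs(np.nan_to_num(t)), df), 1.0)
    p = np.maximum(p, np.finfo(float).tiny)
    return pd.DataFrame(
        {"beta": beta, "se": se, "t": t, "p": p, "n_carriers": n_carriers}
    )
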