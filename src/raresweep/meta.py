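"""Sample-size-weighted Z-score meta-analysis and meta-qualification gates.

Each cohort's (p, direction) is converted to a signed normal deviate
``z = direction * Phi^{-1}(1 - p/2)`` and combined as

    Z = sum_i w_i z_i / sqrt(sum_i w_i^2),   w_i = sqrt(n_i),

with the two-sided combined p-value ``2 * (1 - Phi(|Z|))`` — the METAL-style
weighted-Z scheme. A combined result *qualifies* only when (1) both cohorts
have at least one variant carrier, (2) the meta p is strictly lower (better)
than each cohort's own p, and (3) for binary traits the pooled expected
carrier count in the smaller phenotype group is at least 10.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .assoc import AssociationResult
from .collapse import expected_case_carriers
from .errors import DataError


@dataclass
class MetaResult:
    gene: str
    model: str
    phenotype: str
    combined_z: float
    combined_p: float
    weights: tuple
    cohort_z: tuple
    cohort_p: tuple
    gates: dict = field(default_factory=dict)
    qualified: bool | None = None


def signed_z(p: float, direction: int) -> float:
    """Signed normal deviate of a two-sided p-value.

    ``z = direction * Phi^{-1}(1 - p/2)``. ``p`` must lie in (0, 1]; an exact
    zero must be clamped upstream (the deviate would be infinite).
    """
    if not (0.0 < p <= 1.0):
        raise DataError(f"p must lie in (0, 1], got {p}")
    if direction not in (-1, 0, 1):
        raise DataError(f"direction must be -1, 0 or +1, got {direction}")
    return float(direction * stats.norm.isf(p / 2.0))


def effective_sample_size(n_cases: int, n_controls: int) -> float:
    """METAL's effective n for binary traits: 4 / (1/n_cases + 1/n_controls)."""
    if n_cases <= 0 or n_controls <= 0:
        raise DataError("effective sample size needs positive case and control counts")
    return 4.0 / (1.0 / n_cases + 1.0 / n_controls)


def weighted_z_meta(
    cohort_stats,
    gene: str = "",
    model: str = "",
    phenotype: str = "",
) -> MetaResult:
    """Combine per-cohort ``(p, direction, n)`` triples into one signed Z and p.

    ``cohort_stats`` is an iterable of ``(p, direction, n)`` or of
    :class:`~raresweep.assoc.AssociationResult`. With a single cohort the
    combined p equals the input p.
    """
    triples = []
    for s in cohort_stats:
        if isinstance(s, AssociationResult):
            triples.append((s.p, s.direction, s.n))
        else:
            triples.append(tuple(s))
    if not triples:
        raise DataError("at least one cohort result required")
    for p, _, n in triples:
        if n <= 0:
            raise DataError(f"nonpositive sample size {n}")
        if not (0.0 < p <= 1.0):
            raise DataError(f"p outside (0, 1]: {p}")
    w = np.sqrt([float(n) for _, _, n in triples])
    z = np.array([signed_z(p, d) for p, d, _ in triples])
    combined_z = float((w * z).sum() / np.sqrt((w**2).sum()))
    combined_p = float(min(max(2.0 * stats.norm.sf(abs(combined_z)), np.finfo(float).tiny), 1.0))
    return MetaResult(
        gene=gene,
        model=model,
        phenotype=phenotype,
        combined_z=combined_z,
        combined_p=combined_p,
        weights=tuple(w),
        cohort_z=tuple(z),
        cohort_p=tuple(p for p, _, _ in triples),
    )


def meta_gate(
    meta: MetaResult,
    cohort_carrier_counts,
    kind: str,
    pooled_carrier_frequency: float | None = None,
    pooled_n_smaller_group: int | None = None,
    min_expected: float = 10.0,
) -> MetaResult:
    """Fill the meta-qualification gates on a combined result.

    Gates: at least one carrier in every cohort; meta p strictly lower than
    each cohort p; and, for binary traits only, pooled expected carriers in
    the smaller group >= ``min_expected`` (computed on the pooled two-cohort
    carrier frequency and pooled smaller-group size).
    """
    counts = list(cohort_carrier_counts)
    gates = {}
    missing = any(c is None for c in counts)
    gates["both_cohorts_have_carriers"] = (not missing) and all(c >= 1 for c in counts)
    gates["meta_p_better_than_each"] = all(meta.combined_p < p for p in meta.cohort_p)
    if kind == "binary":
        if pooled_carrier_frequency is None or pooled_n_smaller_group is None:
            raise DataError("binary meta gate requires pooled carrier frequency and group size")
        e = expected_case_carriers(pooled_carrier_frequency, pooled_n_smaller_group)
        gates["pooled_expected_ge_min"] = e >= min_expected
        gates["pooled_expected_case_carriers"] = e
    meta.gates = gates
    meta.qualified = all(v for k, v in gates.items() if isinstance(v, (bool, np.bool_)))
    return meta
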