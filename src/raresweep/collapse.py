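"""Gene-level collapsing and carrier-count gates.

Collapsing codes each sample 1 if it carries at least one alternate allele at
any qualifying variant in the gene, 0 otherwise, yielding one indicator per
gene (a dominant burden model). Two gates then decide whether the indicator
may enter the regression-based association test:

* binary traits — the *expected* number of carriers in the smaller phenotype
  group, ``E = carrier_frequency x n_smaller_group``, must be at least 10;
* quantitative traits — at least 5 carriers.

The expected-carrier gate is the device that keeps the regression test
statistic calibrated under severe case:control imbalance; genes failing it
fall back to Fisher's exact test (binary) or are excluded (quantitative).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .errors import DataError

logger = logging.getLogger(__name__)

#: Default gate thresholds.
MIN_EXPECTED_CASE_CARRIERS = 10.0
MIN_QUANTITATIVE_CARRIERS = 5


@dataclass
class CollapsedGene:
    """Per-gene carrier indicator for one collapsing model."""

    gene: str
    model: str
    indicator: np.ndarray  # int8 {0,1} per sample; missing genotypes count as 0
    sample_ids: tuple

    @property
    def n_carriers(self) -> int:
        return int(self.indicator.sum())

    @property
    def carrier_frequency(self) -> float:
        return self.n_carriers / len(self.indicator)


@dataclass
class GateResult:
    gene: str
    phenotype: str
    kind: str  # binary | quantitative
    expected_case_carriers: float
    observed_case_carriers: int | None
    n_smaller_group: int | None
    n_carriers: int
    verdict: bool
    reason: str


def collapse_gene(genotypes, qualifying_variant_ids, gene: str = "", model: str = "") -> CollapsedGene:
    """Collapse qualifying variants of one gene into a 0/1 carrier indicator.

    ``genotypes`` is a :class:`~raresweep.io.GenotypeMatrix`. A sample is a
    carrier iff it has >= 1 alternate allele at >= 1 qualifying variant;
    carrying several qualifying variants still yields 1. Missing genotypes
    (coded -1) are treated as non-carrying.
    """
    ids = list(qualifying_variant_ids)
    if not ids:
        raise DataError(f"gene {gene!r}: empty qualifying variant list (should be omitted upstream)")
    sub = genotypes.columns(ids)
    indicator = (sub > 0).any(axis=1).astype(np.int8)
    return CollapsedGene(gene=gene, model=model, indicator=indicator, sample_ids=tuple(genotypes.sample_ids))


def expected_case_carriers(carrier_frequency: float, n_smaller_group: int) -> float:
    """Expected carriers in the smaller phenotype group under the overall carrier frequency."""
    if not np.isfinite(carrier_frequency) or not (0.0 <= carrier_frequency <= 1.0):
        raise DataError(f"carrier_frequency outside [0, 1]: {carrier_frequency}")
    return carrier_frequency * n_smaller_group


def carrier_gate(
    collapsed: CollapsedGene,
    kind: str,
    phenotype: str = "",
    n_cases: int | None = None,
    n_controls: int | None = None,
    n_carriers_phenotyped: int | None = None,
    carrier_frequency: float | None = None,
    observed_case_carriers: int | None = None,
    min_expected: float = MIN_EXPECTED_CASE_CARRIERS,
    min_carriers: int = MIN_QUANTITATIVE_CARRIERS,
) -> GateResult:
    """Apply the carrier-count gate for one gene x phenotype.

    Binary traits pass iff the *expected* carrier count in the smaller of the
    case/control groups is at least ``min_expected`` — the gate is on the
    expectation under the overall carrier frequency, never on the observed
    case-carrier count. Quantitative traits pass iff the number of carriers
    (among phenotyped samples when supplied) is at least ``min_carriers``.
    """
    cf = collapsed.carrier_frequency if carrier_frequency is None else carrier_frequency
    n_carriers = collapsed.n_carriers if n_carriers_phenotyped is None else n_carriers_phenotyped

    if kind == "binary":
        if n_cases is None or n_controls is None:
            raise DataError("binary gate requires n_cases and n_controls")
        if n_cases + n_controls == 0:
            raise DataError("zero phenotyped samples")
        n_smaller = min(n_cases, n_controls)
        e = expected_case_carriers(cf, n_smaller)
        verdict = e >= min_expected
        reason = (
            f"expected carriers in smaller group {e:.3g} "
            f"{'>=' if verdict else '<'} {min_expected:g}"
        )
        return GateResult(
            gene=collapsed.gene,
            phenotype=phenotype,
            kind=kind,
            expected_case_carriers=e,
            observed_case_carriers=observed_case_carriers,
            n_smaller_group=n_smaller,
            n_carriers=n_carriers,
            verdict=verdict,
            reason=reason,
        )
    if kind == "quantitative":
        verdict = n_carriers >= min_carriers
        reason = f"{n_carriers} carriers {'>=' if verdict else '<'} {min_carriers}"
        return GateResult(
            gene=collapsed.gene,
            phenotype=phenotype,
            kind=kind,
            expected_case_carriers=float("nan"),
            observed_case_carriers=None,
            n_smaller_group=None,
            n_carriers=n_carriers,
            verdict=verdict,
            reason=reason,
        )
    raise DataError(f"unknown phenotype kind {kind!r}")
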