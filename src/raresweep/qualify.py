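"""Qualifying-variant selection.

A variant "qualifies" for a gene-based collapsing model when it passes four
independent filters:

1. **Consequence / deleteriousness.** The coding model keeps protein-altering
   consequence terms that are not predicted benign by PolyPhen (< 0.15) or
   SIFT (> 0.05); the loss-of-function (LoF) model keeps only terms predicted
   to abolish the gene product.
2. **Frequency.** The allele frequency must be strictly below the cutoff
   (default 0.1%) in *every* reference (gnomAD-style) population and in every
   local study population.
3. **Region.** The site must fall inside both the CDS intervals and the
   high-confidence-region intervals.
4. **Call quality.** Records whose VCF ``FILTER`` is neither PASS nor missing
   are dropped.

Variants that survive are grouped per gene into :class:`QualifyingSets`, with
a singleton flag (dataset allele count 1, never seen in the reference
database) attached to each variant.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd
from intervaltree import IntervalTree

from .errors import ConfigError, DataError

logger = logging.getLogger(__name__)

#: Consequence terms eligible for the coding model (before score filtering).
CODING_TERMS = frozenset(
    {
        "stop_lost",
        "missense_variant",
        "start_lost",
        "splice_donor_variant",
        "inframe_deletion",
        "frameshift_variant",
        "splice_acceptor_variant",
        "stop_gained",
        "inframe_insertion",
    }
)

#: Consequence terms eligible for the loss-of-function model.
LOF_TERMS = frozenset(
    {
        "stop_lost",
        "start_lost",
        "splice_donor_variant",
        "frameshift_variant",
        "splice_acceptor_variant",
        "stop_gained",
    }
)


@dataclass
class QualifyingConfig:
    """Thresholds and term lists for qualifying-variant selection.

    Parameters
    ----------
    maf_cutoff
        Strict upper bound on every reference and local allele frequency.
    polyphen_benign_below
        PolyPhen scores below this value mark a variant benign.
    sift_benign_above
        SIFT scores above this value mark a variant benign.
    benign_rule
        ``"either"`` (default): a variant is excluded when either tool calls
        it benign. ``"both"``: excluded only when both tools call it benign.
    """

    maf_cutoff: float = 1e-3
    polyphen_benign_below: float = 0.15
    sift_benign_above: float = 0.05
    benign_rule: str = "either"
    coding_terms: frozenset = field(default_factory=lambda: CODING_TERMS)
    lof_terms: frozenset = field(default_factory=lambda: LOF_TERMS)
    reference_populations: tuple = ()
    local_populations: tuple = ()

    def __post_init__(self) -> None:
        for name in ("maf_cutoff", "polyphen_benign_below", "sift_benign_above"):
            v = getattr(self, name)
            if not (0.0 < v < 1.0):
                raise ConfigError(f"{name} must lie in (0, 1), got {v}")
        if self.benign_rule not in ("either", "both"):
            raise ConfigError(f"benign_rule must be 'either' or 'both', got {self.benign_rule!r}")
        if not self.lof_terms <= self.coding_terms:
            raise ConfigError("lof_terms must be a subset of coding_terms")

    @classmethod
    def from_yaml(cls, path) -> "QualifyingConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("coding_terms", "lof_terms"):
            if key in raw:
                raw[key] = frozenset(raw[key])
        for key in ("reference_populations", "local_populations"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


@dataclass
class QualifyingSets:
    """Per-gene ordered lists of qualifying variant ids for one model."""

    model: str
    genes: dict  # gene -> list of variant ids, ordered by position
    singleton: dict  # variant id -> bool
    n_input: int = 0
    n_rejected: int = 0

    @property
    def n_qualifying(self) -> int:
        return sum(len(v) for v in self.genes.values())


def _is_missing(score) -> bool:
    return score is None or (isinstance(score, float) and math.isnan(score))


def _score_benign(polyphen, sift, config: QualifyingConfig) -> bool:
    """Benignity from deleteriousness scores; missing scores never show benignity."""
    pp_benign = (not _is_missing(polyphen)) and polyphen < config.polyphen_benign_below
    sift_benign = (not _is_missing(sift)) and sift > config.sift_benign_above
    if config.benign_rule == "either":
        return pp_benign or sift_benign
    return pp_benign and sift_benign


def classify_model(consequence, polyphen, sift, config: QualifyingConfig | None = None):
    """Classify one variant's eligibility for the coding and LoF models.

    Returns a ``(coding, lof)`` pair of booleans. Unrecognized consequence
    terms classify as ``(False, False)`` with a logged warning rather than
    raising, so that a stray annotation cannot abort a genome-wide run.
    """
    config = config or QualifyingConfig()
    if consequence not in config.coding_terms and consequence not in config.lof_terms:
        if consequence not in _KNOWN_NONQUALIFYING:
            logger.warning("unrecognized consequence term %r -> non-qualifying", consequence)
        return False, False
    coding = consequence in config.coding_terms and not _score_benign(polyphen, sift, config)
    lof = consequence in config.lof_terms
    return coding, lof


# Terms we expect to see and silently reject (no warning).
_KNOWN_NONQUALIFYING = frozenset(
    {
        "synonymous_variant",
        "intron_variant",
        "5_prime_UTR_variant",
        "3_prime_UTR_variant",
        "upstream_gene_variant",
        "downstream_gene_variant",
        "intergenic_variant",
        "splice_region_variant",
    }
)


def passes_maf_filter(
    reference_afs: Mapping[str, float],
    local_afs: Mapping[str, float],
    cutoff: float = 1e-3,
) -> bool:
    """True iff every provided reference and local frequency is strictly below ``cutoff``.

    A variant absent from the reference database (empty map) trivially passes
    the reference side; exact-cutoff frequencies fail (strict inequality).
    """
    for pop, f in list(reference_afs.items()) + list(local_afs.items()):
        if _is_missing(f):
            continue
        if not (0.0 <= f <= 1.0):
            raise DataError(f"allele frequency for {pop} outside [0, 1]: {f}")
        if f >= cutoff:
            return False
    return True


def build_interval_tree(intervals: Iterable[tuple]) -> IntervalTree:
    """Build an interval tree from ``(start, end)`` half-open pairs.

    Raises :class:`DataError` for malformed intervals (start >= end).
    """
    tree = IntervalTree()
    for start, end in intervals:
        if start >= end:
            raise DataError(f"malformed interval [{start}, {end})")
        tree[start:end] = True
    return tree


def passes_region_filter(position: int, cds: IntervalTree, high_confidence: IntervalTree) -> bool:
    """True iff ``position`` falls inside both interval sets.

    Intervals are half-open ``[start, end)`` as parsed from BED; the position
    is tested for membership directly (``start <= position < end``).
    """
    return bool(cds[position]) and bool(high_confidence[position])


def is_singleton(dataset_allele_count: int, reference_allele_count: int) -> bool:
    """Singleton: seen exactly once in this dataset and never in the reference."""
    if dataset_allele_count < 0 or reference_allele_count < 0:
        raise DataError("allele counts must be nonnegative")
    return dataset_allele_count == 1 and reference_allele_count == 0


def build_qualifying_sets(
    variants: pd.DataFrame,
    dataset_allele_counts: Mapping[str, int],
    config: QualifyingConfig,
    model: str,
    cds: IntervalTree,
    high_confidence: IntervalTree,
    local_af_prefix: str = "local_af_",
    reference_af_prefix: str = "af_",
) -> QualifyingSets:
    """Assemble per-gene qualifying variant sets for one collapsing model.

    ``variants`` must carry columns ``variant_id, gene, pos, consequence,
    polyphen, sift, reference_allele_count`` plus per-population frequency
    columns named ``af_<pop>`` (reference) and ``local_af_<pop>`` (local).
    An optional ``filter`` column is honored: records that are neither
    ``PASS`` nor empty are dropped. Local frequencies not provided as columns
    are derived from ``dataset_allele_counts`` over ``2 * n_samples`` when a
    ``_n_samples`` attribute is present on the mapping; otherwise only the
    provided columns are used.

    Genes with zero qualifying variants are omitted. Variants with no gene
    assignment are skipped (counted and logged).
    """
    if model not in ("coding", "lof"):
        raise ConfigError(f"model must be 'coding' or 'lof', got {model!r}")

    ref_cols = [c for c in variants.columns if c.startswith(reference_af_prefix) and not c.startswith(local_af_prefix)]
    local_cols = [c for c in variants.columns if c.startswith(local_af_prefix)]

    genes: dict = {}
    singleton: dict = {}
    n_rejected = 0
    n_no_gene = 0
    has_filter = "filter" in variants.columns

    for row in variants.sort_values("pos").itertuples(index=False):
        gene = getattr(row, "gene", None)
        if gene is None or (isinstance(gene, float) and math.isnan(gene)) or gene == "":
            n_no_gene += 1
            continue
        if has_filter and getattr(row, "filter") not in ("PASS", ".", "", None):
            n_rejected += 1
            continue
        coding, lof = classify_model(row.consequence, row.polyphen, row.sift, config)
        ok = coding if model == "coding" else lof
        if not ok:
            n_rejected += 1
            continue
        ref_afs = {c: getattr(row, c) for c in ref_cols}
        local_afs = {c: getattr(row, c) for c in local_cols}
        if not passes_maf_filter(ref_afs, local_afs, config.maf_cutoff):
            n_rejected += 1
            continue
        if not passes_region_filter(row.pos, cds, high_confidence):
            n_rejected += 1
            continue
        genes.setdefault(gene, []).append(row.variant_id)
        singleton[row.variant_id] = is_singleton(
            int(dataset_allele_counts[row.variant_id]), int(row.reference_allele_count)
        )

    if n_no_gene:
        logger.info("skipped %d variants with no gene assignment", n_no_gene)
    return QualifyingSets(
        model=model,
        genes=genes,
        singleton=singleton,
        n_input=len(variants),
        n_rejected=n_rejected + n_no_gene,
    )
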