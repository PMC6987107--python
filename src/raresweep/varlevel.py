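"""Variant-level decomposition of significant gene burden signals.

Once a gene x phenotype association is significant, three follow-up analyses
ask *which variants carry the signal*:

* per-variant association — the burden regression re-run with a single
  variant's carrier indicator;
* lead-variant conditioning — the gene test repeated with the best
  (>= 3 carriers) variant's indicator appended to the covariates, showing
  how much signal survives;
* singleton sensitivity — the gene test repeated with singletons removed;
* protein-domain enrichment — a Fisher test of whether direction-consistent
  missense variants concentrate in (or directly adjacent to) a protein
  domain.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .assoc import AssociationResult, PhenotypeVector, burden_regression
from .errors import DataError


@dataclass
class VariantEffect:
    variant_id: str
    gene: str
    n_carriers: int
    beta: float
    p: float
    direction: int
    pos: int | None = None
    protein_position: int | None = None
    domain_membership: str | None = None  # in | adjacent | outside
    singleton: bool = False


@dataclass
class DomainMap:
    """Protein-domain intervals (closed residue ranges) for one gene."""

    gene: str
    protein_length: int
    domains: tuple  # ((start, end), ...) closed, 1-based residues
    adjacency_margin: int = 1

    def __post_init__(self):
        for start, end in self.domains:
            if not (1 <= start <= end <= self.protein_length):
                raise DataError(
                    f"domain [{start}, {end}] outside protein [1, {self.protein_length}]"
                )

    def classify(self, residue: int) -> str:
        """'in' | 'adjacent' (within the margin of a boundary) | 'outside'."""
        for start, end in self.domains:
            if start <= residue <= end:
                return "in"
        m = self.adjacency_margin
        for start, end in self.domains:
            if start - m <= residue <= end + m:
                return "adjacent"
        return "outside"


def per_variant_test(
    variant_genotypes: np.ndarray,
    pheno: PhenotypeVector,
    covariates: pd.DataFrame | None = None,
    sample_ids=None,
    variant_id: str = "",
    gene: str = "",
    pos: int | None = None,
    protein_position: int | None = None,
    singleton: bool = False,
) -> VariantEffect | None:
    """Single-variant association via the same regression machinery as the gene test.

    Returns ``None`` when the variant has no carriers among phenotyped
    samples (the variant is skipped, not an error).
    """
    indicator = (np.asarray(variant_genotypes) > 0).astype(np.int8)
    try:
        res = burden_regression(
            indicator, pheno, covariates, sample_ids=sample_ids, gene=gene
        )
    except DataError:
        return None
    return VariantEffect(
        variant_id=variant_id,
        gene=gene,
        n_carriers=res.n_carriers,
        beta=res.beta,
        p=res.p,
        direction=res.direction,
        pos=pos,
        protein_position=protein_position,
        singleton=singleton,
    )


def select_lead_variant(effects, min_carriers: int = 3):
    """Best-p variant with at least ``min_carriers`` carriers; ``None`` if no variant qualifies.

    Ties on p break to the smaller genomic coordinate, then the variant id,
    so selection is deterministic.
    """
    effects = list(effects)
    if not effects:
        raise DataError("empty effects list")
    eligible = [e for e in effects if e.n_carriers >= min_carriers]
    if not eligible:
        return None
    key = lambda e: (e.p, e.pos if e.pos is not None else math.inf, e.variant_id)
    return min(eligible, key=key).variant_id


def conditional_gene_test(
    gene_indicator: np.ndarray,
    lead_indicator: np.ndarray,
    pheno: PhenotypeVector,
    covariates: pd.DataFrame | None = None,
    sample_ids=None,
    gene: str = "",
) -> AssociationResult:
    """Gene burden test with the lead variant's carrier status as an extra covariate.

    When the lead indicator is identical to the gene indicator the
    conditional fit is undefined (perfect collinearity); the result is
    returned with ``extra['driven_entirely_by_lead'] = True`` and p = NaN.
    """
    gi = np.asarray(gene_indicator)
    li = np.asarray(lead_indicator, dtype=float)
    if np.array_equal(gi.astype(bool), li.astype(bool)):
        return AssociationResult(
            gene=gene,
            model="",
            phenotype=pheno.phenotype_id,
            cohort="",
            test="regression",
            beta=float("nan"),
            p=float("nan"),
            direction=0,
            n=pheno.n_phenotyped,
            n_carriers=int((gi > 0).sum()),
            extra={"driven_entirely_by_lead": True},
        )
    index = list(sample_ids) if sample_ids is not None else list(pheno.values.index)
    if covariates is None:
        cov = pd.DataFrame({"lead": li}, index=index)
    else:
        cov = covariates.copy()
        cov["lead"] = pd.Series(li, index=index)
    res = burden_regression(gi, pheno, cov, sample_ids=sample_ids, gene=gene)
    res.extra["driven_entirely_by_lead"] = False
    res.extra["conditioned_on"] = "lead"
    return res


def singleton_sensitivity(
    genotypes,
    qualifying_variant_ids,
    singleton_flags: dict,
    pheno: PhenotypeVector,
    covariates: pd.DataFrame | None = None,
    sample_ids=None,
    gene: str = "",
) -> dict:
    """Burden p-value with and without singleton variants.

    Returns ``{"p_with", "p_without", "n_singletons"}``; when every
    qualifying variant is a singleton, ``p_without`` is ``None`` and the
    result is flagged ``all_singletons``.
    """
    from .collapse import collapse_gene

    ids = list(qualifying_variant_ids)
    non_singletons = [v for v in ids if not singleton_flags.get(v, False)]
    full = collapse_gene(genotypes, ids, gene=gene)
    res_with = burden_regression(full.indicator, pheno, covariates, sample_ids=sample_ids, gene=gene)
    out = {
        "p_with": res_with.p,
        "n_singletons": len(ids) - len(non_singletons),
        "all_singletons": not non_singletons,
        "p_without": None,
    }
    if non_singletons:
        reduced = collapse_gene(genotypes, non_singletons, gene=gene)
        try:
            res_wo = burden_regression(
                reduced.indicator, pheno, covariates, sample_ids=sample_ids, gene=gene
            )
            out["p_without"] = res_wo.p
        except DataError:
            out["p_without"] = None
    return out


def domain_enrichment(
    effects,
    domain_map: DomainMap,
    direction_of_interest: int,
) -> tuple[float, np.ndarray]:
    """Fisher test for concentration of direction-consistent missense variants in a domain.

    Each positioned variant is classified in/adjacent vs outside the domain
    intervals; the 2x2 table crosses (direction-consistent vs not) with
    (in/adjacent vs outside) and is tested with the two-sided Fisher's exact
    test. Returns ``(p, table)``.
    """
    positioned = [e for e in effects if e.protein_position is not None]
    if not positioned:
        raise DataError("no variants with protein positions")
    table = np.zeros((2, 2), dtype=int)
    for e in positioned:
        membership = domain_map.classify(e.protein_position)
        e.domain_membership = membership
        row = 0 if e.direction == direction_of_interest else 1
        col = 0 if membership in ("in", "adjacent") else 1
        table[row, col] += 1
    _, p = stats.fisher_exact(table, alternative="two-sided")
    return float(p), table
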