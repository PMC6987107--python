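"""File formats and in-memory containers.

Genotypes travel as VCF v4.2 (GT-only), annotations and phenotypes as TSV,
and region masks as BED (0-based half-open). The in-memory genotype container
is a dense ``int8`` matrix (samples x variants) with -1 for missing calls —
appropriate at the cohort sizes this package simulates and analyzes.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .errors import DataError
from .qualify import build_interval_tree

MISSING = -1


@dataclass
class GenotypeMatrix:
    """Dense dosage matrix: rows are samples, columns are variants.

    Entries are alternate-allele dosages {0, 1, 2} with ``-1`` for missing
    calls. Column order matches ``variant_ids``.
    """

    data: np.ndarray
    sample_ids: tuple
    variant_ids: tuple
    _col: dict = field(default_factory=dict, repr=False)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.int8)
        if self.data.shape != (len(self.sample_ids), len(self.variant_ids)):
            raise DataError("genotype matrix shape does not match sample/variant ids")
        self._col = {v: j for j, v in enumerate(self.variant_ids)}

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def columns(self, variant_ids: Sequence[str]) -> np.ndarray:
        try:
            idx = [self._col[v] for v in variant_ids]
        except KeyError as e:
            raise DataError(f"unknown variant id {e.args[0]!r}") from None
        return self.data[:, idx]

    def column(self, variant_id: str) -> np.ndarray:
        return self.columns([variant_id])[:, 0]

    def allele_counts(self) -> pd.Series:
        """Dataset alternate-allele count per variant (missing calls ignored)."""
        d = self.data.astype(np.int64)
        d[d == MISSING] = 0
        return pd.Series(d.sum(axis=0), index=list(self.variant_ids))

    def carrier_indicator(self, variant_ids: Sequence[str]) -> np.ndarray:
        """0/1 per sample: carries >=1 alt allele at >=1 of the given variants."""
        return (self.columns(variant_ids) > 0).any(axis=1).astype(np.int8)


@dataclass
class CohortData:
    """Everything one cohort contributes to the analysis."""

    name: str
    variants: pd.DataFrame
    genotypes: GenotypeMatrix
    samples: pd.DataFrame
    phenotypes: pd.DataFrame  # long: sample_id, phenotype_id, value
    manifest: pd.DataFrame  # phenotype_id, kind, sex_restriction
    covariates: pd.DataFrame  # indexed by sample_id
    cds: IntervalTree
    high_confidence: IntervalTree


# ---------------------------------------------------------------------------
# VCF


def write_vcf(path, variants: pd.DataFrame, genotypes: GenotypeMatrix) -> None:
    """Write a minimal VCF v4.2 with GT-only genotype columns.

    ``variants`` must have columns ``variant_id, chrom, pos, ref, alt`` and may
    carry a ``filter`` column (defaults to PASS). Missing calls are written
    ``./.``.
    """
    gt_code = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    order = {v: j for j, v in enumerate(genotypes.variant_ids)}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FILTER=<ID=LowQual,Description="Low quality call">\n')
        for chrom in pd.unique(variants["chrom"].astype(str)):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(genotypes.sample_ids) + "\n")
        has_filter = "filter" in variants.columns
        for row in variants.sort_values(["chrom", "pos"]).itertuples(index=False):
            j = order[row.variant_id]
            col = genotypes.data[:, j]
            gts = "\t".join(gt_code[int(g)] for g in col)
            filt = getattr(row, "filter") if has_filter else "PASS"
            fh.write(
                f"{row.chrom}\t{row.pos}\t{row.variant_id}\t{row.ref}\t{row.alt}"
                f"\t.\t{filt}\t.\tGT\t{gts}\n"
            )


def read_vcf(path) -> tuple[pd.DataFrame, GenotypeMatrix]:
    """Read a GT-only VCF back into a sites table and a :class:`GenotypeMatrix`."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    sample_ids = tuple(vcf.samples)
    rows = []
    cols = []
    for rec in vcf:
        vid = rec.ID or f"{rec.CHROM}-{rec.POS}-{rec.REF}-{rec.ALT[0]}"
        rows.append(
            {
                "variant_id": vid,
                "chrom": rec.CHROM,
                "pos": rec.POS,
                "ref": rec.REF,
                "alt": rec.ALT[0],
                "filter": rec.FILTER or "PASS",
            }
        )
        # gt_types: 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
        gt = rec.gt_types
        dosage = np.select([gt == 0, gt == 1, gt == 3], [0, 1, 2], default=MISSING)
        cols.append(dosage.astype(np.int8))
    vcf.close()
    sites = pd.DataFrame(rows)
    data = (
        np.column_stack(cols) if cols else np.zeros((len(sample_ids), 0), dtype=np.int8)
    )
    gm = GenotypeMatrix(data=data, sample_ids=sample_ids, variant_ids=tuple(sites["variant_id"]))
    return sites, gm


# ---------------------------------------------------------------------------
# BED


def write_bed(path, intervals: Iterable[tuple], chrom: str = "1") -> None:
    with open(path, "w") as fh:
        for start, end in intervals:
            fh.write(f"{chrom}\t{start}\t{end}\n")


def read_bed(path) -> IntervalTree:
    """Parse a BED file (0-based half-open) into an interval tree."""
    ivs = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise DataError(f"malformed BED line: {line!r}")
            ivs.append((int(parts[1]), int(parts[2])))
    return build_interval_tree(ivs)


# ---------------------------------------------------------------------------
# Cohort round-trip


def export_cohort(
    outdir,
    variants: pd.DataFrame,
    genotypes: GenotypeMatrix,
    samples: pd.DataFrame,
    phenotypes: pd.DataFrame,
    manifest: pd.DataFrame,
    covariates: pd.DataFrame,
    cds_intervals: Iterable[tuple],
    high_confidence_intervals: Iterable[tuple],
) -> dict:
    """Write one cohort's inputs to ``outdir``; returns the paths written."""
    os.makedirs(outdir, exist_ok=True)
    paths = {
        "vcf": os.path.join(outdir, "genotypes.vcf"),
        "annotation": os.path.join(outdir, "annotation.tsv"),
        "cds": os.path.join(outdir, "cds.bed"),
        "high_confidence": os.path.join(outdir, "high_confidence.bed"),
        "phenotypes": os.path.join(outdir, "phenotypes.tsv"),
        "manifest": os.path.join(outdir, "manifest.tsv"),
        "covariates": os.path.join(outdir, "covariates.tsv"),
        "samples": os.path.join(outdir, "samples.tsv"),
    }
    write_vcf(paths["vcf"], variants, genotypes)
    anno_cols = [c for c in variants.columns if c not in ("ref", "alt", "filter")]
    variants[anno_cols].to_csv(paths["annotation"], sep="\t", index=False)
    chrom = str(variants["chrom"].iloc[0]) if len(variants) else "1"
    write_bed(paths["cds"], cds_intervals, chrom)
    write_bed(paths["high_confidence"], high_confidence_intervals, chrom)
    phenotypes.to_csv(paths["phenotypes"], sep="\t", index=False)
    manifest.to_csv(paths["manifest"], sep="\t", index=False)
    covariates.to_csv(paths["covariates"], sep="\t", index=True, index_label="sample_id")
    samples.to_csv(paths["samples"], sep="\t", index=False)
    return paths


def load_cohort(indir, name: str = "cohort") -> CohortData:
    """Load a cohort previously written by :func:`export_cohort`."""
    indir = str(indir)
    sites, gm = read_vcf(os.path.join(indir, "genotypes.vcf"))
    anno = pd.read_csv(os.path.join(indir, "annotation.tsv"), sep="\t")
    variants = sites.merge(
        anno.drop(columns=[c for c in ("chrom", "pos") if c in anno.columns]),
        on="variant_id",
        validate="one_to_one",
    )
    phenotypes = pd.read_csv(os.path.join(indir, "phenotypes.tsv"), sep="\t")
    manifest = pd.read_csv(os.path.join(indir, "manifest.tsv"), sep="\t")
    covariates = pd.read_csv(os.path.join(indir, "covariates.tsv"), sep="\t", index_col="sample_id")
    samples = pd.read_csv(os.path.join(indir, "samples.tsv"), sep="\t")
    return CohortData(
        name=name,
        variants=variants,
        genotypes=gm,
        samples=samples,
        phenotypes=phenotypes,
        manifest=manifest,
        covariates=covariates,
        cds=read_bed(os.path.join(indir, "cds.bed")),
        high_confidence=read_bed(os.path.join(indir, "high_confidence.bed")),
    )
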