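# raresweep

Rare-variant gene-based collapsing PheWAS: a tested, reusable implementation
of the qualification → collapse → gate → test → meta-analyze → decompose
workflow used to scan thousands of phenotypes for genes in which rare coding
variants act in aggregate.

## The problem and the method

Variants with minor allele frequency below 0.1% are individually untestable:
almost every carrier set is too small for a per-variant association. The
collapsing approach groups them per gene: a sample is coded 1 if it carries
at least one *qualifying* variant in the gene and 0 otherwise, giving one
dominant-model burden test per gene. A variant qualifies for the **coding**
model when its consequence is protein-altering (stop_lost, missense,
start_lost, splice donor/acceptor, inframe indel, frameshift, stop_gained)
and not predicted benign (PolyPhen < 0.15 or SIFT > 0.05), and for the
**LoF** model when the consequence is loss-of-function; in both models its
frequency must be < 0.1% in every reference and local population and the
site must fall in CDS and high-confidence regions.

The statistical core:

* **Burden test.** OLS regression of the (rank-inverse-normal transformed)
  phenotype on the gene carrier indicator with age, sex, batch and
  principal-component covariates; binary traits use the same linear fit on
  their {0,1} coding, with a two-sided Fisher's exact test
  (point-probability convention) as the fallback path.
* **Inflation control.** For a binary trait, the regression is run only when
  the *expected* number of carriers in the smaller phenotype group,
  `E = carrier_frequency × n_smaller`, is at least 10 (quantitative traits
  need ≥ 5 carriers). Under severe case:control imbalance (e.g. 1:22) the
  ungated scan produces a large excess of extreme p-values from genes with
  few expected case carriers; the gate removes them and the Fisher fallback
  covers the gated-out genes without inflation.
* **Meta-analysis.** Cohorts combine by METAL-style weighted Z:
  `Z = Σ wᵢzᵢ / √(Σ wᵢ²)` with `wᵢ = √nᵢ` and `zᵢ = dᵢ·Φ⁻¹(1 − pᵢ/2)`. A
  combined result qualifies only with ≥ 1 carrier in both cohorts, a meta p
  strictly below both cohort p's, and (binary) pooled expected carriers ≥ 10.
* **Significance.** Bonferroni over genes × models × phenotypes:
  `α / ((n_coding + n_lof) × n_phenotypes)`.
* **Follow-up.** Per-variant effects, conditioning on the lead variant
  (best p with ≥ 3 carriers), singleton-removal sensitivity (singleton =
  dataset allele count 1, never seen in the reference), and protein-domain
  enrichment of direction-consistent missense variants.

Real inputs at this scale are access-restricted biobank exomes, so the
package ships a synthetic-cohort simulator (`raresweep.sim`) that generates
two-cohort exome-like data — rare sites with a large singleton fraction,
annotations, covariates, and traits with configurable per-gene burden
effects — making every stage testable end to end.

## Worked example

`examples/03_burden_phewas_meta.py` simulates two 1,500-sample cohorts with
one injected effect gene (beta 1.2 SD on carriers of qualifying coding
variants), runs both cohorts through the pipeline and meta-analyzes them:

```
per-cohort funnel: {'n_variants_input': 397, 'n_qualifying_coding': 233,
                    'n_genes_coding': 15, 'n_qualifying_lof': 82, 'n_genes_lof': 14}

Bonferroni threshold for this desk-scale study: 1.72e-03
injected effect gene: gene0003 (beta 1.2 SD on carriers)

    gene   combined_p          p_a          p_b  qualified
gene0003 4.187498e-23 4.714692e-12 1.380794e-12       True
gene0004 4.688087e-03 3.063599e-01 2.919309e-03      False
...
top gene IS the injected gene; meta p 4.19e-23 is lower than both cohort p's
(4.71e-12, 1.38e-12) as the qualification gate requires.
```

The funnel line mirrors the analysis stages (input variants → qualifying →
genes per model); the injected gene is recovered with a combined p far below
both per-cohort p's, and only it passes the meta-qualification gates. The
other examples cover simulation/export (`01`), the qualifying filters and
carrier gates (`02`), inflation diagnostics under a 1:22 case:control
imbalance (`04`), and variant-level follow-up (`05`). A thin CLI wraps the
same pipeline: `raresweep simulate|run|report`.

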