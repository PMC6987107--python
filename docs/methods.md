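# Methods

This note documents the models, conventions and design choices behind
`raresweep`, in the spirit of a statistical-software methods appendix. It
describes what the code computes; every number quoted here is produced by
the test suite or `scripts/acceptance.py`, not asserted from elsewhere.

## 1. Qualifying variants

A variant qualifies for a collapsing model when it passes four filters:

1. **Consequence/deleteriousness.** Coding model: consequence ∈ {stop_lost,
   missense_variant, start_lost, splice_donor_variant, inframe_deletion,
   frameshift_variant, splice_acceptor_variant, stop_gained,
   inframe_insertion} and the variant is not score-benign. LoF model:
   consequence ∈ {stop_lost, start_lost, splice_donor_variant,
   frameshift_variant, splice_acceptor_variant, stop_gained}, with no score
   filter (these consequences are damaging irrespective of missense scores).
   *Benign* means PolyPhen < 0.15 or SIFT > 0.05. The "or" is a deliberate
   strict reading — evidence of benignity from either tool excludes the
   variant; `QualifyingConfig(benign_rule="both")` switches to requiring
   both tools to agree. Variants lacking a score cannot be shown benign and
   are retained (exclusion requires positive evidence); this also covers
   inframe indels, which the score tools do not annotate. Unrecognized
   consequence terms classify as non-qualifying with a logged warning rather
   than an exception, so one stray annotation cannot abort a run.
2. **Frequency.** Strictly below the cutoff (default 0.1%) in *every*
   provided reference-population and local-population frequency. Absence
   from the reference trivially passes the reference side; a frequency
   exactly at the cutoff fails. Local per-population frequencies are
   consumed as annotation columns (`local_af_*`); they are an input, not
   recomputed from the cohort, because at desk-scale cohort sizes a
   dataset-derived frequency for an allele count of 2 already exceeds 0.1%
   and would empty the qualifying sets — the filter is meant for
   biobank-scale denominators.
3. **Region.** The position must fall in both the CDS and high-confidence
   BED masks. Intervals are half-open `[start, end)`; the (1-based) variant
   position is tested for direct membership, i.e. `start <= pos < end`.
   This convention is applied consistently by the simulator's BED writer and
   the filter, so the pipeline is self-consistent; callers supplying
   external BEDs should note the membership rule.
4. **Call quality.** Records with a VCF FILTER other than PASS/missing are
   dropped.

A **singleton** is a variant with dataset allele count exactly 1 and
reference (gnomAD-style) allele count 0.

## 2. Collapsing and carrier gates

Per gene and model, a sample's indicator is 1 iff it carries ≥ 1 alternate
allele at ≥ 1 qualifying variant (dominant model; multiple qualifying
variants still give 1). Missing genotypes count as non-carriers — the
least-assumption default for rare alleles, where a missing call is almost
always reference.

Gates before the regression test:

* binary: expected carriers in the smaller phenotype group,
  `E = carrier_frequency × min(n_cases, n_controls)`, must be ≥ 10. The
  gate is on the *expected* count under the overall carrier frequency, not
  the observed case-carrier count; the smaller-group formulation reduces to
  the case group whenever cases are the minority.
* quantitative: ≥ 5 carriers among phenotyped samples.

Gate-failing binary genes route to Fisher's exact test; gate-failing
quantitative genes are excluded.

## 3. Association tests

**Phenotype preparation.** Quantitative traits: per-sample median of
repeated measurements first, then a rank-based inverse-normal transform with
Blom offsets, `z = Φ⁻¹((r − 3/8)/(n + 1/4))`, average ranks for ties. The
offset constant is a documented choice (the transform family is standard;
the constant is not dictated by anything upstream). Binary traits: 1 if the
diagnosis code was ever recorded, 0 otherwise; under a sex restriction,
samples of the other sex (or unknown sex) are missing. Inclusion thresholds
across cohorts: ≥ 50 cases total with ≥ 5 per cohort (binary), ≥ 400
phenotyped (quantitative).

**Regression.** OLS of the prepared phenotype on the carrier indicator plus
an intercept and the caller's covariates (age, sex, batch levels, principal
components in the simulator's covariate table). Collinear covariate columns
are dropped with a warning via a greedy rank check. Binary traits are fit
with the same linear model on the {0,1} coding: this is the fixed-effect
analogue of the linear mixed model used at biobank scale (which also fits
binary traits as quantitative); relatedness random effects are out of scope
because the simulator draws unrelated samples, and every calibration claim
in this repository is made for this fixed-effect stand-in. A vectorized scan
(`burden_scan`) residualizes the phenotype and all indicators on the
covariates once (Frisch–Waugh) and is unit-tested to agree with the
per-gene OLS to 1e-9 relative.

**Fisher fallback.** Two-sided Fisher's exact test on the carrier ×
case/control 2×2 table with the point-probability ("minimum-likelihood")
two-sided convention: the p-value sums all tables whose point probability
does not exceed the observed table's. The implementation delegates to
`scipy.stats.fisher_exact`, which uses this convention; the test suite
verifies exact agreement with an integer-arithmetic hypergeometric
enumeration on every 2×2 table with grand total ≤ 60 (631,595 tables).
Direction comes from the sign of the sample odds ratio; degenerate margins
give p = 1 and direction 0.

**Zero-heritability path.** Phenotypes flagged as unfittable by a mixed
model route to the unrelated-samples regression/Fisher path — which is the
path implemented here, so the flag does not change the plan; it is accepted
as an input rather than recomputed.

## 4. Meta-analysis

Signed deviate `z = d·Φ⁻¹(1 − p/2)`, weights `w = √n`, combined
`Z = Σwz/√Σw²`, two-sided `p = 2(1 − Φ(|Z|))`. p-values of exactly 0 must
be clamped upstream (the deviate is infinite); the package clamps to the
smallest positive double with a warning where it generates p-values itself.
For binary traits the weight uses total phenotyped n by default; METAL-style
effective n, `4/(1/n_cases + 1/n_controls)`, is available behind
`use_effective_n=True` since either configuration is defensible.
Qualification gates: ≥ 1 carrier in both cohorts; meta p **strictly** lower
than both cohort p's; pooled expected carriers ≥ 10 for binary traits,
computed on the pooled two-cohort carrier frequency and pooled smaller-group
size. Phenotypes present in only one cohort bypass the meta track and are
reported as single-cohort results.

## 5. Significance and diagnostics

Bonferroni threshold `α/((n_coding_genes + n_lof_genes) × n_phenotypes)`;
at a reference biobank study scale (17,365 + 16,650 genes × 4,377 phenotypes,
α = 0.05) this evaluates to 3.4e-10. Significance is strict (`p <
threshold`) and, for meta results, conditional on all qualification gates.
Replication screens use `α/n_discovery_hits` with direction consistency
required before any replication verdict.

Genomic inflation λ = median(χ²₁(1−p))/0.45494. QQ plots use expected
quantiles `−log10(i/(n+1))`. Because collapsing tests of rare binary traits
have strongly discrete statistics, the median-based λ can *understate* (or
even invert) tail pathology: under the null with few expected case
carriers, most genes have zero case carriers and tiny χ², deflating the
median, while the rare genes with a case carrier or two produce extreme
p-values. The package therefore also reports a tail-excess diagnostic
(observed vs expected count of p-values below 1e-4), which is the metric
that actually exhibits the imbalance pathology and its removal by the gate;
see `examples/04_inflation_diagnostics.py` and the calibration experiments.

## 6. Variant-level follow-up

Per-variant tests reuse the burden regression with a single-variant carrier
indicator and the same covariates as the gene test (a documented choice; a
single carrier yields a valid wide-interval estimate, zero carriers skip
the variant). The lead variant is the best-p variant with ≥ 3 carriers;
ties break to the smaller genomic coordinate, then the variant id, making
selection deterministic. Conditioning appends the lead variant's 0/1
carrier status to the covariates (dosage conditioning would be a one-line
variation); a lead indicator identical to the gene indicator makes the
conditional fit undefined and is reported as driven-entirely-by-lead.
Singleton sensitivity re-runs the burden test on the qualifying set minus
singletons. Domain enrichment classifies positioned missense variants as
in/adjacent/outside domain intervals (closed residue ranges; "directly
adjacent" = within K residues of a boundary, K configurable, default 1 —
the notion is not quantified upstream) and Fisher-tests the 2×2 of
direction-consistency × domain membership.

## 7. The synthetic-data generator

The simulator emulates the statistical structure the analysis assumes, not
any real genome:

* genes as disjoint genomic spans on one chromosome; variant count per gene
  shifted-Poisson (≥ 1) with configurable mean, default 34 — the scale of a
  qualifying-variant-per-gene distribution in a large exome cohort;
* allele frequencies log-uniform on [2e-5, 1e-3); a configurable singleton
  fraction (default 0.38) of sites instead get exactly one alternate allele
  in the dataset and zero reference frequency; an optional common fraction
  (default 0) exceeds the cutoff to exercise the frequency filter;
* consequence terms from a categorical mix (missense-dominated, with ~20%
  synonymous to exercise rejection); PolyPhen/SIFT scores for missense
  drawn from the benign or damaging region (30% benign), 5% unscored;
* genotypes binomial(2, AF) per sample (no Hardy–Weinberg violation, no LD
  between rare sites — real rare variants are nearly LD-free anyway); a
  0.2% missing-call rate, never applied to a singleton's carrier so the
  dataset allele count of singleton sites stays exactly 1;
* samples unrelated, with cohort label, ancestry mix, sex (55% female),
  age uniform in cohort-specific ranges (40–69 and 18–89 by default), a
  small categorical batch covariate with optional additive shift, and
  standard-normal PC-like covariates;
* quantitative traits: sum of per-gene burden effects (in SD units) over
  carriers of qualifying variants plus Gaussian noise; binary traits: a
  log-odds liability model with baseline logit at the stated prevalence —
  any generative model producing the stated prevalence and carrier
  enrichment would serve, this one is the simplest;
* `simulate_null_binary_collapse` draws carrier indicators directly at the
  collapsed scale for calibration experiments where variant-level structure
  is irrelevant.

Everything is deterministic given the configuration seed (numpy
`default_rng` with per-component seed sequences).

What passing tests on these data do **not** show: robustness to
relatedness and population stratification (handled by mixed models at
biobank scale, out of scope here), annotation error, genotyping batch
artifacts correlated with phenotype, LD with common causal variants, or
real phenotype distributions. The calibration claims are about the
statistical machinery, not about any biological dataset.

## 8. Calibration experiments and problem sizes

`raresweep.calibration` packages the simulation studies used by the test
suite and the reproduction script; sizes were chosen to give stable
estimates at single-CPU desk scale:

* **Inflation experiment**: one null binary trait, prevalence 1/23,
  n = 20,000 (≈ 870 cases), 2,000 genes with carrier frequencies
  log-uniform in [5e-5, 5e-3]; reports λ and tail excess for the ungated
  regression, the gated regression, and the Fisher fallback. Under these
  conditions the maximum expected-carrier count is carrier_freq × n_cases ≈
  4.4 < 10, so the E ≥ 10 gate passes no gene at all (its λ is NaN), and
  the ungated *median* λ is deflated (≈ 0.6) even though the tail shows a
  ~25-fold excess of p < 1e-4 — the discreteness effect described in §5.
  A variant of the experiment with carrier frequencies up to 5e-2 (as in
  `examples/04`) has gate-passing genes and shows the gated scan calibrated
  (λ ≈ 1) with no tail excess.
* **Effect recovery**: beta = 1.0 SD on 50 carriers in n = 10,000, 200
  replicates; the estimate falls within 2 estimated SE of the truth at the
  nominal ≈ 95% rate. Note that a pass criterion of "≥ 95% of replicates"
  sits exactly at the nominal coverage of a 2-SE interval (95.45%), so the
  observed rate hovers at the boundary by construction.
* **Type-I error**: null quantitative trait, n = 2,000, 4,000 genes with
  carrier frequencies in [5e-3, 5e-2], gated at ≥ 5 carriers; the fraction
  of p < 0.05 is ≈ 0.05.
* **Singleton/conditioning**: constructed genes at n = 4,000 with a 1.8 SD
  carrier effect — a 25-carrier signal with 84% singleton carriers (loses
  ≫ 2 orders of magnitude of significance without its singletons), a
  single-recurrent-variant gene (conditioning on the lead leaves only
  noise), and a 20-singleton + lead signal (conditional p stays far below
  5e-8).

## 9. Known limitations

* The mixed-model machinery of biobank practice is replaced by fixed-effect
  OLS on unrelated samples; inflation-control results transfer
  qualitatively, not as a statement about any specific LMM implementation.
* Logistic regression, SKAT/SKAT-O, dosage/weighted burden scores and
  recessive models are intentionally out of scope.
* Multi-allelic sites are assumed decomposed to biallelic records upstream.
* Protein-coordinate mapping is consumed from the annotation table; no
  transcript arithmetic is performed.
* The dense int8 genotype matrix targets desk-scale cohorts (≲ 10⁵ samples
  × 10⁴ variants), not biobank-scale storage.
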