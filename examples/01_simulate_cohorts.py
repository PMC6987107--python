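"""Simulate a synthetic two-cohort exome dataset and export it to disk.

Builds a variant pool (rare sites grouped into genes, with consequence terms,
PolyPhen/SIFT scores and reference-population frequencies), draws genotypes
for two cohorts, simulates one quantitative trait with an injected burden
effect and one imbalanced binary trait, and writes VCF/TSV/BED files.
"""

import pandas as pd

from raresweep import PhenotypeSpec, SimConfig
from raresweep.io import export_cohort
from raresweep.sim import (
    cds_intervals,
    covariate_table,
    high_confidence_intervals,
    two_cohort_dataset,
)

config = SimConfig(n_samples_per_cohort=1000, n_genes=40, mean_variants_per_gene=20, seed=42)
specs = (
    PhenotypeSpec("ldl_like", "quantitative", effect_genes={"gene0003": 1.0}),
    PhenotypeSpec.from_case_control_ratio("afib_like", "1:22"),
)
data = two_cohort_dataset(config, phenotype_specs=specs)

pool = data["pool"]
print(f"variant pool: {len(pool)} sites in {pool['gene'].nunique()} genes")
print(f"  singleton sites: {pool['is_singleton_site'].mean():.0%} "
      "(allele count exactly 1, absent from the reference)")

for name, cohort in data["cohorts"].items():
    gm = cohort["genotypes"]
    qs = cohort["qualifying_coding"]
    rows = []
    for pid, vec in cohort["phenotypes"].items():
        for sid, val in vec.values.items():
            rows.append({"sample_id": sid, "phenotype_id": pid, "value": val})
    manifest = pd.DataFrame(
        [{"phenotype_id": s.phenotype_id, "kind": s.kind, "sex_restriction": s.sex_restriction}
         for s in specs]
    )
    paths = export_cohort(
        f"scratch/example_cohorts/{name}",
        pool, gm, cohort["samples"], pd.DataFrame(rows), manifest,
        covariate_table(cohort["samples"]),
        cds_intervals(config), high_confidence_intervals(config),
    )
    afib = cohort["phenotypes"]["afib_like"].values
    print(f"{name}: {gm.n_samples} samples, {qs.n_qualifying} qualifying coding variants "
          f"in {len(qs.genes)} genes; binary trait case fraction {afib.mean():.3f} "
          f"(target 1/23 = {1 / 23:.3f})")
    print(f"  wrote {paths['vcf']}")
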