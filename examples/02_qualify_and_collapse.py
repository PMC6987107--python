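"""Qualify variants under the coding and LoF models and collapse one gene.

Shows the filter composition — consequence term, deleteriousness scores,
frequency in every reference population, region masks — and the per-gene
0/1 carrier indicator with its expected-carrier gate for a binary trait.
"""

from raresweep import (
    QualifyingConfig,
    SimConfig,
    build_qualifying_sets,
    carrier_gate,
    classify_model,
    collapse_gene,
    generate_genotypes,
    generate_variant_pool,
)
from raresweep.qualify import build_interval_tree
from raresweep.sim import cds_intervals, high_confidence_intervals

cfg = SimConfig(n_samples_per_cohort=2000, n_genes=30, mean_variants_per_gene=25, seed=5)
pool = generate_variant_pool(cfg)
gm, _ = generate_genotypes(pool, cfg)
qc = QualifyingConfig()  # MAF < 0.1% everywhere, PolyPhen/SIFT benign excluded

print("single-variant classification (coding, lof):")
for term, pp, sf in [("stop_gained", None, None),
                     ("missense_variant", 0.10, 0.50),
                     ("missense_variant", 0.90, 0.01),
                     ("synonymous_variant", None, None)]:
    print(f"  {term:22s} polyphen={pp} sift={sf} -> {classify_model(term, pp, sf, qc)}")

cds = build_interval_tree(cds_intervals(cfg))
hc = build_interval_tree(high_confidence_intervals(cfg))
for model in ("coding", "lof"):
    qs = build_qualifying_sets(pool, gm.allele_counts(), qc, model, cds, hc)
    print(f"{model}: {qs.n_qualifying} qualifying variants in {len(qs.genes)} genes "
          f"(rejected {qs.n_rejected} of {qs.n_input})")

qs = build_qualifying_sets(pool, gm.allele_counts(), qc, "coding", cds, hc)
gene = max(qs.genes, key=lambda g: len(qs.genes[g]))
cg = collapse_gene(gm, qs.genes[gene], gene=gene, model="coding")
print(f"\n{gene}: {len(qs.genes[gene])} qualifying variants -> "
      f"{cg.n_carriers} carriers ({cg.carrier_frequency:.2%} of samples)")

# a 1:22 binary trait in this cohort has ~87 cases (the smaller group)
gate = carrier_gate(cg, "binary", n_cases=87, n_controls=1913)
print(f"binary gate: expected carriers in smaller group = "
      f"{gate.expected_case_carriers:.2f} -> {'pass' if gate.verdict else 'fail'} "
      f"({gate.reason}); gate-failing genes route to Fisher's exact test")
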