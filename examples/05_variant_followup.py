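"""Decompose a significant gene signal into per-variant effects.

Builds a gene whose burden signal is spread over singletons plus one
recurrent variant, then runs the three follow-up analyses: per-variant
association, lead-variant conditioning, and singleton-removal sensitivity;
finishes with a protein-domain enrichment test on direction-consistent
missense variants.
"""

import numpy as np

from raresweep import DomainMap, domain_enrichment, select_lead_variant
from raresweep.calibration import (
    _effect_gene_fixture,
    _variant_effects,
    singleton_and_conditioning_experiment,
)
from raresweep.varlevel import VariantEffect

rng = np.random.default_rng(3)
gm, vids, flags, pheno = _effect_gene_fixture(
    n_samples=4000, singleton_carriers=20, recurrent_carriers=8, beta=1.5, rng=rng
)
effects = _variant_effects(gm, vids, flags, pheno)
lead = select_lead_variant(effects)
print(f"gene with {len(vids)} qualifying variants "
      f"({sum(flags.values())} singletons); lead variant (>=3 carriers, best p): {lead}")
best = min(effects, key=lambda e: e.p)
print(f"best single variant: {best.variant_id} "
      f"(carriers={best.n_carriers}, beta={best.beta:.2f}, p={best.p:.2e})")

res = singleton_and_conditioning_experiment(seed=3)
print(f"\nsingleton-dominated gene: p with singletons {res['singleton_p_with']:.2e}, "
      f"without {res['singleton_p_without']:.2e} "
      f"({res['singleton_orders_worse']:.1f} orders of magnitude worse)")
rc = res["recurrent_conditional_p"]
print(f"single-recurrent-variant gene conditioned on its lead: p = {rc:.3f} "
      f"({'no residual signal: driven by the lead' if rc > 0.05 else 'residual noise only'})")
print(f"distributed 20-singleton signal conditioned on its lead: "
      f"p = {res['distributed_conditional_p']:.2e} (signal survives)")

# domain enrichment: negative-beta missense variants clustered in a domain
dm = DomainMap(gene="G", protein_length=300, domains=((30, 90), (150, 210)),
               adjacency_margin=1)
enr = []
for i in range(16):  # direction-consistent, mostly in-domain
    enr.append(VariantEffect(f"d{i}", "G", 2, -1.0, 0.01, -1,
                             protein_position=40 + i if i < 13 else 250 + i))
for i in range(10):  # opposite direction, mostly outside
    enr.append(VariantEffect(f"u{i}", "G", 2, 1.0, 0.5, 1,
                             protein_position=230 + i if i < 8 else 60 + i))
p, table = domain_enrichment(enr, dm, direction_of_interest=-1)
print(f"\ndomain enrichment 2x2 {table.tolist()} -> Fisher p = {p:.4f}")
print("(rows: direction-consistent vs not; columns: in/adjacent vs outside the domain)")
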