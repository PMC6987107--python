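import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from raresweep import (
    PhenotypeSpec,
    QualifyingConfig,
    SimConfig,
    build_qualifying_sets,
    generate_genotypes,
    generate_variant_pool,
)
from raresweep.qualify import build_interval_tree
from raresweep.sim import cds_intervals, covariate_table, high_confidence_intervals


@pytest.fixture(scope="session")
def small_config():
    return SimConfig(
        n_samples_per_cohort=600,
        n_genes=30,
        mean_variants_per_gene=12,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_cohort(small_config):
    """Pool, genotypes, samples and coding qualifying sets for one small cohort."""
    pool = generate_variant_pool(small_config)
    gm, samples = generate_genotypes(pool, small_config, cohort="cohA", cohort_index=0)
    cds = build_interval_tree(cds_intervals(small_config))
    hc = build_interval_tree(high_confidence_intervals(small_config))
    qsets = build_qualifying_sets(
        pool, gm.allele_counts(), QualifyingConfig(), "coding", cds, hc
    )
    return {
        "config": small_config,
        "pool": pool,
        "genotypes": gm,
        "samples": samples,
        "covariates": covariate_table(samples),
        "cds": cds,
        "hc": hc,
        "qualifying": qsets,
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


@pytest.fixture()
def toy_variants():
    """Three-variant gene exercising the classic filter composition."""
    return pd.DataFrame(
        {
            "variant_id": ["v1", "v2", "v3"],
            "chrom": ["1"] * 3,
            "pos": [100, 110, 120],
            "gene": ["G1"] * 3,
            "consequence": ["missense_variant", "stop_gained", "missense_variant"],
            "polyphen": [0.05, np.nan, 0.9],
            "sift": [0.5, np.nan, 0.01],
            "af_NFE": [1e-4, 0.0, 0.01],
            "reference_allele_count": [10, 0, 1200],
        }
    )
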