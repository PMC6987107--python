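"""Synthetic two-cohort exome data with the structure the analysis assumes.

Real inputs for a rare-variant collapsing PheWAS (biobank exomes with linked
phenotypes) are access-restricted, so this module generates cohorts with the
relevant statistical structure: rare variant sites (allele frequencies below
the qualifying cutoff, a large singleton fraction) grouped into genes and
annotated with consequence terms and PolyPhen/SIFT scores; unrelated samples
with cohort, ancestry, sex, age, batch and principal-component covariates;
and phenotypes — rank-normalizable quantitative traits and binary traits at
a configurable prevalence (including severe case:control imbalance) — with
optional per-gene burden effects on carriers of qualifying variants.

Defaults echo large exome cohorts: a mean of 34 qualifying coding variants
per gene, a 38% singleton fraction, a 0.1% frequency cutoff, ages uniform in
cohort-specific ranges, and a small categorical batch covariate.

Everything is deterministic given the configuration seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .assoc import PhenotypeVector
from .errors import ConfigError
from .qualify import CODING_TERMS, QualifyingSets

_BASES = ("A", "C", "G", "T")

DEFAULT_CONSEQUENCE_MIX = {
    "missense_variant": 0.52,
    "synonymous_variant": 0.20,
    "stop_gained": 0.06,
    "frameshift_variant": 0.06,
    "splice_acceptor_variant": 0.03,
    "splice_donor_variant": 0.03,
    "inframe_deletion": 0.03,
    "inframe_insertion": 0.03,
    "start_lost": 0.02,
    "stop_lost": 0.02,
}


@dataclass
class SimConfig:
    """Generator settings for one synthetic cohort.

    ``mean_variants_per_gene`` controls a shifted-Poisson count (always
    >= 1 variant per gene); ``maf_spectrum`` is log-uniform on
    ``[maf_low, maf_cutoff)``; a ``singleton_fraction`` of sites instead get
    exactly one alternate allele in the dataset and a reference frequency of
    zero. ``benign_fraction`` of scored missense variants draw their
    PolyPhen/SIFT scores from the benign region. ``common_fraction`` sites
    (default 0) exceed the frequency cutoff, to exercise the frequency
    filter downstream.
    """

    n_samples_per_cohort: int = 2000
    n_genes: int = 100
    mean_variants_per_gene: float = 34.0
    maf_cutoff: float = 1e-3
    maf_low: float = 2e-5
    singleton_fraction: float = 0.38
    common_fraction: float = 0.0
    consequence_mix: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CONSEQUENCE_MIX)
    )
    benign_fraction: float = 0.30
    score_missing_rate: float = 0.05
    ancestry_groups: Mapping[str, float] = field(default_factory=lambda: {"EUR": 1.0})
    reference_populations: tuple = ("AFR", "NFE", "EAS", "SAS")
    reference_n: int = 60_000
    filter_fail_rate: float = 0.01
    missing_rate: float = 0.002
    hc_exclude_fraction: float = 0.05
    gene_span: int = 6000
    female_fraction: float = 0.55
    age_range: tuple = (40, 69)
    n_batches: int = 2
    n_pcs: int = 10
    seed: int = 0

    def __post_init__(self):
        for name in (
            "singleton_fraction",
            "common_fraction",
            "benign_fraction",
            "score_missing_rate",
            "filter_fail_rate",
            "missing_rate",
            "hc_exclude_fraction",
            "female_fraction",
        ):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ConfigError(f"{name} must lie in [0, 1], got {v}")
        for mix_name in ("consequence_mix", "ancestry_groups"):
            mix = getattr(self, mix_name)
            if not mix:
                raise ConfigError(f"{mix_name} must be nonempty")
            if any(w < 0 for w in mix.values()) or abs(sum(mix.values()) - 1.0) > 1e-9:
                raise ConfigError(f"{mix_name} weights must be nonnegative and sum to 1")
        if not (0.0 < self.maf_low < self.maf_cutoff < 1.0):
            raise ConfigError("need 0 < maf_low < maf_cutoff < 1")
        if self.n_samples_per_cohort < 1 or self.n_genes < 1:
            raise ConfigError("cohort and gene counts must be positive")
        if self.mean_variants_per_gene < 1.0:
            raise ConfigError("mean_variants_per_gene must be >= 1")


@dataclass
class PhenotypeSpec:
    """Generative description of one phenotype.

    ``effect_genes`` maps gene -> effect size: for quantitative traits the
    additive shift (in phenotype SD units) applied to carriers of qualifying
    variants in that gene; for binary traits a log-odds shift on the carrier's
    case probability.
    """

    phenotype_id: str
    kind: str  # binary | quantitative
    prevalence: float | None = None
    effect_genes: Mapping[str, float] = field(default_factory=dict)
    sex_restriction: str = "none"
    noise_sd: float = 1.0
    batch_shift: float = 0.0  # additive per-batch-code shift (quantitative only)

    def __post_init__(self):
        if self.kind not in ("binary", "quantitative"):
            raise ConfigError(f"kind must be binary or quantitative, got {self.kind!r}")
        if self.kind == "binary":
            if self.prevalence is None or not (0.0 < self.prevalence < 1.0):
                raise ConfigError("binary phenotype needs prevalence in (0, 1)")
        if self.noise_sd <= 0:
            raise ConfigError("noise_sd must be positive")
        if self.sex_restriction not in ("none", "female", "male"):
            raise ConfigError(f"invalid sex_restriction {self.sex_restriction!r}")

    @classmethod
    def from_case_control_ratio(cls, phenotype_id: str, ratio: str, **kwargs) -> "PhenotypeSpec":
        """Build a binary spec from ratio notation, e.g. ``"1:22"`` -> prevalence 1/23."""
        cases, controls = (float(x) for x in ratio.split(":"))
        return cls(
            phenotype_id=phenotype_id,
            kind="binary",
            prevalence=cases / (cases + controls),
            **kwargs,
        )


def _gene_intervals(config: SimConfig):
    """(start, end) half-open genomic span per gene, well separated."""
    spans = []
    for g in range(config.n_genes):
        start = 10_000 + g * (config.gene_span + 4_000)
        spans.append((start, start + config.gene_span))
    return spans


def high_confidence_intervals(config: SimConfig):
    """High-confidence mask: each gene span minus its trailing fraction."""
    out = []
    for start, end in _gene_intervals(config):
        cut = end - int(round(config.hc_exclude_fraction * (end - start)))
        out.append((start, cut))
    return out


def cds_intervals(config: SimConfig):
    return _gene_intervals(config)


def generate_variant_pool(config: SimConfig) -> pd.DataFrame:
    """Simulate the variant sites table for one cohort pair.

    Columns: ``variant_id, chrom, pos, ref, alt, gene, consequence, polyphen,
    sift, protein_position, target_af, is_singleton_site, filter,
    reference_allele_count`` plus one ``af_<pop>`` reference-frequency column
    per configured population. Reference frequencies of rare sites stay
    strictly below the cutoff; singleton sites are absent from the reference.
    """
    rng = np.random.default_rng([config.seed, 0])
    spans = _gene_intervals(config)
    terms = list(config.consequence_mix)
    term_p = np.array([config.consequence_mix[t] for t in terms])

    rows = []
    used_pos = set()
    for g, (start, end) in enumerate(spans):
        gene = f"gene{g:04d}"
        n_var = 1 + rng.poisson(config.mean_variants_per_gene - 1.0)
        pos_candidates = rng.choice(np.arange(start, end), size=min(n_var, end - start), replace=False)
        for pos in np.sort(pos_candidates):
            pos = int(pos)
            if pos in used_pos:
                continue
            used_pos.add(pos)
            consequence = terms[rng.choice(len(terms), p=term_p)]
            polyphen = sift = np.nan
            if consequence == "missense_variant" and rng.random() >= config.score_missing_rate:
                if rng.random() < config.benign_fraction:
                    polyphen = rng.uniform(0.0, 0.15)
                    sift = rng.uniform(0.051, 1.0)
                else:
                    polyphen = rng.uniform(0.15, 1.0)
                    sift = rng.uniform(0.0, 0.05)
            singleton_site = bool(rng.random() < config.singleton_fraction)
            common_site = (not singleton_site) and rng.random() < config.common_fraction
            if singleton_site:
                target_af = 0.5 / config.n_samples_per_cohort
            elif common_site:
                target_af = float(
                    np.exp(rng.uniform(np.log(config.maf_cutoff), np.log(0.05)))
                )
            else:
                target_af = float(
                    np.exp(rng.uniform(np.log(config.maf_low), np.log(config.maf_cutoff)))
                )
            ref, alt = rng.choice(_BASES, size=2, replace=False)
            row = {
                "variant_id": f"1-{pos}-{ref}-{alt}",
                "chrom": "1",
                "pos": pos,
                "ref": ref,
                "alt": alt,
                "gene": gene,
                "consequence": consequence,
                "polyphen": polyphen,
                "sift": sift,
                "protein_position": (pos - start) // 3 + 1,
                "target_af": target_af,
                "is_singleton_site": singleton_site,
                "filter": "PASS" if rng.random() >= config.filter_fail_rate else "LowQual",
            }
            ref_ac_total = 0
            for pop in config.reference_populations:
                if singleton_site:
                    af = 0.0
                else:
                    af = target_af * float(rng.lognormal(0.0, 0.25))
                    cap = (0.05 if common_site else config.maf_cutoff) * 0.999
                    af = min(af, cap)
                row[f"af_{pop}"] = af
                ref_ac_total += int(round(af * 2 * config.reference_n))
            row["reference_allele_count"] = ref_ac_total
            rows.append(row)
    pool = pd.DataFrame(rows).sort_values("pos").reset_index(drop=True)
    return pool


def generate_genotypes(pool: pd.DataFrame, config: SimConfig, cohort: str = "cohortA", cohort_index: int = 0):
    """Draw genotypes and a sample table for one cohort.

    Genotype dosages are binomial(2, target_af) per sample; singleton sites
    place exactly one heterozygous carrier. A small missing-call rate is
    applied (never to the singleton carrier, so dataset allele counts of
    singleton sites are exactly 1). Returns ``(GenotypeMatrix, samples)``.
    """
    from .io import MISSING, GenotypeMatrix

    if pool.empty:
        raise ConfigError("variant pool is empty")
    rng = np.random.default_rng([config.seed, 1, cohort_index])
    n = config.n_samples_per_cohort
    n_var = len(pool)
    data = np.zeros((n, n_var), dtype=np.int8)
    afs = pool["target_af"].to_numpy()
    singleton = pool["is_singleton_site"].to_numpy()

    for j in range(n_var):
        if singleton[j]:
            data[rng.integers(0, n), j] = 1
        elif afs[j] > 0:
            data[:, j] = rng.binomial(2, afs[j], size=n).astype(np.int8)
    if config.missing_rate > 0:
        miss = rng.random((n, n_var)) < config.missing_rate
        # keep singleton carriers callable so dataset AC stays exactly 1
        miss[:, singleton] &= data[:, singleton] == 0
        data[miss] = MISSING

    sample_ids = tuple(f"{cohort}_s{i:05d}" for i in range(n))
    ancestries = list(config.ancestry_groups)
    anc_p = np.array([config.ancestry_groups[a] for a in ancestries])
    samples = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "cohort": cohort,
            "ancestry": [ancestries[k] for k in rng.choice(len(ancestries), size=n, p=anc_p)],
            "sex": np.where(rng.random(n) < config.female_fraction, "F", "M"),
            "age": rng.integers(config.age_range[0], config.age_range[1] + 1, size=n),
            "batch": [f"b{k}" for k in rng.integers(0, config.n_batches, size=n)],
        }
    )
    for k in range(config.n_pcs):
        samples[f"pc{k + 1}"] = rng.standard_normal(n)
    gm = GenotypeMatrix(
        data=data, sample_ids=sample_ids, variant_ids=tuple(pool["variant_id"])
    )
    return gm, samples


def covariate_table(samples: pd.DataFrame, n_pcs: int = 10) -> pd.DataFrame:
    """Numeric covariate table (age, sex, batch, PCs) indexed by sample id."""
    cov = pd.DataFrame(index=samples["sample_id"].to_numpy())
    cov["age"] = samples["age"].to_numpy(dtype=float)
    cov["sex"] = (samples["sex"] == "F").to_numpy(dtype=float)
    batches = sorted(samples["batch"].unique())
    for b in batches[1:]:  # first batch is the reference level
        cov[f"batch_{b}"] = (samples["batch"] == b).to_numpy(dtype=float)
    for k in range(n_pcs):
        col = f"pc{k + 1}"
        if col in samples.columns:
            cov[col] = samples[col].to_numpy(dtype=float)
    return cov


def simulate_phenotype(
    genotypes,
    qualifying: QualifyingSets,
    spec: PhenotypeSpec,
    samples: pd.DataFrame | None = None,
    seed: int = 0,
) -> PhenotypeVector:
    """Simulate one phenotype over a cohort.

    Quantitative: value = sum over effect genes of (beta x carrier
    indicator) + Gaussian noise, optionally plus a batch shift. Binary: a
    log-odds (liability) model — the baseline logit matches the stated
    prevalence and carriers of qualifying variants in effect genes are
    shifted by the configured log-odds. Sex restriction is recorded on the
    vector; masking happens at encoding/analysis time.
    """
    for g in spec.effect_genes:
        if g not in qualifying.genes:
            raise ConfigError(
                f"effect gene {g!r} has no qualifying variants in the {qualifying.model} model"
            )
    rng = np.random.default_rng([seed, 2])
    n = genotypes.n_samples
    shift = np.zeros(n)
    for g, beta in spec.effect_genes.items():
        shift += float(beta) * genotypes.carrier_indicator(qualifying.genes[g])

    if spec.kind == "quantitative":
        y = shift + rng.normal(0.0, spec.noise_sd, size=n)
        if spec.batch_shift and samples is not None and "batch" in samples.columns:
            codes = pd.factorize(samples["batch"])[0]
            y = y + codes * spec.batch_shift
    else:
        eta = logit(spec.prevalence) + shift
        y = (rng.random(n) < expit(eta)).astype(float)
    values = pd.Series(y, index=list(genotypes.sample_ids), dtype=float)
    return PhenotypeVector(
        phenotype_id=spec.phenotype_id,
        kind=spec.kind,
        values=values,
        sex_restriction=spec.sex_restriction,
    )


# ---------------------------------------------------------------------------
# Direct collapsed-scale simulation (for calibration experiments)


def simulate_null_binary_collapse(
    n_samples: int,
    prevalence: float,
    carrier_frequencies,
    seed: int = 0,
):
    """Null binary trait plus per-gene carrier indicators, drawn directly.

    For calibration experiments at the collapsed scale it is enough to draw
    each gene's carrier indicator Bernoulli(carrier frequency) and the trait
    Bernoulli(prevalence), independently — exactly the null the carrier gates
    are designed for. Returns ``(y, indicators)`` with indicators of shape
    ``(n_samples, n_genes)``.
    """
    rng = np.random.default_rng([seed, 3])
    cf = np.asarray(carrier_frequencies, dtype=float)
    y = (rng.random(n_samples) < prevalence).astype(float)
    indicators = (rng.random((n_samples, cf.size)) < cf[None, :]).astype(np.int8)
    return y, indicators


def log_uniform(low: float, high: float, size: int, seed: int = 0) -> np.ndarray:
    """Log-uniform draws on [low, high)."""
    rng = np.random.default_rng([seed, 4])
    return np.exp(rng.uniform(np.log(low), np.log(high), size))


def two_cohort_dataset(
    config: SimConfig,
    phenotype_specs=(),
    cohort_names=("cohortA", "cohortB"),
    cohort_sizes=None,
    age_ranges=((40, 69), (18, 89)),
):
    """Convenience wrapper: one variant pool, two cohorts drawn from it.

    Returns a dict with the pool and, per cohort, genotypes, samples and raw
    phenotype vectors (simulated with the cohort's genotypes against a
    coding-model qualifying set built with default filters).
    """
    from .qualify import QualifyingConfig, build_interval_tree, build_qualifying_sets

    pool = generate_variant_pool(config)
    cds = build_interval_tree(cds_intervals(config))
    hc = build_interval_tree(high_confidence_intervals(config))
    out = {"pool": pool, "cohorts": {}}
    for i, name in enumerate(cohort_names):
        cfg = config
        if cohort_sizes is not None:
            cfg = replace(cfg, n_samples_per_cohort=cohort_sizes[i])
        if age_ranges is not None:
            cfg = replace(cfg, age_range=age_ranges[i])
        gm, samples = generate_genotypes(pool, cfg, cohort=name, cohort_index=i)
        qsets = build_qualifying_sets(
            pool, gm.allele_counts(), QualifyingConfig(), "coding", cds, hc
        )
        phenos = {
            spec.phenotype_id: simulate_phenotype(
                gm, qsets, spec, samples, seed=config.seed + 17 * i
            )
            for spec in phenotype_specs
        }
        out["cohorts"][name] = {
            "genotypes": gm,
            "samples": samples,
            "qualifying_coding": qsets,
            "phenotypes": phenos,
        }
    out["cds"] = cds
    out["high_confidence"] = hc
    return out
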