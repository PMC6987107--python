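"""End-to-end orchestration of the two-cohort collapsing PheWAS.

Per cohort: qualify variants per model, collapse per gene, gate per
phenotype, run the routed tests (regression and/or Fisher), and emit an
inflation report per phenotype x model. Across cohorts: weighted-Z
meta-analysis with the qualification gates for shared phenotypes, a
single-cohort track for phenotypes unique to one cohort, significance
calling against the Bonferroni threshold, and a replication screen mode.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import __version__
from .assoc import (
    AssociationResult,
    PhenotypeVector,
    burden_regression,
    encode_binary,
    fisher_burden,
    inclusion_filter,
    prepare_quantitative,
    route_test,
)
from .collapse import collapse_gene, carrier_gate
from .diagnostics import inflation_report
from .errors import DataError
from .io import CohortData
from .meta import MetaResult, meta_gate, weighted_z_meta
from .qualify import QualifyingConfig, build_qualifying_sets

logger = logging.getLogger(__name__)

MODELS = ("coding", "lof")

ASSOC_COLUMNS = [
    "cohort",
    "gene",
    "model",
    "phenotype",
    "test",
    "beta",
    "direction",
    "p",
    "n",
    "n_carriers",
    "case_carriers",
    "control_carriers",
    "gate_verdict",
]


@dataclass
class CohortResults:
    name: str
    associations: pd.DataFrame
    inflation: dict  # (phenotype, model, test) -> InflationReport
    collapsed: dict  # (model, gene) -> CollapsedGene
    qualifying: dict  # model -> QualifyingSets
    phenotypes: dict  # phenotype_id -> PhenotypeVector
    funnel: dict = field(default_factory=dict)


def prepare_phenotypes(cohort: CohortData) -> dict:
    """Build PhenotypeVectors from the cohort's long phenotype table + manifest."""
    out = {}
    for row in cohort.manifest.itertuples(index=False):
        pid = row.phenotype_id
        sub = cohort.phenotypes[cohort.phenotypes["phenotype_id"] == pid]
        try:
            if row.kind == "quantitative":
                out[pid] = PhenotypeVector(
                    phenotype_id=pid,
                    kind="quantitative",
                    values=prepare_quantitative(sub, phenotype_id=pid).values,
                )
            else:
                cases = sub.loc[sub["value"] == 1, "sample_id"]
                out[pid] = encode_binary(
                    cases,
                    cohort.samples,
                    phenotype_id=pid,
                    sex_restriction=getattr(row, "sex_restriction", "none") or "none",
                )
        except DataError as e:
            logger.warning("phenotype %s dropped: %s", pid, e)
    return out


def run_cohort(
    cohort: CohortData,
    qualifying_config: QualifyingConfig | None = None,
    phenotypes: dict | None = None,
    models=MODELS,
    apply_inclusion: bool = False,
) -> CohortResults:
    """Qualification -> collapse -> gate -> association for one cohort.

    Returns per-gene association rows (regression where the gate passes,
    Fisher for gate-failing binary genes) and one inflation report per
    phenotype x model x test. Stage errors are logged with gene/phenotype
    context and the run continues.
    """
    qc = qualifying_config or QualifyingConfig()
    phenos = phenotypes if phenotypes is not None else prepare_phenotypes(cohort)
    acounts = cohort.genotypes.allele_counts()
    covariates = cohort.covariates

    qualifying = {}
    collapsed = {}
    rows = []
    inflation = {}
    funnel = {"n_variants_input": len(cohort.variants)}

    for model in models:
        qsets = build_qualifying_sets(
            cohort.variants, acounts, qc, model, cohort.cds, cohort.high_confidence
        )
        qualifying[model] = qsets
        funnel[f"n_qualifying_{model}"] = qsets.n_qualifying
        funnel[f"n_genes_{model}"] = len(qsets.genes)
        for gene, ids in qsets.genes.items():
            collapsed[(model, gene)] = collapse_gene(
                cohort.genotypes, ids, gene=gene, model=model
            )

    for pid, pheno in phenos.items():
        if apply_inclusion:
            ok, reason = inclusion_filter([pheno])
            if not ok:
                logger.info("phenotype %s excluded: %s", pid, reason)
                continue
        phenotyped = pheno.values.notna()
        for model in models:
            pvals = {"regression": [], "fisher": []}
            for gene, ids in qualifying[model].genes.items():
                cg = collapsed[(model, gene)]
                ind = pd.Series(cg.indicator, index=list(cg.sample_ids))
                ind_ph = ind[phenotyped.reindex(ind.index, fill_value=False)]
                n_carriers_ph = int((ind_ph > 0).sum())
                try:
                    if pheno.kind == "binary":
                        gate = carrier_gate(
                            cg,
                            "binary",
                            phenotype=pid,
                            n_cases=pheno.n_cases,
                            n_controls=pheno.n_controls,
                            carrier_frequency=(
                                float(ind_ph.mean()) if len(ind_ph) else 0.0
                            ),
                            n_carriers_phenotyped=n_carriers_ph,
                        )
                    else:
                        gate = carrier_gate(
                            cg, "quantitative", phenotype=pid,
                            n_carriers_phenotyped=n_carriers_ph,
                        )
                    plan = route_test(pheno.kind, gate)
                    for test in plan:
                        if test == "regression":
                            if n_carriers_ph == 0:
                                continue
                            res = burden_regression(
                                cg.indicator,
                                pheno,
                                covariates,
                                sample_ids=cg.sample_ids,
                                gene=gene,
                                model=model,
                                cohort=cohort.name,
                            )
                        else:
                            vals = pheno.values.reindex(ind.index)
                            carrier = ind > 0
                            a = int(((vals == 1) & carrier).sum())
                            b = int((vals == 1).sum()) - a
                            c = int(((vals == 0) & carrier).sum())
                            d = int((vals == 0).sum()) - c
                            res = fisher_burden(
                                a, b, c, d,
                                gene=gene, model=model, phenotype=pid, cohort=cohort.name,
                            )
                        res.gate_verdict = gate.verdict
                        rows.append(res)
                        pvals[res.test].append(res.p)
                except DataError as e:
                    logger.warning("%s/%s/%s: %s", pid, model, gene, e)
            for test, ps in pvals.items():
                if ps:
                    inflation[(pid, model, test)] = inflation_report(
                        ps, label=f"{cohort.name}:{pid}:{model}:{test}"
                    )

    assoc_df = _results_frame(rows)
    return CohortResults(
        name=cohort.name,
        associations=assoc_df,
        inflation=inflation,
        collapsed=collapsed,
        qualifying=qualifying,
        phenotypes=phenos,
        funnel=funnel,
    )


def _results_frame(rows) -> pd.DataFrame:
    if not rows:
        return pd.DataFrame(columns=ASSOC_COLUMNS)
    recs = []
    for r in rows:
        d = dataclasses.asdict(r)
        d.pop("extra", None)
        recs.append(d)
    return pd.DataFrame(recs)[ASSOC_COLUMNS]


def run_meta(
    results_a: CohortResults,
    results_b: CohortResults,
    min_expected: float = 10.0,
    use_effective_n: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Meta-analyze two cohorts' association tables.

    Shared phenotypes are combined with the weighted-Z method (the main-path
    test per gene: regression when both cohorts ran it, otherwise Fisher) and
    the meta-qualification gates are applied. Phenotypes unique to one cohort
    pass through unchanged as the single-cohort track. Returns
    ``(meta_frame, single_cohort_frame)``.
    """
    from .meta import effective_sample_size

    a, b = results_a.associations, results_b.associations
    shared = set(a["phenotype"]) & set(b["phenotype"])
    singles = pd.concat(
        [a[~a["phenotype"].isin(shared)], b[~b["phenotype"].isin(shared)]],
        ignore_index=True,
    )

    rows = []
    key = ["gene", "model", "phenotype", "test"]
    ia = a.set_index(key)
    ib = b.set_index(key)
    common = ia.index.intersection(ib.index)
    for idx in common:
        gene, model, pid, test = idx
        ra, rb = ia.loc[idx], ib.loc[idx]
        if isinstance(ra, pd.DataFrame) or isinstance(rb, pd.DataFrame):
            raise DataError(f"duplicate association rows for {idx}")
        kind = results_a.phenotypes[pid].kind
        if use_effective_n and kind == "binary":
            stats_pairs = [
                (float(r["p"]), int(r["direction"]),
                 effective_sample_size(res.phenotypes[pid].n_cases,
                                       res.phenotypes[pid].n_controls))
                for r, res in ((ra, results_a), (rb, results_b))
            ]
        else:
            stats_pairs = [
                (float(r["p"]), int(r["direction"]), int(r["n"])) for r in (ra, rb)
            ]
        m = weighted_z_meta(stats_pairs, gene=gene, model=model, phenotype=pid)

        pooled_ind = np.concatenate(
            [
                results_a.collapsed[(model, gene)].indicator,
                results_b.collapsed[(model, gene)].indicator,
            ]
        )
        pooled_cf = float(pooled_ind.mean())
        pooled_smaller = None
        if kind == "binary":
            n_cases = results_a.phenotypes[pid].n_cases + results_b.phenotypes[pid].n_cases
            n_ctrl = (
                results_a.phenotypes[pid].n_controls + results_b.phenotypes[pid].n_controls
            )
            pooled_smaller = min(n_cases, n_ctrl)
        m = meta_gate(
            m,
            [int(ra["n_carriers"]), int(rb["n_carriers"])],
            kind,
            pooled_carrier_frequency=pooled_cf,
            pooled_n_smaller_group=pooled_smaller,
            min_expected=min_expected,
        )
        rows.append(
            {
                "gene": gene,
                "model": model,
                "phenotype": pid,
                "test": test,
                "combined_z": m.combined_z,
                "combined_p": m.combined_p,
                "p_a": m.cohort_p[0],
                "p_b": m.cohort_p[1],
                "gate_both_carriers": m.gates["both_cohorts_have_carriers"],
                "gate_meta_p_better": m.gates["meta_p_better_than_each"],
                "gate_pooled_expected": m.gates.get("pooled_expected_ge_min", True),
                "qualified": m.qualified,
            }
        )
    meta_df = pd.DataFrame(rows)
    return meta_df, singles


def replication_screen(
    discovery: pd.DataFrame,
    replication: pd.DataFrame,
    alpha: float = 0.05,
    discovery_threshold: float | None = None,
) -> pd.DataFrame:
    """Per-association replication verdicts.

    ``discovery`` rows significant at ``discovery_threshold`` (or all rows if
    None) are looked up in ``replication`` by gene x model x phenotype;
    verdicts record direction consistency, nominal replication (p < 0.05)
    and Bonferroni replication (p < alpha / n_discovery_hits). Missing
    replication entries get verdict ``untested``.
    """
    hits = discovery
    if discovery_threshold is not None:
        hits = discovery[discovery["p"] < discovery_threshold]
    n_hits = len(hits)
    if n_hits == 0:
        return pd.DataFrame(
            columns=["gene", "model", "phenotype", "verdict", "direction_consistent",
                     "nominal", "bonferroni", "replication_p"]
        )
    bonf = alpha / n_hits
    rep = replication.set_index(["gene", "model", "phenotype"])
    rows = []
    for r in hits.itertuples(index=False):
        key = (r.gene, r.model, r.phenotype)
        row = {"gene": r.gene, "model": r.model, "phenotype": r.phenotype,
               "direction_consistent": None, "nominal": False, "bonferroni": False,
               "replication_p": np.nan}
        if key not in rep.index:
            row["verdict"] = "untested"
        else:
            rr = rep.loc[key]
            same_dir = int(rr["direction"]) == int(r.direction)
            p = float(rr["p"])
            row.update(
                direction_consistent=same_dir,
                replication_p=p,
                nominal=same_dir and p < 0.05,
                bonferroni=same_dir and p < bonf,
            )
            row["verdict"] = (
                "bonferroni" if row["bonferroni"]
                else "nominal" if row["nominal"]
                else "direction" if same_dir
                else "inconsistent"
            )
        rows.append(row)
    out = pd.DataFrame(rows)
    out.attrs["bonferroni_bar"] = bonf
    return out


def write_outputs(outdir, cohort_results=(), meta_df=None, singles_df=None,
                  manifest_extra=None) -> None:
    """Write TSV outputs plus a JSON run manifest."""
    os.makedirs(outdir, exist_ok=True)
    for cr in cohort_results:
        cr.associations.to_csv(
            os.path.join(outdir, f"associations_{cr.name}.tsv"), sep="\t", index=False
        )
        inf = pd.DataFrame(
            [
                {
                    "phenotype": k[0], "model": k[1], "test": k[2],
                    "n_tests": r.n_tests, "lambda": r.lam,
                    "tail_observed": r.tail_observed, "tail_expected": r.tail_expected,
                }
                for k, r in cr.inflation.items()
            ]
        )
        inf.to_csv(os.path.join(outdir, f"inflation_{cr.name}.tsv"), sep="\t", index=False)
    if meta_df is not None:
        meta_df.to_csv(os.path.join(outdir, "meta.tsv"), sep="\t", index=False)
    if singles_df is not None:
        singles_df.to_csv(os.path.join(outdir, "single_cohort.tsv"), sep="\t", index=False)
    manifest = {"package_version": __version__}
    manifest.update(manifest_extra or {})
    with open(os.path.join(outdir, "run_manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
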