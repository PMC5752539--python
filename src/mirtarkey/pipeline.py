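"""End-to-end orchestration of the key-interaction pipeline.

``run_pipeline`` strings the stages together on an in-memory cohort:
filter -> normalize -> differential expression -> dysregulated-interaction
screen -> resampled-Cox selection -> network topology -> hallmark RWR ->
signature evaluation.  ``load_cohort`` reads a cohort from the on-disk
layout the simulator writes, so the same entry point serves simulated and
user-provided data.
"""

from __future__ import annotations

import logging
import os
import time
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from . import io as mio
from .config import RunConfig
from .datatypes import ClinicalTable, ExpressionMatrix, GeneSetCollection
from .evaluate import (
    PatientClustering,
    SignatureEvaluation,
    baseline_comparison,
    cluster_patients,
    evaluate_signature,
    ratio_matrix,
    secondary_outcome_tests,
)
from .hallmark import hallmark_permutation_test
from .preprocess import (
    dichotomize_by_median,
    differential_expression,
    filter_low_expression,
    normalize,
)
from .screen import candidate_pairs, screen_dysregulated
from .simulate import SimulatedCohort
from .survival import KeyInteractionModel, KeyInteractionResults
from .topology import PowerLawFit, build_network, degree_powerlaw_fit, find_hubs

logger = logging.getLogger(__name__)

__all__ = ["PipelineResult", "run_pipeline", "load_cohort", "MIN_READS_GENE", "MIN_READS_MIRNA"]

MIN_READS_GENE = 10
MIN_READS_MIRNA = 2


@dataclass
class PipelineResult:
    """Everything one pipeline run produces."""

    config: RunConfig
    mirna_log: ExpressionMatrix
    mrna_log: ExpressionMatrix
    mirna_de: pd.DataFrame
    gene_de: pd.DataFrame
    dysregulated: pd.DataFrame
    selection: KeyInteractionResults | None = None
    network: nx.Graph | None = None
    powerlaw: PowerLawFit | None = None
    hubs: list[str] = field(default_factory=list)
    hallmark_scores: pd.DataFrame | None = None
    clustering: PatientClustering | None = None
    signature: SignatureEvaluation | None = None
    baselines: pd.DataFrame | None = None
    secondary: pd.DataFrame | None = None

    @property
    def key_interactions(self) -> pd.DataFrame:
        if self.selection is None:
            return pd.DataFrame(columns=["mirna", "target"])
        return self.selection.key_interactions

    def write(self, out_dir: str) -> None:
        tables = {
            "mirna_de": self.mirna_de.reset_index(names="feature"),
            "gene_de": self.gene_de.reset_index(names="feature"),
            "dysregulated_interactions": self.dysregulated,
            "key_interactions": self.key_interactions,
        }
        if self.selection is not None:
            tables["selection_diagnostics"] = self.selection.diagnostics
        if self.hallmark_scores is not None:
            tables["hallmark_scores"] = self.hallmark_scores
        if self.baselines is not None:
            tables["baselines"] = self.baselines
        if self.secondary is not None:
            tables["secondary_tests"] = self.secondary
        if self.clustering is not None:
            tables["clustering"] = self.clustering.labels.reset_index().rename(
                columns={"index": "sample"}
            )
        mio.write_results(tables, out_dir, config=self.config)
        if self.network is not None:
            mio.write_edge_list(self.network, os.path.join(out_dir, "network.tsv"))
        if self.powerlaw is not None:
            pd.DataFrame(
                {
                    "metric": ["slope", "intercept", "r_squared", "p_value"],
                    "value": [
                        self.powerlaw.slope,
                        self.powerlaw.intercept,
                        self.powerlaw.r_squared,
                        self.powerlaw.p_value,
                    ],
                }
            ).to_csv(os.path.join(out_dir, "degree_fit.tsv"), sep="\t", index=False)
        if self.hubs:
            pd.DataFrame({"hub_mirna": self.hubs}).to_csv(
                os.path.join(out_dir, "hubs.tsv"), sep="\t", index=False
            )


def _timed(label: str):
    class _Timer:
        def __enter__(self):
            self.t0 = time.perf_counter()
            return self

        def __exit__(self, *exc):
            logger.info("%s: %.1fs", label, time.perf_counter() - self.t0)

    return _Timer()


def run_pipeline(
    cohort: SimulatedCohort,
    cfg: RunConfig | None = None,
    seed: int | None = None,
    run_hallmark: bool = True,
    run_evaluation: bool = True,
) -> PipelineResult:
    """Execute the full pipeline on an in-memory cohort."""
    cfg = cfg or RunConfig()
    if seed is not None:
        cfg = RunConfig(**{**cfg.to_dict(), "rng_seed": seed})

    with _timed("preprocess"):
        mirna_f = filter_low_expression(cohort.mirna_counts, MIN_READS_MIRNA)
        mrna_f = filter_low_expression(cohort.mrna_counts, MIN_READS_GENE)
        mirna_log = normalize(mirna_f)
        mrna_log = normalize(mrna_f, gene_lengths=cohort.gene_lengths)
        mirna_de = differential_expression(mirna_log, cfg)
        gene_de = differential_expression(mrna_log, cfg)

    with _timed("screen"):
        candidates = candidate_pairs(
            cohort.disease_mirnas, cohort.predicted_pairs, mirna_de, gene_de
        )
        states_m = dichotomize_by_median(mirna_log)
        states_g = dichotomize_by_median(mrna_log)
        dysregulated = screen_dysregulated(candidates, states_m, states_g, cfg)

    result = PipelineResult(
        config=cfg,
        mirna_log=mirna_log,
        mrna_log=mrna_log,
        mirna_de=mirna_de,
        gene_de=gene_de,
        dysregulated=dysregulated,
    )
    if len(dysregulated) == 0:
        logger.warning("no dysregulated interactions; downstream stages skipped")
        return result

    with _timed("select"):
        model = KeyInteractionModel(mirna_log, mrna_log, cohort.clinical, dysregulated, cfg)
        result.selection = model.fit()

    key = result.key_interactions
    if len(key) == 0:
        logger.warning("no key interactions selected; downstream stages skipped")
        return result

    with _timed("network"):
        result.network = build_network(key)
        try:
            result.powerlaw = degree_powerlaw_fit(result.network)
        except ValueError as err:
            logger.warning("power-law fit unavailable: %s", err)
        result.hubs = find_hubs(result.network, cfg)

    if run_hallmark and cohort.ppi is not None and len(cohort.pathways.hallmark_map):
        with _timed("hallmark"):
            seeds = sorted(set(key["target"]) & set(cohort.ppi.nodes))
            if seeds:
                result.hallmark_scores = hallmark_permutation_test(
                    cohort.ppi, seeds, cohort.pathways, cfg
                )
            else:
                logger.warning("no key target present in the PPI network")

    if run_evaluation:
        with _timed("evaluate"):
            ratios = ratio_matrix(key, mirna_log, mrna_log)
            shared = ratios.columns.intersection(cohort.clinical.samples)
            result.clustering = cluster_patients(ratios[shared], cfg)
            result.signature = evaluate_signature(result.clustering, cohort.clinical)
            result.baselines = baseline_comparison(
                key, dysregulated, mirna_log, mrna_log, cohort.clinical, cfg
            )
            result.secondary = secondary_outcome_tests(result.clustering, cohort.clinical)

    return result


def load_cohort(in_dir: str) -> SimulatedCohort:
    """Read a cohort from the on-disk layout ``simulate.write_cohort`` uses.

    ``truth.tsv`` is optional (absent for real data); the PPI network,
    pathways and hallmark map are optional as well — without them the
    hallmark stage is skipped.
    """
    from .simulate import PlantedTruth

    def p(name: str) -> str:
        return os.path.join(in_dir, name)

    cond = pd.read_csv(p("sample_conditions.tsv"), sep="\t")
    condition_map = dict(zip(cond["sample"], cond["condition"]))
    mirna = mio.read_expression_matrix(p("mirna_counts.tsv"), "mirna", condition_map)
    mrna = mio.read_expression_matrix(p("mrna_counts.tsv"), "gene", condition_map)
    lengths = pd.read_csv(p("gene_lengths.tsv"), sep="\t", index_col=0)["length_kb"]
    clinical = mio.read_clinical_table(p("clinical.tsv"))
    ppi = mio.read_edge_list(p("ppi.tsv")) if os.path.exists(p("ppi.tsv")) else None
    if os.path.exists(p("pathways.gmt")):
        hm = p("hallmark_map.tsv") if os.path.exists(p("hallmark_map.tsv")) else None
        pathways = mio.read_gene_sets(p("pathways.gmt"), hm)
    else:
        pathways = GeneSetCollection({"_none": {"_"}}, {})
    with open(p("disease_mirnas.txt")) as fh:
        disease = [line.strip() for line in fh if line.strip()]
    predicted = pd.read_csv(p("predicted_pairs.tsv"), sep="\t")
    truth = None
    if os.path.exists(p("truth.tsv")):
        truth = PlantedTruth(pd.read_csv(p("truth.tsv"), sep="\t"))
    return SimulatedCohort(
        mirna_counts=mirna,
        mrna_counts=mrna,
        gene_lengths=lengths,
        clinical=clinical,
        ppi=ppi,
        pathways=pathways,
        disease_mirnas=disease,
        predicted_pairs=predicted,
        truth=truth,
    )
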