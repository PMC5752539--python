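"""Synthetic TCGA-like cohort generator with planted ground truth.

Emulates the statistical structure the screening pipeline assumes:

* negative-binomial sequencing counts for miRNAs and mRNAs in tumor and
  normal samples;
* a set of planted miRNA->target regulations: the regulator is
  differentially expressed between tumor and normal, its target is shifted
  the opposite way, and within tumors the target's NB mean is multiplied by
  ``regulation_strength ** z`` where ``z`` is the regulator's standardized
  log-expression — producing the anticorrelation the screen looks for;
* a prognostic subset of those regulations whose regulators additionally
  load on a shared per-patient latent risk factor (a co-regulated
  prognostic program), so each prognostic pair's miRNA:target log-ratio is
  informative about the hazard;
* proportional-hazards survival: exponential event times with hazard
  ``baseline_hazard * exp(cox_beta * R)`` where ``R`` is the standardized
  mean of the sign-oriented, standardized prognostic log-ratios, with
  uniform administrative censoring;
* a preferential-attachment (scale-free) protein interaction network over
  the simulated gene universe containing every planted target;
* random pathway gene sets, with one hallmark whose pathways are enriched
  for network neighbors of the prognostic targets and one neutral hallmark;
* disease-miRNA and predicted-pair candidate lists mixing the planted
  truth with inert decoys.

A small fraction of miRNAs are high-abundance invariant "housekeeping"
species (the miR-21/let-7 class that dominates real miRNA libraries); they
stabilize per-sample library totals so that counts-per-million values of
unrelated miRNAs do not inherit a compositional echo of the planted risk
program.  Gene lengths are fixed at 1 kb so RPKM and RPM arithmetic agree.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable

import networkx as nx
import numpy as np
import pandas as pd

from .config import stage_rng
from .datatypes import ClinicalTable, ExpressionMatrix, GeneSetCollection
from . import io as mio

__all__ = [
    "SimulationConfig",
    "PlantedTruth",
    "SimulatedCohort",
    "simulate_expression",
    "simulate_survival",
    "simulate_ppi_network",
    "simulate_pathways",
    "simulate_candidate_lists",
    "simulate_cohort",
    "write_cohort",
]


@dataclass
class SimulationConfig:
    """Parameters of the synthetic cohort.

    ``regulation_strength`` is the multiplicative suppression of a planted
    target's NB mean per standard deviation of its regulator's tumor
    log-expression (0.5 halves the target per +1 SD; 1.0 switches the
    coupling off).  ``cox_beta`` is the true log-hazard per SD of the
    aggregate prognostic ratio; ``risk_loading`` is the log2-units-per-SD
    loading of prognostic regulators on the shared latent risk factor.
    """

    n_tumor: int = 200
    n_normal: int = 40
    n_genes: int = 2000
    n_mirnas: int = 100
    n_planted_regulations: int = 30
    n_planted_prognostic: int = 10
    regulation_strength: float = 0.5
    cox_beta: float = 0.8
    nb_dispersion: float = 0.2
    baseline_hazard: float = 0.01          # events per day
    censoring_horizon_days: float = 2000.0
    ppi_n_nodes: int = 1000
    ppi_edges_per_node: int = 3
    n_pathways: int = 50
    pathway_size_range: tuple[int, int] = (15, 80)
    # tumor/normal differential-expression effect sizes
    mirna_fold: float = 2.0
    target_fold: float = 0.6
    risk_loading: float = 1.0
    housekeeping_fraction: float = 0.05
    housekeeping_boost: float = 50.0
    # candidate-list composition
    n_decoy_disease_mirnas: int = 30
    decoys_per_mirna: int = 20
    n_pathways_per_hallmark: int = 5
    enriched_member_fraction: float = 0.7
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.regulation_strength <= 1.0:
            raise ValueError("regulation_strength must be in (0, 1]")
        if self.n_planted_prognostic > self.n_planted_regulations:
            raise ValueError("planted prognostic pairs must be a subset of planted regulations")
        if self.n_planted_regulations > self.n_mirnas * self.n_genes:
            raise ValueError("more planted regulations than miRNA x gene capacity")
        if self.ppi_edges_per_node >= self.ppi_n_nodes:
            raise ValueError("ppi_edges_per_node must be < ppi_n_nodes")
        lo, hi = self.pathway_size_range
        if not (0 < lo <= hi <= self.ppi_n_nodes):
            raise ValueError(f"infeasible pathway size range {self.pathway_size_range}")
        for name in ("n_tumor", "n_normal", "n_genes", "n_mirnas", "n_pathways"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class PlantedTruth:
    """Planted (miRNA, target) pairs with regulation/prognosis flags."""

    pairs: pd.DataFrame  # columns: mirna, target, is_regulation, is_prognostic, sign
    latent_risk: np.ndarray | None = None  # per-tumor latent factor (diagnostics)

    @property
    def regulations(self) -> set[tuple[str, str]]:
        sub = self.pairs[self.pairs["is_regulation"]]
        return set(zip(sub["mirna"], sub["target"]))

    @property
    def prognostic(self) -> set[tuple[str, str]]:
        sub = self.pairs[self.pairs["is_prognostic"]]
        return set(zip(sub["mirna"], sub["target"]))


@dataclass
class SimulatedCohort:
    """All pipeline inputs for one synthetic cohort."""

    mirna_counts: ExpressionMatrix
    mrna_counts: ExpressionMatrix
    gene_lengths: pd.Series
    clinical: ClinicalTable
    ppi: nx.Graph
    pathways: GeneSetCollection
    disease_mirnas: list[str]
    predicted_pairs: pd.DataFrame  # columns: mirna, target
    truth: PlantedTruth


def _mirna_ids(n: int) -> list[str]:
    return [f"miR-{i + 1:03d}" for i in range(n)]


def _gene_ids(n: int) -> list[str]:
    return [f"GENE{i + 1:04d}" for i in range(n)]


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    size = 1.0 / dispersion
    return rng.negative_binomial(size, size / (size + mean))


def _log2_cpm(counts: np.ndarray) -> np.ndarray:
    totals = counts.sum(axis=0, keepdims=True).astype(float)
    return np.log2(counts / (totals / 1e6) + 1.0)


def simulate_expression(
    cfg: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[ExpressionMatrix, ExpressionMatrix, PlantedTruth]:
    """Simulate miRNA and mRNA count matrices with planted regulations."""
    if rng is None:
        rng = stage_rng(cfg.seed, "expression")
    n_m, n_g, n_t, n_n = cfg.n_mirnas, cfg.n_genes, cfg.n_tumor, cfg.n_normal
    mirnas, genes = _mirna_ids(n_m), _gene_ids(n_g)
    tumor_samples = [f"T{i + 1:03d}" for i in range(n_t)]
    normal_samples = [f"N{i + 1:03d}" for i in range(n_n)]

    mir_mu = rng.lognormal(mean=5.0, sigma=1.0, size=n_m)
    n_hk = max(3, int(round(cfg.housekeeping_fraction * n_m)))
    hk = rng.choice(n_m, size=n_hk, replace=False)
    mir_mu[hk] *= cfg.housekeeping_boost
    gene_mu = rng.lognormal(mean=4.0, sigma=1.0, size=n_g)

    pool_m = np.setdiff1d(np.arange(n_m), hk)
    if cfg.n_planted_regulations > len(pool_m):
        raise ValueError("not enough non-housekeeping miRNAs for planted regulations")
    reg_m = rng.choice(pool_m, size=cfg.n_planted_regulations, replace=False)
    reg_g = rng.choice(n_g, size=cfg.n_planted_regulations, replace=False)
    prog_idx = rng.choice(
        cfg.n_planted_regulations, size=cfg.n_planted_prognostic, replace=False
    )
    prog_set = set(prog_idx.tolist())
    sign = rng.choice([1, -1], size=cfg.n_planted_regulations)

    latent = rng.normal(size=n_t)  # shared risk program across tumors

    mt_mu = np.tile(mir_mu[:, None], (1, n_t))
    mn_mu = np.tile(mir_mu[:, None], (1, n_n))
    for k, m in enumerate(reg_m):
        fold = cfg.mirna_fold if sign[k] > 0 else 1.0 / cfg.mirna_fold
        mt_mu[m] = mt_mu[m] * fold
        if k in prog_set:
            mt_mu[m] = mt_mu[m] * 2.0 ** (cfg.risk_loading * latent * sign[k])
    mirna_tumor = _nb_draw(rng, mt_mu, cfg.nb_dispersion)
    mirna_normal = _nb_draw(rng, mn_mu, cfg.nb_dispersion)

    # suppression is driven by the *realized* regulator expression
    log_mirna_tumor = _log2_cpm(mirna_tumor)
    gt_mu = np.tile(gene_mu[:, None], (1, n_t))
    gn_mu = np.tile(gene_mu[:, None], (1, n_n))
    for k, (m, g) in enumerate(zip(reg_m, reg_g)):
        lm = log_mirna_tumor[m]
        z = (lm - lm.mean()) / (lm.std() + 1e-12)
        fold = cfg.target_fold if sign[k] > 0 else 1.0 / cfg.target_fold
        gt_mu[g] = gene_mu[g] * fold * cfg.regulation_strength ** z
    mrna_tumor = _nb_draw(rng, gt_mu, cfg.nb_dispersion)
    mrna_normal = _nb_draw(rng, gn_mu, cfg.nb_dispersion)

    def _pack(tumor, normal, ids, kind):
        values = pd.DataFrame(
            np.hstack([tumor, normal]), index=ids, columns=tumor_samples + normal_samples
        )
        condition = pd.Series(
            ["tumor"] * n_t + ["normal"] * n_n, index=values.columns
        )
        return ExpressionMatrix(values, kind, condition, scale="counts")

    pairs = pd.DataFrame(
        {
            "mirna": [mirnas[m] for m in reg_m],
            "target": [genes[g] for g in reg_g],
            "is_regulation": True,
            "is_prognostic": [k in prog_set for k in range(cfg.n_planted_regulations)],
            "sign": sign,
        }
    )
    truth = PlantedTruth(pairs, latent_risk=latent)
    return (
        _pack(mirna_tumor, mirna_normal, mirnas, "mirna"),
        _pack(mrna_tumor, mrna_normal, genes, "gene"),
        truth,
    )


def simulate_survival(
    cfg: SimulationConfig,
    ratios: np.ndarray | pd.DataFrame,
    rng: np.random.Generator | None = None,
    tumor_samples: Iterable[str] | None = None,
) -> ClinicalTable:
    """Simulate survival from per-patient prognostic ratio vectors.

    ``ratios`` is (n_prognostic_pairs x n_tumor), already oriented so that a
    larger value means higher risk.  The hazard acts on the standardized
    mean of the standardized rows.
    """
    if rng is None:
        rng = stage_rng(cfg.seed, "survival")
    R = np.asarray(ratios, dtype=float)
    if R.ndim == 1:
        R = R[None, :]
    if R.shape[1] != cfg.n_tumor:
        raise ValueError(
            f"ratio vectors have {R.shape[1]} patients, expected n_tumor={cfg.n_tumor}"
        )
    z = (R - R.mean(axis=1, keepdims=True)) / (R.std(axis=1, keepdims=True) + 1e-12)
    agg = z.mean(axis=0)
    agg = (agg - agg.mean()) / (agg.std() + 1e-12)

    hazard = cfg.baseline_hazard * np.exp(cfg.cox_beta * agg)
    event_time = rng.exponential(1.0 / hazard)
    censor_time = rng.uniform(0.0, cfg.censoring_horizon_days, size=cfg.n_tumor)
    time = np.minimum(event_time, censor_time)
    event = (event_time <= censor_time).astype(int)

    # progression-free survival: same risk structure, faster clock
    pfs_event_time = rng.exponential(1.0 / (1.5 * hazard))
    pfs_time = np.minimum(pfs_event_time, censor_time)
    pfs_event = (pfs_event_time <= censor_time).astype(int)

    if tumor_samples is None:
        tumor_samples = [f"T{i + 1:03d}" for i in range(cfg.n_tumor)]
    data = pd.DataFrame(
        {
            "time": time,
            "event": event,
            "age": rng.uniform(40.0, 80.0, size=cfg.n_tumor),
            "gender": rng.choice(["male", "female"], size=cfg.n_tumor),
            "pfs_time": pfs_time,
            "pfs_event": pfs_event,
            "kps": rng.choice(np.arange(40, 101, 10), size=cfg.n_tumor),
            "m_stage": rng.choice(["M0", "M1"], size=cfg.n_tumor, p=[0.7, 0.3]),
        },
        index=pd.Index(list(tumor_samples), name="sample"),
    )
    return ClinicalTable(data)


def simulate_ppi_network(
    cfg: SimulationConfig,
    truth: PlantedTruth | None = None,
    rng: np.random.Generator | None = None,
) -> nx.Graph:
    """Scale-free protein interaction network over the simulated genes.

    Preferential attachment (Barabasi-Albert) with ``ppi_edges_per_node``
    new edges per node; nodes are gene IDs, with every planted target gene
    guaranteed to be in the network.
    """
    if rng is None:
        rng = stage_rng(cfg.seed, "ppi")
    raw = nx.barabasi_albert_graph(
        cfg.ppi_n_nodes, cfg.ppi_edges_per_node, seed=int(rng.integers(2**31))
    )
    genes = np.array(_gene_ids(cfg.n_genes))
    planted = sorted(truth.pairs["target"].unique()) if truth is not None else []
    others = np.setdiff1d(genes, planted)
    n_other = cfg.ppi_n_nodes - len(planted)
    if n_other < 0:
        raise ValueError("ppi_n_nodes smaller than the number of planted targets")
    chosen = list(planted) + list(rng.choice(others, size=n_other, replace=False))
    perm = rng.permutation(cfg.ppi_n_nodes)
    mapping = {i: chosen[perm[i]] for i in range(cfg.ppi_n_nodes)}
    g = nx.relabel_nodes(raw, mapping)
    nx.set_node_attributes(g, "protein", "kind")
    return g


def simulate_pathways(
    cfg: SimulationConfig,
    truth: PlantedTruth,
    ppi: nx.Graph,
    rng: np.random.Generator | None = None,
) -> GeneSetCollection:
    """Random pathway sets plus an enriched and a neutral hallmark.

    Pathways of the ``tissue_invasion_and_metastasis`` hallmark draw
    ``enriched_member_fraction`` of their members from the prognostic
    planted targets and their network neighborhood (the genes a walk
    seeded at the key targets reaches first); the ``neutral_process``
    hallmark's pathways are uniformly random.
    """
    if rng is None:
        rng = stage_rng(cfg.seed, "pathways")
    lo, hi = cfg.pathway_size_range
    nodes = np.array(sorted(ppi.nodes))
    prog_targets = sorted(
        set(truth.pairs.loc[truth.pairs["is_prognostic"], "target"]) & set(ppi.nodes)
    )
    neighborhood: set[str] = set(prog_targets)
    for t in prog_targets:
        neighborhood |= set(ppi.neighbors(t))
    neighbors = np.array(sorted(neighborhood))

    n_per = cfg.n_pathways_per_hallmark
    if cfg.n_pathways < 2 * n_per:
        raise ValueError("n_pathways too small for two hallmarks")
    sets: dict[str, set[str]] = {}
    for i in range(cfg.n_pathways):
        size = int(rng.integers(lo, hi + 1))
        name = f"PATHWAY_{i + 1:03d}"
        if i < n_per and len(neighbors) > 0:
            k = min(int(round(cfg.enriched_member_fraction * size)), len(neighbors))
            members = set(rng.choice(neighbors, size=k, replace=False))
            members |= set(rng.choice(nodes, size=size - k, replace=False))
        else:
            members = set(rng.choice(nodes, size=size, replace=False))
        sets[name] = {str(m) for m in members}
    hallmark_map = {
        "tissue_invasion_and_metastasis": [f"PATHWAY_{i + 1:03d}" for i in range(n_per)],
        "neutral_process": [f"PATHWAY_{i + 1:03d}" for i in range(n_per, 2 * n_per)],
    }
    return GeneSetCollection(sets, hallmark_map)


def simulate_candidate_lists(
    cfg: SimulationConfig,
    truth: PlantedTruth,
    rng: np.random.Generator | None = None,
) -> tuple[list[str], pd.DataFrame]:
    """Disease-miRNA list and predicted-pair list mixing truth with decoys.

    Every planted regulation appears in the predicted list; decoy pairs use
    targets outside the planted target set so they carry no planted effect.
    """
    if rng is None:
        rng = stage_rng(cfg.seed, "candidates")
    mirnas = np.array(_mirna_ids(cfg.n_mirnas))
    genes = np.array(_gene_ids(cfg.n_genes))
    planted_mirnas = sorted(truth.pairs["mirna"].unique())
    planted_targets = set(truth.pairs["target"])

    decoy_pool = np.setdiff1d(mirnas, planted_mirnas)
    n_decoy = min(cfg.n_decoy_disease_mirnas, len(decoy_pool))
    disease = sorted(
        set(planted_mirnas) | set(rng.choice(decoy_pool, size=n_decoy, replace=False))
    )

    target_pool = np.setdiff1d(genes, sorted(planted_targets))
    rows: list[tuple[str, str]] = [
        (m, t) for m, t in zip(truth.pairs["mirna"], truth.pairs["target"])
    ]
    for m in disease:
        for t in rng.choice(target_pool, size=cfg.decoys_per_mirna, replace=False):
            rows.append((m, str(t)))
    predicted = (
        pd.DataFrame(rows, columns=["mirna", "target"])
        .drop_duplicates()
        .sort_values(["mirna", "target"])
        .reset_index(drop=True)
    )
    return disease, predicted


def simulate_cohort(cfg: SimulationConfig) -> SimulatedCohort:
    """Generate every pipeline input for one synthetic cohort."""
    mirna_counts, mrna_counts, truth = simulate_expression(cfg)
    tumor_mask = mirna_counts.condition == "tumor"
    tumor_samples = list(mirna_counts.samples[tumor_mask])

    log_m = _log2_cpm(mirna_counts.values.loc[:, tumor_samples].to_numpy())
    log_g = _log2_cpm(mrna_counts.values.loc[:, tumor_samples].to_numpy())
    m_index = {m: i for i, m in enumerate(mirna_counts.features)}
    g_index = {g: i for i, g in enumerate(mrna_counts.features)}
    prog = truth.pairs[truth.pairs["is_prognostic"]]
    ratios = np.array(
        [
            (log_m[m_index[m]] - log_g[g_index[g]]) * s
            for m, g, s in zip(prog["mirna"], prog["target"], prog["sign"])
        ]
    )
    clinical = simulate_survival(cfg, ratios, tumor_samples=tumor_samples)
    ppi = simulate_ppi_network(cfg, truth)
    pathways = simulate_pathways(cfg, truth, ppi)
    disease, predicted = simulate_candidate_lists(cfg, truth)
    gene_lengths = pd.Series(1.0, index=mrna_counts.features, name="length_kb")
    return SimulatedCohort(
        mirna_counts=mirna_counts,
        mrna_counts=mrna_counts,
        gene_lengths=gene_lengths,
        clinical=clinical,
        ppi=ppi,
        pathways=pathways,
        disease_mirnas=disease,
        predicted_pairs=predicted,
        truth=truth,
    )


def write_cohort(cohort: SimulatedCohort, out_dir: str) -> None:
    """Write every simulated input to ``out_dir`` in its on-disk format."""
    os.makedirs(out_dir, exist_ok=True)
    mio.write_expression_matrix(cohort.mirna_counts, os.path.join(out_dir, "mirna_counts.tsv"))
    mio.write_expression_matrix(cohort.mrna_counts, os.path.join(out_dir, "mrna_counts.tsv"))
    cohort.gene_lengths.to_frame().to_csv(
        os.path.join(out_dir, "gene_lengths.tsv"), sep="\t", index_label="feature"
    )
    pd.DataFrame(
        {"sample": cohort.mirna_counts.samples, "condition": cohort.mirna_counts.condition.values}
    ).to_csv(os.path.join(out_dir, "sample_conditions.tsv"), sep="\t", index=False)
    mio.write_clinical_table(cohort.clinical, os.path.join(out_dir, "clinical.tsv"))
    mio.write_edge_list(cohort.ppi, os.path.join(out_dir, "ppi.tsv"))
    mio.write_gene_sets(
        cohort.pathways,
        os.path.join(out_dir, "pathways.gmt"),
        os.path.join(out_dir, "hallmark_map.tsv"),
    )
    with open(os.path.join(out_dir, "disease_mirnas.txt"), "w") as fh:
        fh.write("\n".join(cohort.disease_mirnas) + "\n")
    cohort.predicted_pairs.to_csv(
        os.path.join(out_dir, "predicted_pairs.tsv"), sep="\t", index=False
    )
    cohort.truth.pairs.to_csv(os.path.join(out_dir, "truth.tsv"), sep="\t", index=False)
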