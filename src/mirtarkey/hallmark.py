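"""Hallmark impact scoring by random walk with restart on the PPI network.

The key miRNA targets seed a random walk with restart (RWR) over the
protein interaction network; each hallmark of cancer is scored by the
median steady-state probability over the distinct genes in the union of
its associated pathways.  Significance comes from a degree-preserving
rewiring null: the network is rewired by double-edge swaps and the whole
RWR + scoring recomputed per permutation, with an add-one empirical
p-value, p = (1 + #{permuted score >= observed}) / (n_permutations + 1).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import sparse

from .config import RunConfig, stage_rng
from .datatypes import GeneSetCollection

logger = logging.getLogger(__name__)

__all__ = [
    "RWRResult",
    "HallmarkScore",
    "rwr",
    "hallmark_score",
    "rewire_network",
    "hallmark_permutation_test",
]


@dataclass
class RWRResult:
    """Steady-state probability per node for a given seed set."""

    probabilities: pd.Series
    restart_prob: float
    seeds: tuple[str, ...]


@dataclass
class HallmarkScore:
    hallmark: str
    score: float
    p_value: float
    n_permutations: int
    n_genes_in_network: int


def _adjacency(network: nx.Graph, nodes: list) -> sparse.csr_array:
    return nx.to_scipy_sparse_array(network, nodelist=nodes, format="csr")


def _rwr_vector(
    adj: sparse.csr_array,
    seed_idx: np.ndarray,
    r: float,
    tol: float,
    max_iter: int = 10000,
) -> np.ndarray:
    """Iterate p <- (1-r) W p + r p0 with column-normalized W to the fixed
    point (L1 change < tol)."""
    n = adj.shape[0]
    deg = np.asarray(adj.sum(axis=0)).ravel()
    inv_deg = np.divide(1.0, deg, out=np.zeros_like(deg, dtype=float), where=deg > 0)
    w = adj.multiply(inv_deg)  # column-stochastic on non-isolated nodes
    p0 = np.zeros(n)
    p0[seed_idx] = 1.0 / len(seed_idx)
    p = p0.copy()
    for _ in range(max_iter):
        p_next = (1.0 - r) * (w @ p) + r * p0
        if np.abs(p_next - p).sum() < tol:
            return p_next
        p = p_next
    logger.warning("RWR did not reach tol=%.1e in %d iterations", tol, max_iter)
    return p


def rwr(
    network: nx.Graph,
    seeds: Iterable[str],
    restart_prob: float = 0.7,
    tol: float = 1e-10,
) -> RWRResult:
    """Random walk with restart from a seed gene set.

    The restart mass ``restart_prob`` returns the walker to a uniform
    distribution over the seeds each step; nodes in components disjoint
    from every seed end with probability 0.  Duplicate seeds and seed
    order do not affect the result.
    """
    seed_set = sorted(set(seeds))
    nodes = sorted(network.nodes)
    node_idx = {n: i for i, n in enumerate(nodes)}
    present = [s for s in seed_set if s in node_idx]
    missing = [s for s in seed_set if s not in node_idx]
    if not present:
        raise ValueError(f"no seed present in the network; missing: {missing[:10]}")
    if missing:
        logger.info("%d seed(s) absent from the network", len(missing))
    adj = _adjacency(network, nodes)
    p = _rwr_vector(adj, np.array([node_idx[s] for s in present]), restart_prob, tol)
    return RWRResult(
        probabilities=pd.Series(p, index=pd.Index(nodes)),
        restart_prob=restart_prob,
        seeds=tuple(present),
    )


def hallmark_score(
    result: RWRResult, collection: GeneSetCollection
) -> dict[str, float]:
    """Median steady-state probability per hallmark.

    The median runs over the distinct genes in the union of the hallmark's
    pathways that are present in the network; a hallmark with no
    network-resident gene scores NaN (flagged).
    """
    scores: dict[str, float] = {}
    probs = result.probabilities
    for hallmark in collection.hallmark_map:
        genes = sorted(collection.hallmark_genes(hallmark) & set(probs.index))
        if not genes:
            logger.warning("hallmark %r has no genes in the network", hallmark)
            scores[hallmark] = float("nan")
            continue
        scores[hallmark] = float(probs.loc[genes].median())
    return scores


def rewire_network(
    network: nx.Graph,
    rng: np.random.Generator,
    swaps_per_edge: int = 10,
) -> nx.Graph:
    """Degree-preserving randomization by double-edge swaps.

    Attempts ``swaps_per_edge * |E|`` swaps so every edge is expected to be
    rewired several times; self-loops and multi-edges are never introduced,
    and every node keeps its exact degree.  Graphs admitting no valid swap
    are returned unchanged with a warning.
    """
    m = network.number_of_edges()
    if m < 2:
        logger.warning("graph has < 2 edges; rewiring impossible, returned unchanged")
        return network.copy()
    g = network.copy()
    seed = int(rng.integers(2**31))
    try:
        nx.double_edge_swap(g, nswap=swaps_per_edge * m, max_tries=100 * swaps_per_edge * m, seed=seed)
    except nx.NetworkXError as err:  # too few valid swaps (degenerate graph)
        logger.warning("rewiring degenerate (%s); graph returned unchanged", err)
        return network.copy()
    except nx.NetworkXAlgorithmError as err:
        logger.warning("rewiring exhausted swap attempts (%s); using partial result", err)
    return g


def hallmark_permutation_test(
    network: nx.Graph,
    seeds: Sequence[str],
    collection: GeneSetCollection,
    cfg: RunConfig | None = None,
    rng: np.random.Generator | None = None,
    add_one: bool = True,
) -> pd.DataFrame:
    """Score every hallmark and assess significance on rewired networks.

    For each of ``cfg.n_permutations`` degree-preserving rewirings the RWR
    and hallmark scores are recomputed; the empirical p-value is the
    (add-one) fraction of permutations with a score at least as large as
    observed.  Returns a DataFrame with columns hallmark, score, p_value,
    n_permutations, significant.
    """
    cfg = cfg or RunConfig()
    if rng is None:
        rng = stage_rng(cfg.rng_seed, "hallmark-permutation")
    observed_rwr = rwr(network, seeds, cfg.restart_prob)
    observed = hallmark_score(observed_rwr, collection)
    hallmarks = sorted(collection.hallmark_map)
    exceed = {h: 0 for h in hallmarks}
    for _ in range(cfg.n_permutations):
        permuted = rewire_network(network, rng)
        perm_scores = hallmark_score(rwr(permuted, seeds, cfg.restart_prob), collection)
        for h in hallmarks:
            if perm_scores[h] >= observed[h]:
                exceed[h] += 1
    rows = []
    for h in hallmarks:
        if add_one:
            p = (1 + exceed[h]) / (cfg.n_permutations + 1)
        else:
            p = exceed[h] / cfg.n_permutations
        genes = collection.hallmark_genes(h) & set(observed_rwr.probabilities.index)
        rows.append(
            {
                "hallmark": h,
                "score": observed[h],
                "p_value": p,
                "n_permutations": cfg.n_permutations,
                "n_genes_in_network": len(genes),
                "significant": p < 0.05,
            }
        )
    return pd.DataFrame(rows)
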