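"""Key miRNA-target network construction and topology statistics.

The selected interactions form a bipartite miRNA-gene graph.  Its degree
distribution is summarized by an ordinary least-squares line on log10-log10
axes (log count of nodes with degree k against log k), and hub miRNAs are
the miRNA nodes in the top fraction of all nodes by degree that regulate at
least a minimum number of targets.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .config import RunConfig

__all__ = ["PowerLawFit", "build_network", "degree_powerlaw_fit", "find_hubs"]


@dataclass
class PowerLawFit:
    """OLS fit of log10 N(k) on log10 k."""

    slope: float
    intercept: float
    r_squared: float
    p_value: float
    degrees: np.ndarray
    counts: np.ndarray


def build_network(key_interactions: pd.DataFrame) -> nx.Graph:
    """Bipartite graph with miRNA and gene node kinds; duplicate
    interactions collapse to a single edge."""
    if len(key_interactions) == 0:
        raise ValueError("no key interactions to build a network from")
    g = nx.Graph()
    for row in key_interactions.itertuples():
        g.add_node(row.mirna, kind="mirna")
        g.add_node(row.target, kind="gene")
        g.add_edge(row.mirna, row.target)
    return g


def degree_powerlaw_fit(network: nx.Graph) -> PowerLawFit:
    """Least-squares power-law fit to the raw degree histogram.

    For every degree k >= 1 with N(k) > 0 nodes, regress log10 N(k) on
    log10 k.  Requires at least three distinct degree values.
    """
    degrees = np.array([d for _, d in network.degree() if d >= 1])
    ks, counts = np.unique(degrees, return_counts=True)
    if len(ks) < 3:
        raise ValueError(
            f"need >= 3 distinct degree values for a power-law fit, got {len(ks)}"
        )
    lx, ly = np.log10(ks), np.log10(counts)
    fit = stats.linregress(lx, ly)
    return PowerLawFit(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        p_value=float(fit.pvalue),
        degrees=ks,
        counts=counts,
    )


def find_hubs(network: nx.Graph, cfg: RunConfig | None = None) -> list[str]:
    """Hub miRNAs: top ``hub_top_fraction`` of nodes by degree (ties at the
    cutoff included) that regulate >= ``hub_min_targets`` targets.

    With ``cfg.hub_rank_all_nodes`` (default) the degree ranking covers all
    nodes, miRNA and gene alike; otherwise miRNA nodes only.
    """
    cfg = cfg or RunConfig()
    kinds = nx.get_node_attributes(network, "kind")
    if cfg.hub_rank_all_nodes:
        ranked = sorted(network.degree(), key=lambda nd: -nd[1])
    else:
        ranked = sorted(
            ((n, d) for n, d in network.degree() if kinds.get(n) == "mirna"),
            key=lambda nd: -nd[1],
        )
    if not ranked:
        return []
    n_top = max(1, int(np.ceil(cfg.hub_top_fraction * len(ranked))))
    cutoff_degree = ranked[n_top - 1][1]
    top = {n for n, d in ranked if d >= cutoff_degree}  # ties included
    hubs = [
        n
        for n in top
        if kinds.get(n) == "mirna" and network.degree(n) >= cfg.hub_min_targets
    ]
    return sorted(hubs)
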