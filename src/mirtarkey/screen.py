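"""Dysregulated miRNA-target interaction screen.

Three criteria applied to candidate pairs: (1) both the disease-associated
miRNA and its predicted target are differentially expressed, (2) their
differential-expression directions are opposite, and (3) the joint
miRNA-high/target-low pattern (oriented by the miRNA's direction) occurs in
strictly more than ``pattern_min_fraction`` of tumor samples.
"""

from __future__ import annotations

from typing import Iterable

import pandas as pd

from .config import RunConfig

__all__ = ["candidate_pairs", "pattern_fraction", "screen_dysregulated"]


def candidate_pairs(
    disease_mirnas: Iterable[str],
    predicted_pairs: pd.DataFrame,
    mirna_de: pd.DataFrame,
    gene_de: pd.DataFrame,
) -> pd.DataFrame:
    """Predicted pairs whose miRNA is disease-associated, both members are
    differentially expressed, and the directions are opposite.

    Returns columns ``mirna``, ``target``, ``mirna_dir``, ``target_dir``.
    """
    if len(predicted_pairs) == 0:
        raise ValueError("predicted pair list is empty")
    disease = set(disease_mirnas)
    pairs = predicted_pairs[predicted_pairs["mirna"].isin(disease)].copy()
    pairs["mirna_dir"] = pairs["mirna"].map(mirna_de["direction"]).fillna("ns")
    pairs["target_dir"] = pairs["target"].map(gene_de["direction"]).fillna("ns")
    opposite = (
        ((pairs["mirna_dir"] == "up") & (pairs["target_dir"] == "down"))
        | ((pairs["mirna_dir"] == "down") & (pairs["target_dir"] == "up"))
    )
    return pairs[opposite].reset_index(drop=True)


def pattern_fraction(
    mirna: str, target: str, mirna_dir: str, states_mirna: pd.DataFrame, states_gene: pd.DataFrame
) -> float:
    """Fraction of tumor samples showing the reversed-expression pattern.

    Up-regulated miRNA: miRNA high AND target low; down-regulated miRNA:
    miRNA low AND target high.  ``states_*`` are boolean feature x tumor
    matrices from median dichotomization.
    """
    if mirna not in states_mirna.index:
        raise KeyError(f"miRNA {mirna!r} absent from state matrix")
    if target not in states_gene.index:
        raise KeyError(f"gene {target!r} absent from state matrix")
    hi_m = states_mirna.loc[mirna]
    hi_g = states_gene.loc[target]
    if mirna_dir == "up":
        joint = hi_m & ~hi_g
    elif mirna_dir == "down":
        joint = ~hi_m & hi_g
    else:
        raise ValueError(f"mirna_dir must be 'up' or 'down', got {mirna_dir!r}")
    return float(joint.mean())


def screen_dysregulated(
    candidates: pd.DataFrame,
    states_mirna: pd.DataFrame,
    states_gene: pd.DataFrame,
    cfg: RunConfig | None = None,
) -> pd.DataFrame:
    """Retain candidates whose pattern fraction strictly exceeds the
    threshold; output sorted by (mirna, target) for determinism."""
    cfg = cfg or RunConfig()
    if len(candidates) == 0:
        return pd.DataFrame(
            columns=["mirna", "target", "mirna_dir", "target_dir", "pattern_fraction"]
        )
    fractions = [
        pattern_fraction(r.mirna, r.target, r.mirna_dir, states_mirna, states_gene)
        for r in candidates.itertuples()
    ]
    out = candidates.copy()
    out["pattern_fraction"] = fractions
    out = out[out["pattern_fraction"] > cfg.pattern_min_fraction]
    return out.sort_values(["mirna", "target"]).reset_index(drop=True)
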