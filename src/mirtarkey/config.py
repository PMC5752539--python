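"""Run-level configuration and the seed policy.

All thresholds of the screening pipeline live in one place so a run is fully
described by a :class:`RunConfig` plus the input files.  Every stochastic
stage draws its generator from :func:`stage_rng`, which splits a single
master seed deterministically per stage name — two runs with the same config
and seed are byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
from dataclasses import dataclass, field
from typing import Any

import numpy as np
import yaml

__all__ = ["RunConfig", "stage_rng", "stage_seed"]


@dataclass
class RunConfig:
    """Global thresholds and knobs of the key-interaction pipeline.

    Defaults are the canonical operating point of the method: differential
    expression at FDR < 0.05 with fold change > 1.2, the joint high/low
    expression pattern required in more than 20% of tumors, 1,000 Cox
    resamples of 80% of each outcome-extreme group with significance
    frequency > 0.6, log-rank confirmation at 0.05, random-walk restart
    probability 0.7 with 1,000 degree-preserving network permutations, and
    hubs as the top 10% of nodes by degree with at least 10 targets.
    """

    de_fdr: float = 0.05
    de_fc: float = 1.2
    pattern_min_fraction: float = 0.20
    n_resamples: int = 1000
    resample_fraction: float = 0.80
    sig_freq_threshold: float = 0.60
    logrank_alpha: float = 0.05
    restart_prob: float = 0.70
    n_permutations: int = 1000
    hub_top_fraction: float = 0.10
    hub_min_targets: int = 10
    #: require the Cox coefficient sign to agree across *all* resamples
    #: (strict reading); False relaxes it to the significant resamples only.
    strict_sign_consistency: bool = True
    #: z-score ratio-matrix rows before k-means clustering.
    standardize_ratios: bool = True
    #: rank all network nodes (miRNA + gene) for the hub degree cutoff;
    #: False ranks miRNA nodes only.
    hub_rank_all_nodes: bool = True
    rng_seed: int = 0
    paths: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in (
            "de_fdr",
            "pattern_min_fraction",
            "resample_fraction",
            "sig_freq_threshold",
            "logrank_alpha",
            "restart_prob",
            "hub_top_fraction",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v!r}")
        for name in ("n_resamples", "n_permutations", "hub_min_targets"):
            v = getattr(self, name)
            if not (isinstance(v, (int, np.integer)) and v > 0):
                raise ValueError(f"{name} must be a positive integer, got {v!r}")
        if self.de_fc < 1.0:
            raise ValueError(f"de_fc must be >= 1, got {self.de_fc!r}")

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            raw: dict[str, Any] = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the master seed.

    Hash-based so adding a stage never shifts the streams of the others.
    Result is a valid 31-bit seed.
    """
    h = hashlib.sha256(f"{int(master_seed)}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


def stage_rng(master_seed: int, stage: str) -> np.random.Generator:
    """Independent :class:`numpy.random.Generator` for a named stage."""
    return np.random.default_rng(stage_seed(master_seed, stage))
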