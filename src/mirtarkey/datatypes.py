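"""In-memory containers shared across the pipeline.

Thin, validated wrappers over pandas/networkx objects: an expression matrix
knows its feature kind (miRNA or gene), per-sample condition labels and the
scale its values are on; the clinical table knows which optional covariates
it actually carries.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "ClinicalTable",
    "GeneSetCollection",
    "OPTIONAL_CLINICAL_COLUMNS",
]

OPTIONAL_CLINICAL_COLUMNS = ("pfs_time", "pfs_event", "kps", "m_stage")


@dataclass
class ExpressionMatrix:
    """Feature x sample numeric matrix with metadata.

    Parameters
    ----------
    values
        DataFrame indexed by feature ID, columns are sample IDs.
    feature_kind
        ``"mirna"`` or ``"gene"``.
    condition
        Per-sample condition, aligned with ``values.columns``;
        entries are ``"tumor"`` or ``"normal"``.
    scale
        ``"counts"`` for raw counts, ``"log2"`` for log-normalized values.
    """

    values: pd.DataFrame
    feature_kind: str
    condition: pd.Series
    scale: str = "counts"

    def __post_init__(self) -> None:
        if self.feature_kind not in ("mirna", "gene"):
            raise ValueError(f"feature_kind must be 'mirna' or 'gene', got {self.feature_kind!r}")
        if self.scale not in ("counts", "log2"):
            raise ValueError(f"scale must be 'counts' or 'log2', got {self.scale!r}")
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate feature IDs: {dups}")
        self.condition = pd.Series(self.condition).reindex(self.values.columns)
        if self.condition.isna().any():
            missing = self.condition[self.condition.isna()].index.tolist()
            raise ValueError(f"samples without a condition label: {missing}")
        bad = set(self.condition.unique()) - {"tumor", "normal"}
        if bad:
            raise ValueError(f"unknown condition labels: {sorted(bad)}")

    @property
    def features(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns

    def subset(self, condition: str) -> "ExpressionMatrix":
        """Sub-matrix restricted to samples with the given condition."""
        keep = self.condition[self.condition == condition].index
        return ExpressionMatrix(
            self.values[keep], self.feature_kind, self.condition[keep], self.scale
        )

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        n_t = int((self.condition == "tumor").sum())
        n_n = int((self.condition == "normal").sum())
        return (
            f"<ExpressionMatrix {self.feature_kind}: {self.values.shape[0]} features x "
            f"{self.values.shape[1]} samples ({n_t} tumor / {n_n} normal), {self.scale}>"
        )


@dataclass
class ClinicalTable:
    """Per-sample survival outcomes and covariates.

    ``data`` is indexed by sample ID with required columns ``time`` (days),
    ``event`` (1 = death observed, 0 = censored), ``age``, ``gender``
    (``male``/``female``) and any of the optional columns ``pfs_time``,
    ``pfs_event``, ``kps``, ``m_stage``.  Missing optional covariates are
    recorded as absent, never imputed.
    """

    data: pd.DataFrame
    available_optional: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        required = ["time", "event", "age", "gender"]
        missing = [c for c in required if c not in self.data.columns]
        if missing:
            raise ValueError(f"clinical table missing required columns: {missing}")
        if (self.data["time"] < 0).any():
            bad = self.data.index[self.data["time"] < 0].tolist()
            raise ValueError(f"negative survival time for samples: {bad}")
        ev = set(pd.unique(self.data["event"]))
        if not ev <= {0, 1}:
            raise ValueError(f"event codes must be 0/1, got {sorted(ev)}")
        genders = set(self.data["gender"].dropna().unique())
        if not genders <= {"male", "female"}:
            raise ValueError(f"unknown gender codes: {sorted(genders - {'male', 'female'})}")
        self.available_optional = tuple(
            c for c in OPTIONAL_CLINICAL_COLUMNS
            if c in self.data.columns and self.data[c].notna().any()
        )

    @property
    def samples(self) -> pd.Index:
        return self.data.index

    def aligned(self, samples) -> pd.DataFrame:
        """Rows for the given samples, in the given order; errors if absent."""
        missing = [s for s in samples if s not in self.data.index]
        if missing:
            raise KeyError(f"samples without clinical records: {missing[:5]}")
        return self.data.loc[list(samples)]

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"<ClinicalTable: {len(self.data)} subjects, "
            f"{int(self.data['event'].sum())} events, "
            f"optional={list(self.available_optional)}>"
        )


@dataclass
class GeneSetCollection:
    """Named gene sets with an optional hallmark -> set-name mapping."""

    sets: dict[str, set[str]]
    hallmark_map: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise ValueError(f"gene set {name!r} is empty")
        for hallmark, names in self.hallmark_map.items():
            unknown = [n for n in names if n not in self.sets]
            if unknown:
                raise ValueError(
                    f"hallmark {hallmark!r} maps to unknown sets: {unknown}"
                )

    def hallmark_genes(self, hallmark: str) -> set[str]:
        """Union of genes over a hallmark's associated sets."""
        genes: set[str] = set()
        for name in self.hallmark_map[hallmark]:
            genes |= self.sets[name]
        return genes

    def __len__(self) -> int:
        return len(self.sets)


def typed_network(edges, node_kinds: dict[str, str] | None = None) -> nx.Graph:
    """Undirected graph with a ``kind`` attribute per node."""
    g = nx.Graph()
    g.add_edges_from(edges)
    if node_kinds:
        nx.set_node_attributes(g, {n: node_kinds.get(n, "protein") for n in g}, "kind")
    return g
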