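"""Readers and writers for the pipeline's external formats.

Everything tabular is TSV; gene sets are GMT; networks are two-column TSV
edge lists with the three-column SIF dialect accepted (middle column
ignored).  Writers and readers round-trip losslessly on the formats the
simulator emits.
"""

from __future__ import annotations

import json
import logging
import os
import platform
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd

from .config import RunConfig
from .datatypes import (
    OPTIONAL_CLINICAL_COLUMNS,
    ClinicalTable,
    ExpressionMatrix,
    GeneSetCollection,
)

logger = logging.getLogger(__name__)

__all__ = [
    "read_expression_matrix",
    "write_expression_matrix",
    "read_clinical_table",
    "write_clinical_table",
    "read_gene_sets",
    "write_gene_sets",
    "read_edge_list",
    "write_edge_list",
    "write_results",
]


def read_expression_matrix(
    path: str,
    feature_kind: str,
    condition_map: Mapping[str, str],
    scale: str = "counts",
) -> ExpressionMatrix:
    """Read a feature x sample TSV into an :class:`ExpressionMatrix`.

    The header row carries sample IDs, the first column feature IDs.  Every
    sample named in ``condition_map`` must be present; samples not named are
    rejected so condition labels can never be silently absent.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"{path}: duplicate feature IDs {dups}")
    non_numeric = df.columns[[not np.issubdtype(dt, np.number) for dt in df.dtypes]]
    if len(non_numeric):
        col = non_numeric[0]
        bad = df[col][pd.to_numeric(df[col], errors="coerce").isna()]
        row = bad.index[0] if len(bad) else "?"
        raise ValueError(f"{path}: non-numeric value in column {col!r}, row {row!r}")
    missing = [s for s in condition_map if s not in df.columns]
    if missing:
        raise ValueError(f"{path}: samples in condition map missing from header: {missing}")
    condition = pd.Series({s: condition_map.get(s) for s in df.columns})
    return ExpressionMatrix(df, feature_kind, condition, scale=scale)


def write_expression_matrix(matrix: ExpressionMatrix, path: str) -> None:
    matrix.values.to_csv(path, sep="\t", index_label="feature")


def read_clinical_table(path: str) -> ClinicalTable:
    """Read the clinical TSV (sample, time, event, age, gender, + optional)."""
    df = pd.read_csv(path, sep="\t")
    if "sample" not in df.columns:
        raise ValueError(f"{path}: missing 'sample' column")
    df = df.set_index("sample")
    keep = [c for c in df.columns if c in ("time", "event", "age", "gender") + OPTIONAL_CLINICAL_COLUMNS]
    return ClinicalTable(df[keep])


def write_clinical_table(clinical: ClinicalTable, path: str) -> None:
    clinical.data.to_csv(path, sep="\t", index_label="sample")


def read_gene_sets(path: str, hallmark_map_path: str | None = None) -> GeneSetCollection:
    """Read standard GMT (name, description, tab-separated members).

    Duplicate members within a set are deduplicated with a warning; a line
    with fewer than three fields is an error naming the line.
    """
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line has {len(fields)} fields, need >= 3")
            name, _desc, *members = fields
            members = [m for m in members if m]
            if name in sets:
                raise ValueError(f"{path}:{lineno}: duplicate set name {name!r}")
            if len(set(members)) < len(members):
                logger.warning("%s:%d: set %r has duplicate members; deduplicated", path, lineno, name)
            sets[name] = set(members)
    hallmark_map: dict[str, list[str]] = {}
    if hallmark_map_path is not None:
        hm = pd.read_csv(hallmark_map_path, sep="\t")
        if not {"hallmark", "pathway"} <= set(hm.columns):
            raise ValueError(f"{hallmark_map_path}: need columns 'hallmark' and 'pathway'")
        for hallmark, grp in hm.groupby("hallmark", sort=True):
            hallmark_map[str(hallmark)] = sorted(grp["pathway"].astype(str))
    return GeneSetCollection(sets, hallmark_map)


def write_gene_sets(collection: GeneSetCollection, path: str, hallmark_map_path: str | None = None) -> None:
    with open(path, "w") as fh:
        for name in sorted(collection.sets):
            members = "\t".join(sorted(collection.sets[name]))
            fh.write(f"{name}\tna\t{members}\n")
    if hallmark_map_path is not None:
        rows = [
            {"hallmark": h, "pathway": p}
            for h in sorted(collection.hallmark_map)
            for p in collection.hallmark_map[h]
        ]
        pd.DataFrame(rows, columns=["hallmark", "pathway"]).to_csv(
            hallmark_map_path, sep="\t", index=False
        )


def read_edge_list(path: str, directed: bool = False) -> nx.Graph:
    """Read a two-column TSV edge list (or three-column SIF) into a graph.

    Self-loops are dropped with a warning and duplicate edges collapse; the
    node set is the union of all endpoints.
    """
    g: nx.Graph = nx.DiGraph() if directed else nx.Graph()
    n_self = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) == 1:
                fields = line.split()
            if len(fields) < 2:
                raise ValueError(f"{path}:{lineno}: expected >= 2 columns, got {len(fields)}")
            if len(fields) >= 3:
                a, b = fields[0], fields[2]  # SIF: source, interaction, target
            else:
                a, b = fields[0], fields[1]
            if a == b:
                n_self += 1
                continue
            g.add_edge(a, b)
    if n_self:
        logger.warning("%s: dropped %d self-loop(s)", path, n_self)
    return g


def write_edge_list(g: nx.Graph, path: str) -> None:
    with open(path, "w") as fh:
        for a, b in sorted(tuple(sorted(e)) for e in g.edges):
            fh.write(f"{a}\t{b}\n")


def write_results(
    tables: Mapping[str, pd.DataFrame],
    out_dir: str,
    config: RunConfig | None = None,
) -> list[str]:
    """Write one TSV per result table plus a JSON run manifest.

    Column order is preserved as given (stable across runs); an empty table
    produces a header-only file.  Returns the paths written.
    """
    os.makedirs(out_dir, exist_ok=True)
    written = []
    for name, table in tables.items():
        path = os.path.join(out_dir, f"{name}.tsv")
        table.to_csv(path, sep="\t", index=False)
        written.append(path)
    manifest = {
        "config": config.to_dict() if config is not None else None,
        "seed": config.rng_seed if config is not None else None,
        "tables": sorted(tables),
        "versions": {
            "python": platform.python_version(),
            "numpy": np.__version__,
            "pandas": pd.__version__,
            "networkx": nx.__version__,
        },
    }
    mpath = os.path.join(out_dir, "run_manifest.json")
    with open(mpath, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    written.append(mpath)
    return written
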