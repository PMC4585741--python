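"""Readers and writers for the pipeline's tabular and graph formats.

Tab-separated values are the native tabular dialect; networks are written
as SIF, GraphML, or a node1/node2/r/sign edge-list TSV. No science logic
lives here.
"""

from __future__ import annotations

import sys
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .containers import RANKS, CountTable, EcoNetwork, EnvTable, FormatError, TaxonomyMap

NETWORK_FORMATS = ("sif", "graphml", "edgelist")

#: float format used by all writers; round-trips 6 significant digits
_FLOAT_FMT = "%.10g"


def read_count_table(
    path,
    orientation: str = "samples-as-rows",
    group: pd.Series | None = None,
) -> CountTable:
    """Read a TSV count table and normalize it to samples x features.

    Parameters
    ----------
    path
        Tab-separated file with a header row and labels in the first column.
    orientation
        ``"samples-as-rows"`` or ``"samples-as-columns"`` — how the file on
        disk is laid out.
    """
    if orientation not in ("samples-as-rows", "samples-as-columns"):
        raise ValueError(f"unknown orientation {orientation!r}")
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")[1:]
    if len(header) != len(set(header)):
        raise FormatError(f"{path}: duplicate labels in header")
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates or df.columns.has_duplicates:
        raise FormatError(f"{path}: duplicate labels")
    try:
        df = df.astype(float)
    except ValueError as exc:
        raise FormatError(f"{path}: non-numeric entries ({exc})") from exc
    if orientation == "samples-as-columns":
        df = df.T
    return CountTable(df, group=group)


def write_count_table(table: CountTable, path) -> None:
    table.counts.to_csv(path, sep="\t", float_format=_FLOAT_FMT)


def read_group_file(path) -> pd.Series:
    """Two-column TSV (sample, group) -> sample -> label Series."""
    df = pd.read_csv(path, sep="\t", index_col=0, header=None, names=["sample", "group"])
    return df["group"].astype(str)


def write_group_file(group: pd.Series, path) -> None:
    group.to_csv(path, sep="\t", header=False)


def read_taxonomy(path) -> TaxonomyMap:
    """TSV with columns feature + domain...genus (missing ranks allowed)."""
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    df.columns = [c.lower() for c in df.columns]
    unknown = set(df.columns) - set(RANKS)
    if unknown:
        raise FormatError(f"{path}: unknown taxonomy columns {sorted(unknown)}")
    return TaxonomyMap(df)


def write_taxonomy(taxonomy: TaxonomyMap, path) -> None:
    taxonomy.lineages.to_csv(path, sep="\t", index_label="feature")


def read_env_table(path) -> EnvTable:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return EnvTable(df)


def write_env_table(env: EnvTable, path) -> None:
    env.values.to_csv(path, sep="\t", float_format=_FLOAT_FMT)


def write_network(net: EcoNetwork, path, format: str = "edgelist") -> None:
    """Write a network in SIF, GraphML, or edge-list TSV form.

    SIF uses the edge sign (``pos``/``neg``) as the interaction type, one
    line per edge; isolated nodes are emitted as bare single-column lines.
    """
    if format not in NETWORK_FORMATS:
        raise ValueError(f"unknown network format {format!r}; expected {NETWORK_FORMATS}")
    path = Path(path)
    if format == "sif":
        with path.open("w") as fh:
            seen = set()
            for u, v, d in net.graph.edges(data=True):
                kind = "pos" if d["sign"] >= 0 else "neg"
                fh.write(f"{u}\t{kind}\t{v}\n")
                seen.update((u, v))
            for node in net.graph.nodes:
                if node not in seen:
                    fh.write(f"{node}\n")
    elif format == "graphml":
        g = nx.Graph()
        g.add_nodes_from(net.graph.nodes)
        for u, v, d in net.graph.edges(data=True):
            g.add_edge(u, v, r=float(d["r"]), sign=int(d["sign"]), weight=float(d["weight"]))
        g.graph["similarity_threshold"] = float(net.st)
        nx.write_graphml(g, path)
    else:
        df = net.edge_table()
        df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def read_network_edgelist(path, st: float) -> EcoNetwork:
    """Read an edge-list TSV written by :func:`write_network` back."""
    df = pd.read_csv(path, sep="\t")
    g = nx.Graph()
    for row in df.itertuples(index=False):
        r = float(row.r)
        g.add_edge(str(row.node1), str(row.node2), r=r, sign=int(np.sign(r)) or 1, weight=abs(r))
    return EcoNetwork(g, st)


def log(message: str) -> None:
    """Reproducibility log line on stderr."""
    print(f"[pmena] {message}", file=sys.stderr)
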