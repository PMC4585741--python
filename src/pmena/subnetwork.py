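"""Taxon-centric sub-networks (ego networks).

Extract the neighborhood of the most-connected OTUs of a focal taxon,
tally its positive and negative links by partner phylum, and report the
taxon's share of network nodes and of community reads.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import pandas as pd

from .containers import UNCLASSIFIED, CountTable, EcoNetwork, TaxonomyMap


def select_focus(
    net: EcoNetwork,
    taxonomy: TaxonomyMap,
    taxon: str,
    k: int = 6,
    criterion: str = "degree",
) -> list[str]:
    """Top-k OTUs of `taxon` in the network, ranked by degree.

    `criterion` is ``"degree"`` (highest connectivity first, ties broken
    by OTU label) or ``"all"`` (every matching OTU). Returns an empty
    list with a warning when the taxon is absent from the network.
    """
    if criterion not in ("degree", "all"):
        raise ValueError(f"unknown criterion {criterion!r}")
    members = taxonomy.features_of(taxon, features=net.graph.nodes)
    if not members:
        warnings.warn(f"taxon {taxon!r} absent from the network")
        return []
    if criterion == "all":
        return sorted(members)
    ranked = sorted(members, key=lambda n: (-net.graph.degree(n), str(n)))
    return ranked[:k]


@dataclass
class SubnetReport:
    """Ego network of a focus set with signed link tallies by partner phylum."""

    focus: list
    subnet: EcoNetwork
    tallies: pd.DataFrame  # per (focus, partner phylum): n_positive, n_negative
    pct_nodes: float = field(default=float("nan"))
    pct_reads: float = field(default=float("nan"))

    def tally_by_phylum(self) -> pd.DataFrame:
        """Tallies aggregated over the focus OTUs."""
        if self.tallies.empty:
            return self.tallies
        return self.tallies.groupby("partner_phylum")[["n_positive", "n_negative"]].sum()


def ego_network(
    net: EcoNetwork,
    focus,
    taxonomy: TaxonomyMap,
    include_neighbor_edges: bool = False,
) -> SubnetReport:
    """Sub-network of the focus OTUs and their direct neighbors.

    Edges touching at least one focus node are always kept; edges among
    non-focus neighbors only with ``include_neighbor_edges=True``.
    Signed links are tallied per focus OTU by the partner's phylum
    (unclassified partners under "unclassified").
    """
    focus = list(focus)
    if not focus:
        raise ValueError("empty focus set")
    missing = [f for f in focus if f not in net.graph]
    if missing:
        raise KeyError(f"focus nodes not in network: {missing}")
    focus_set = set(focus)
    nodes = set(focus)
    g = nx.Graph()
    g.add_nodes_from(focus)
    for f in focus:
        for nbr in net.graph.neighbors(f):
            nodes.add(nbr)
            g.add_edge(f, nbr, **net.graph[f][nbr])
    if include_neighbor_edges:
        others = nodes - focus_set
        for u, v, d in net.graph.subgraph(others).edges(data=True):
            g.add_edge(u, v, **d)

    rows = []
    for f in focus:
        for nbr in net.graph.neighbors(f):
            phylum = taxonomy.rank_of(nbr, "phylum")
            sign = net.graph[f][nbr]["sign"]
            rows.append({"focus": f, "partner_phylum": phylum or UNCLASSIFIED, "sign": sign})
    if rows:
        df = pd.DataFrame(rows)
        tallies = (
            df.groupby(["focus", "partner_phylum"])["sign"]
            .agg(
                n_positive=lambda s: int((s > 0).sum()),
                n_negative=lambda s: int((s < 0).sum()),
            )
            .reset_index()
        )
    else:
        tallies = pd.DataFrame(columns=["focus", "partner_phylum", "n_positive", "n_negative"])
    return SubnetReport(focus=focus, subnet=EcoNetwork(g, net.st), tallies=tallies)


def node_read_shares(
    net: EcoNetwork,
    table: CountTable,
    taxonomy: TaxonomyMap,
    taxon: str,
    group: str | None = None,
) -> tuple[float, float]:
    """(% of network nodes, % of reads) belonging to `taxon`.

    The read share is computed over the samples of `group` when given,
    otherwise over all samples of the table.
    """
    if net.n_nodes == 0:
        raise ValueError("empty network")
    taxon_nodes = taxonomy.features_of(taxon, features=net.graph.nodes)
    pct_nodes = 100.0 * len(taxon_nodes) / net.n_nodes
    sub = table.select_samples(table.group_samples(group)) if group else table
    total_reads = sub.counts.to_numpy().sum()
    taxon_features = taxonomy.features_of(taxon, features=sub.feature_ids)
    taxon_reads = sub.counts[taxon_features].to_numpy().sum() if taxon_features else 0
    pct_reads = 100.0 * taxon_reads / total_reads
    return float(pct_nodes), float(pct_reads)
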