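"""Core data containers shared across the pipeline.

All tabular data are held as pandas objects with samples as rows (the
internal orientation); networks are held as :class:`networkx.Graph`
instances wrapped with the similarity threshold that produced them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

#: Canonical taxonomic ranks, coarsest to finest.
RANKS = ("domain", "phylum", "class", "order", "family", "genus")

#: Label used for any rank a feature could not be classified at.
UNCLASSIFIED = "unclassified"


class FormatError(ValueError):
    """Raised when an input table violates the format contract."""


@dataclass
class CountTable:
    """A samples x features matrix of non-negative counts or intensities.

    Parameters
    ----------
    counts
        DataFrame with sample ids as the index and feature ids as columns.
    group
        Optional mapping of each sample to a two-level group label
        (e.g. ``"H"`` / ``"L"`` for heavily / less contaminated).
    """

    counts: pd.DataFrame
    group: pd.Series | None = None

    def __post_init__(self) -> None:
        counts = self.counts
        if counts.index.has_duplicates:
            raise FormatError("duplicate sample ids")
        if counts.columns.has_duplicates:
            raise FormatError("duplicate feature ids")
        values = counts.to_numpy()
        if not np.isfinite(values).all():
            raise FormatError("non-finite count values")
        if (values < 0).any():
            raise FormatError("negative count values")
        if self.group is not None:
            group = pd.Series(self.group)
            missing = counts.index.difference(group.index)
            if len(missing):
                raise FormatError(f"group label missing for samples: {list(missing)}")
            self.group = group.reindex(counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def n_samples(self) -> int:
        return self.counts.shape[0]

    @property
    def n_features(self) -> int:
        return self.counts.shape[1]

    def sample_sums(self) -> pd.Series:
        return self.counts.sum(axis=1)

    def relative_abundance(self) -> pd.DataFrame:
        """Counts scaled to proportions per sample."""
        totals = self.counts.sum(axis=1)
        if (totals == 0).any():
            bad = list(totals.index[totals == 0])
            raise ValueError(f"all-zero samples: {bad}")
        return self.counts.div(totals, axis=0)

    def select_samples(self, sample_ids) -> "CountTable":
        group = self.group.loc[sample_ids] if self.group is not None else None
        return CountTable(self.counts.loc[sample_ids], group)

    def select_features(self, feature_ids) -> "CountTable":
        return CountTable(self.counts[list(feature_ids)], self.group)

    def group_samples(self, label: str) -> list[str]:
        if self.group is None:
            raise ValueError("table has no group labels")
        return list(self.group.index[self.group == label])

    def __eq__(self, other) -> bool:  # value equality, for round-trip tests
        if not isinstance(other, CountTable):
            return NotImplemented
        same_counts = self.counts.equals(other.counts)
        if self.group is None or other.group is None:
            return same_counts and self.group is other.group
        return same_counts and self.group.equals(other.group)


@dataclass
class TaxonomyMap:
    """Feature -> ranked lineage (domain ... genus).

    Unknown ranks are stored as ``"unclassified"``.
    """

    lineages: pd.DataFrame  # index: feature id, columns: RANKS

    def __post_init__(self) -> None:
        df = self.lineages
        if df.index.has_duplicates:
            raise FormatError("duplicate feature ids in taxonomy")
        df = df.reindex(columns=list(RANKS)).fillna(UNCLASSIFIED)
        self.lineages = df.astype(str)

    def rank_of(self, feature: str, rank: str) -> str:
        if rank not in RANKS:
            raise KeyError(f"unknown rank {rank!r}; expected one of {RANKS}")
        if feature not in self.lineages.index:
            return UNCLASSIFIED
        return str(self.lineages.at[feature, rank])

    def labels_at(self, rank: str, features) -> pd.Series:
        """Rank label per feature; unmapped features get 'unclassified'."""
        if rank not in RANKS:
            raise KeyError(f"unknown rank {rank!r}; expected one of {RANKS}")
        col = self.lineages[rank]
        return pd.Series(
            [col.get(f, UNCLASSIFIED) for f in features], index=list(features)
        )

    def unmapped(self, features) -> list[str]:
        return [f for f in features if f not in self.lineages.index]

    def features_of(self, taxon: str, features=None) -> list[str]:
        """Features whose lineage contains `taxon` at any rank."""
        df = self.lineages
        if features is not None:
            df = df.loc[df.index.intersection(list(features))]
        mask = (df == taxon).any(axis=1)
        return list(df.index[mask])


@dataclass
class EnvTable:
    """Samples x environmental variables (metal concentrations, totals)."""

    values: pd.DataFrame

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            raise FormatError("duplicate sample ids in environment table")
        if not np.isfinite(self.values.to_numpy(dtype=float)).all():
            raise FormatError("non-finite environment values")
        self.values = self.values.astype(float)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def variables(self) -> list[str]:
        return list(self.values.columns)

    def aligned_to(self, sample_ids) -> pd.DataFrame:
        missing = [s for s in sample_ids if s not in self.values.index]
        if missing:
            raise KeyError(f"environment table missing samples: {missing}")
        return self.values.loc[list(sample_ids)]


@dataclass
class EcoNetwork:
    """Undirected co-occurrence network over features.

    Each edge carries the correlation ``r`` that produced it, its ``sign``
    and ``weight = |r|``; ``st`` is the similarity threshold used, so every
    edge satisfies ``|r| >= st``.
    """

    graph: nx.Graph
    st: float

    def __post_init__(self) -> None:
        for u, v, data in self.graph.edges(data=True):
            if u == v:
                raise ValueError("self-loop in network")
            if abs(data["r"]) < self.st:
                raise ValueError(
                    f"edge ({u},{v}) has |r|={abs(data['r']):.4f} below st={self.st}"
                )

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_links(self) -> int:
        return self.graph.number_of_edges()

    def edge_table(self) -> pd.DataFrame:
        rows = [
            {"node1": u, "node2": v, "r": d["r"], "sign": d["sign"]}
            for u, v, d in self.graph.edges(data=True)
        ]
        return pd.DataFrame(rows, columns=["node1", "node2", "r", "sign"])


@dataclass
class ModulePartition:
    """Node -> module id assignment with its modularity score."""

    assignment: dict = field(default_factory=dict)
    modularity: float = float("nan")

    @property
    def n_modules(self) -> int:
        return len(set(self.assignment.values()))

    def members(self, module_id) -> list:
        return sorted(n for n, m in self.assignment.items() if m == module_id)

    def module_sizes(self) -> pd.Series:
        return pd.Series(self.assignment).value_counts().sort_index()

    def modules_of_min_size(self, min_size: int) -> list:
        sizes = self.module_sizes()
        return list(sizes.index[sizes >= min_size])
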