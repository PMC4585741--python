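"""Topological characterization of co-occurrence networks.

Degree statistics, clustering, geodesic distance, degree-distribution
model fits, fast-greedy (CNM) modularity, and comparison against random
network null models. Edge signs and weights are ignored throughout;
the published indexes are unweighted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .containers import EcoNetwork, ModulePartition


def _as_graph(net) -> nx.Graph:
    return net.graph if isinstance(net, EcoNetwork) else net


def avg_degree(n_nodes: int, n_links: int) -> float:
    """avgK = 2 L / N, reported to 3 decimals."""
    if n_nodes <= 0:
        raise ValueError("network has no nodes")
    return round(2.0 * n_links / n_nodes, 3)


def clustering_and_distance(net) -> tuple[float, float]:
    """(average clustering coefficient, average geodesic distance).

    GD averages shortest-path lengths over all connected node pairs;
    pairs in different components are excluded, so GD stays finite for
    fragmented networks.
    """
    g = _as_graph(net)
    if g.number_of_nodes() == 0:
        raise ValueError("empty network")
    avg_cc = nx.average_clustering(g)
    total, n_pairs = 0.0, 0
    for component in nx.connected_components(g):
        sub = g.subgraph(component)
        k = sub.number_of_nodes()
        if k < 2:
            continue
        for _src, lengths in nx.all_pairs_shortest_path_length(sub):
            total += sum(lengths.values())
        n_pairs += k * (k - 1)
    if n_pairs == 0:
        raise ValueError("no connected node pair; geodesic distance undefined")
    return float(avg_cc), total / n_pairs


# ---------------------------------------------------------------------------
# degree-distribution fits
# ---------------------------------------------------------------------------

def fit_degree_distributions(net) -> pd.DataFrame:
    """Fit P(k) to power-law, truncated power-law and exponential decay.

    All three are fit by least squares in log space (the power law is a
    straight line there, matching the "linear correlation" reading of the
    fit quality): ln f = b - gamma ln k [- k/k_c]. Returns one row per
    model with parameters and R^2 in log space.
    """
    g = _as_graph(net)
    degrees = np.asarray([d for _n, d in g.degree() if d > 0])
    ks, freq = np.unique(degrees, return_counts=True)
    if ks.size < 4:
        raise ValueError("need at least 4 distinct degrees to fit models")
    ln_f = np.log(freq.astype(float))
    ln_k = np.log(ks.astype(float))
    k = ks.astype(float)

    def r2(fitted):
        ss_res = ((ln_f - fitted) ** 2).sum()
        ss_tot = ((ln_f - ln_f.mean()) ** 2).sum()
        return 1.0 - ss_res / ss_tot

    rows = {}
    # power law: ln f = b - gamma ln k
    x = np.column_stack([np.ones_like(ln_k), -ln_k])
    beta, *_ = np.linalg.lstsq(x, ln_f, rcond=None)
    rows["power_law"] = {"gamma": beta[1], "k_c": np.nan, "r_squared": r2(x @ beta)}
    # truncated power law: ln f = b - gamma ln k - k/k_c
    x = np.column_stack([np.ones_like(ln_k), -ln_k, -k])
    beta, *_ = np.linalg.lstsq(x, ln_f, rcond=None)
    kc = 1.0 / beta[2] if beta[2] != 0 else np.inf
    rows["truncated_power_law"] = {
        "gamma": beta[1],
        "k_c": kc,
        "r_squared": r2(x @ beta),
    }
    # exponential: ln f = b - k/k_c
    x = np.column_stack([np.ones_like(k), -k])
    beta, *_ = np.linalg.lstsq(x, ln_f, rcond=None)
    kc = 1.0 / beta[1] if beta[1] != 0 else np.inf
    rows["exponential"] = {"gamma": np.nan, "k_c": kc, "r_squared": r2(x @ beta)}
    return pd.DataFrame(rows).T


# ---------------------------------------------------------------------------
# modularity
# ---------------------------------------------------------------------------

def modularity_score(g: nx.Graph, communities) -> float:
    """Q = sum_m [ l_m/L - (d_m / 2L)^2 ] evaluated directly."""
    return float(nx.community.modularity(g, communities))


def greedy_modularity(net) -> ModulePartition:
    """Fast-greedy (Clauset-Newman-Moore) modularity optimization.

    Agglomerative: singleton communities merged by best modularity gain
    until no merge improves Q. Module ids are assigned in decreasing
    community size, ties broken by smallest member label.
    """
    g = _as_graph(net)
    if g.number_of_nodes() == 0:
        raise ValueError("empty network")
    if g.number_of_edges() == 0:
        raise ValueError("network has no edges")
    communities = nx.community.greedy_modularity_communities(g)
    communities = sorted(
        (sorted(c, key=str) for c in communities),
        key=lambda c: (-len(c), str(c[0])),
    )
    assignment = {node: m for m, members in enumerate(communities) for node in members}
    q = modularity_score(g, communities)
    return ModulePartition(assignment=assignment, modularity=q)


# ---------------------------------------------------------------------------
# report & null comparison
# ---------------------------------------------------------------------------

@dataclass
class TopologyReport:
    n_nodes: int
    n_links: int
    avg_k: float
    avg_cc: float
    gd: float
    n_modules: int
    n_modules_min5: int
    modularity: float
    degree_fits: pd.DataFrame

    def to_dict(self) -> dict:
        d = {
            "n_nodes": self.n_nodes,
            "n_links": self.n_links,
            "avgK": self.avg_k,
            "avgCC": self.avg_cc,
            "GD": self.gd,
            "n_modules": self.n_modules,
            "n_modules_min5": self.n_modules_min5,
            "modularity": self.modularity,
        }
        for model, row in self.degree_fits.iterrows():
            d[f"{model}_r_squared"] = float(row["r_squared"])
        return d


def characterize(net) -> tuple[TopologyReport, ModulePartition]:
    """Full topology report: sizes, avgK, avgCC, GD, modularity, fits."""
    g = _as_graph(net)
    n, l = g.number_of_nodes(), g.number_of_edges()
    avg_cc, gd = clustering_and_distance(g)
    partition = greedy_modularity(g)
    try:
        fits = fit_degree_distributions(g)
    except ValueError:
        fits = pd.DataFrame(
            np.nan,
            index=["power_law", "truncated_power_law", "exponential"],
            columns=["gamma", "k_c", "r_squared"],
        )
    report = TopologyReport(
        n_nodes=n,
        n_links=l,
        avg_k=avg_degree(n, l),
        avg_cc=avg_cc,
        gd=gd,
        n_modules=partition.n_modules,
        n_modules_min5=len(partition.modules_of_min_size(5)),
        modularity=partition.modularity,
        degree_fits=fits,
    )
    return report, partition


def _null_graph(g: nx.Graph, mode: str, rng) -> nx.Graph:
    n, l = g.number_of_nodes(), g.number_of_edges()
    if mode == "er":
        return nx.gnm_random_graph(n, l, seed=int(rng.integers(2**31)))
    h = g.copy()
    nswap = 100 * l
    try:
        nx.double_edge_swap(h, nswap=nswap, max_tries=10 * nswap,
                            seed=int(rng.integers(2**31)))
    except nx.NetworkXError:
        warnings.warn("degree-preserving rewiring impossible; falling back to ER nulls")
        return nx.gnm_random_graph(n, l, seed=int(rng.integers(2**31)))
    return h


def null_comparison(
    net, n_null: int = 100, mode: str = "rewire", seed: int = 0,
    indices: tuple[str, ...] = ("avgCC", "GD", "modularity"),
) -> pd.DataFrame:
    """Empirical indexes versus random-network nulls with a one-sample t-test.

    `mode` is ``"rewire"`` (degree-preserving double-edge swaps, 100 L
    attempted swaps per null) or ``"er"`` (Erdos-Renyi with the same node
    and link counts). Each row gives the empirical value, the null mean
    and sd, and the two-sided one-sample t-test of the null draws against
    the empirical value.
    """
    if mode not in ("rewire", "er"):
        raise ValueError(f"unknown null mode {mode!r}")
    g = _as_graph(net)
    rng = np.random.default_rng(seed)

    def measure(graph) -> dict:
        out = {}
        if "avgCC" in indices or "GD" in indices:
            cc, gd = clustering_and_distance(graph)
            out["avgCC"], out["GD"] = cc, gd
        if "modularity" in indices:
            out["modularity"] = greedy_modularity(graph).modularity
        return out

    empirical = measure(g)
    draws = {k: [] for k in indices}
    for _ in range(n_null):
        h = _null_graph(g, mode, rng)
        vals = measure(h)
        for k in indices:
            draws[k].append(vals[k])
    if n_null < 30:
        warnings.warn("fewer than 30 nulls; t-test validity is questionable")
    rows = {}
    for k in indices:
        null = np.asarray(draws[k])
        mean, sd = null.mean(), null.std(ddof=1)
        # locate the empirical value in the null ensemble: the deviation is
        # scaled by the ensemble spread (not the sd of the mean), so a
        # typical null draw is not flagged
        if sd > 0:
            t = (empirical[k] - mean) / sd
            p = 2 * stats.t.sf(abs(t), n_null - 1)
        else:
            t = 0.0 if empirical[k] == mean else np.inf
            p = 1.0 if empirical[k] == mean else 0.0
        rows[k] = {
            "empirical": empirical[k],
            "null_mean": mean,
            "null_sd": sd,
            "t": float(t),
            "p": float(p),
            "n_null": n_null,
        }
    return pd.DataFrame(rows).T
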