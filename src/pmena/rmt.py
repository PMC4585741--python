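"""Random-matrix-theory thresholded co-occurrence networks.

The similarity threshold is chosen from the spectrum of the thresholded
correlation matrix: as the threshold rises, the nearest-neighbor spacing
distribution (NNSD) of the unfolded eigenvalues transitions from the
Gaussian orthogonal ensemble law (Wigner surmise, correlated system) to
Poisson statistics (uncorrelated / localized system). The chosen
threshold is the smallest grid value whose spacings are consistent with
Poisson, and the network keeps every pair with |r| at or above it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from scipy.interpolate import UnivariateSpline

from .containers import CountTable, EcoNetwork

#: default threshold grid scanned for the NNSD transition
DEFAULT_GRID = np.round(np.arange(0.30, 1.00, 0.01), 2)

#: minimum number of distinct eigenvalues required for a spacing fit
MIN_EIGENVALUES = 20


# ---------------------------------------------------------------------------
# input filtering & correlation
# ---------------------------------------------------------------------------

def prevalence_filter(
    table: CountTable, min_present: int = 5, group: str | None = None
) -> CountTable:
    """Keep features with nonzero counts in >= `min_present` samples.

    With `group` given, both the samples and the presence count are
    restricted to that group (the study design: present in at least 5 of
    the 8 replicates of a group).
    """
    sub = table.select_samples(table.group_samples(group)) if group else table
    if min_present > sub.n_samples:
        raise ValueError(
            f"min_present={min_present} exceeds group size {sub.n_samples}"
        )
    present = (sub.counts > 0).sum(axis=0)
    keep = list(present.index[present >= min_present])
    if not keep:
        raise ValueError("prevalence filter removed every feature")
    return sub.select_features(keep)


@dataclass
class CorrelationMatrix:
    """Pairwise feature correlations with exact symmetry and unit diagonal."""

    feature_ids: list
    r: np.ndarray
    n_samples: int

    def __post_init__(self) -> None:
        r = np.asarray(self.r, dtype=float)
        if not np.allclose(r, r.T):
            raise ValueError("correlation matrix must be symmetric")
        r = (r + r.T) / 2.0
        np.fill_diagonal(r, 1.0)
        self.r = r

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.r, index=self.feature_ids, columns=self.feature_ids)


def correlation_matrix(table: CountTable) -> CorrelationMatrix:
    """Pearson correlation of log10 relative abundances.

    Zeros are handled with a pseudocount of half the smallest nonzero
    relative abundance (added throughout, preserving order); features
    with zero variance after transform are excluded with a warning.
    """
    if table.n_samples < 4:
        raise ValueError("at least 4 samples required for correlations")
    rel = table.relative_abundance().to_numpy()
    nonzero = rel[rel > 0]
    pseudo = 0.5 * nonzero.min()
    logged = np.log10(rel + pseudo)
    sd = logged.std(axis=0)
    keep = sd > 0
    if not keep.all():
        dropped = [f for f, k in zip(table.feature_ids, keep) if not k]
        warnings.warn(f"excluded {len(dropped)} zero-variance features: {dropped[:5]}...")
    logged = logged[:, keep]
    ids = [f for f, k in zip(table.feature_ids, keep) if k]
    r = np.corrcoef(logged, rowvar=False)
    return CorrelationMatrix(feature_ids=ids, r=r, n_samples=table.n_samples)


# ---------------------------------------------------------------------------
# spectral unfolding and spacing fits
# ---------------------------------------------------------------------------

def unfold_spectrum(eigenvalues: np.ndarray) -> np.ndarray:
    """Unfold a spectrum so the mean local eigenvalue spacing is one.

    Exact duplicates are collapsed, then the empirical cumulative spectral
    density is smoothed with a cubic spline G and each eigenvalue is
    mapped to n * G(lambda). The output is non-decreasing and its mean
    nearest-neighbor spacing is ~1 by construction.
    """
    lam = np.unique(np.round(np.asarray(eigenvalues, dtype=float), 10))
    n = lam.size
    if n < MIN_EIGENVALUES:
        raise ValueError(
            f"only {n} distinct eigenvalues; lower the similarity threshold"
        )
    ecdf = np.arange(1, n + 1) / n
    spline = UnivariateSpline(lam, ecdf, k=3)
    unfolded = n * spline(lam)
    unfolded = np.maximum.accumulate(unfolded)
    return unfolded


#: Poisson nearest-neighbor spacing law P(s) = exp(-s)
def poisson_cdf(s):
    return 1.0 - np.exp(-np.asarray(s, dtype=float))


#: Wigner surmise (GOE) P(s) = (pi s / 2) exp(-pi s^2 / 4)
def goe_cdf(s):
    s = np.asarray(s, dtype=float)
    return 1.0 - np.exp(-np.pi * s**2 / 4.0)


def nnsd_fit(
    spacings: np.ndarray, bin_width: float = 0.1, s_max: float = 3.0
) -> tuple[float, float]:
    """Chi-square goodness of fit of spacings against Poisson and GOE laws.

    The spacing histogram uses fixed-width bins on [0, s_max] with the
    tail pooled into the last bin; bins are further pooled from the right
    until every expected count is at least 5 (standard chi-square
    validity). Returns ``(poisson_p, goe_p)``.
    """
    s = np.asarray(spacings, dtype=float)
    s = s[np.isfinite(s)]
    if s.size < MIN_EIGENVALUES:
        raise ValueError(f"need >= {MIN_EIGENVALUES} spacings, got {s.size}")
    edges = np.arange(0.0, s_max + bin_width / 2, bin_width)
    edges = np.append(edges, np.inf)
    observed, _ = np.histogram(s, bins=edges)

    pvals = []
    for cdf in (poisson_cdf, goe_cdf):
        upper = cdf(edges[1:-1])
        probs = np.diff(np.concatenate(([0.0], upper, [1.0])))
        obs, exp = _pool_bins(observed.astype(float), probs * s.size)
        chi2 = ((obs - exp) ** 2 / exp).sum()
        dof = max(len(obs) - 1, 1)
        pvals.append(float(stats.chi2.sf(chi2, dof)))
    return pvals[0], pvals[1]


def _pool_bins(obs: np.ndarray, exp: np.ndarray, min_expected: float = 5.0):
    """Pool histogram bins from the right until each expected count >= 5."""
    obs_list, exp_list = list(obs), list(exp)
    i = len(exp_list) - 1
    while i > 0:
        if exp_list[i] < min_expected:
            exp_list[i - 1] += exp_list.pop(i)
            obs_list[i - 1] += obs_list.pop(i)
        i -= 1
    if exp_list and exp_list[0] < min_expected and len(exp_list) > 1:
        exp_list[1] += exp_list.pop(0)
        obs_list[1] += obs_list.pop(0)
    return np.asarray(obs_list), np.asarray(exp_list)


# ---------------------------------------------------------------------------
# threshold scan & network construction
# ---------------------------------------------------------------------------

@dataclass
class ThresholdScan:
    """Record of the NNSD scan over the threshold grid and the chosen st."""

    scan: pd.DataFrame  # threshold, n_nodes, n_links, n_eigenvalues, poisson_p, goe_p
    st: float | None

    def __post_init__(self) -> None:
        th = self.scan["threshold"].to_numpy()
        if (np.diff(th) <= 0).any():
            raise ValueError("thresholds must be strictly increasing")
        if self.st is not None and self.st not in set(np.round(th, 10)):
            raise ValueError("chosen st must belong to the scanned grid")


def _thresholded_adjacency(r: np.ndarray, s: float):
    """Zero |r| < s off-diagonal, drop link-free features; returns submatrix."""
    a = np.where(np.abs(r) >= s, r, 0.0)
    np.fill_diagonal(a, 1.0)
    linked = (np.abs(a) > 0).sum(axis=1) > 1  # beyond the diagonal
    return a[np.ix_(linked, linked)], int(linked.sum())


def select_threshold(
    corr: CorrelationMatrix,
    grid: np.ndarray = DEFAULT_GRID,
    poisson_alpha: float = 0.05,
) -> ThresholdScan:
    """Scan the threshold grid for the GOE-to-Poisson NNSD transition.

    At each threshold the matrix is hard-thresholded, features without
    links are dropped, the spectrum is unfolded and the spacing
    distribution tested against both laws. The chosen st is the smallest
    threshold whose Poisson goodness-of-fit p exceeds `poisson_alpha`.
    Thresholds with too few distinct eigenvalues are recorded with NaN
    p-values. Deterministic given `corr`.
    """
    r = corr.r
    rows = []
    chosen = None
    for s in np.round(np.asarray(grid, dtype=float), 10):
        a, n_nodes = _thresholded_adjacency(r, s)
        n_links = int((np.abs(np.triu(a, 1)) > 0).sum())
        row = {
            "threshold": float(s),
            "n_nodes": n_nodes,
            "n_links": n_links,
            "n_eigenvalues": 0,
            "poisson_p": np.nan,
            "goe_p": np.nan,
        }
        if n_links > 0:
            eig = np.linalg.eigvalsh(a)
            try:
                unfolded = unfold_spectrum(eig)
                spacings = np.diff(unfolded)
                row["n_eigenvalues"] = unfolded.size
                row["poisson_p"], row["goe_p"] = nnsd_fit(spacings)
            except ValueError:
                row["n_eigenvalues"] = np.unique(np.round(eig, 10)).size
        rows.append(row)
        if chosen is None and np.isfinite(row["poisson_p"]) and row["poisson_p"] > poisson_alpha:
            chosen = float(s)
    return ThresholdScan(scan=pd.DataFrame(rows), st=chosen)


def build_network(corr: CorrelationMatrix, st: float) -> EcoNetwork:
    """Network with an edge for every feature pair with |r| >= st."""
    if not 0.0 < st < 1.0:
        raise ValueError("st must lie in (0, 1)")
    r = corr.r
    ids = corr.feature_ids
    g = nx.Graph()
    n = len(ids)
    ii, jj = np.where(np.triu(np.abs(r) >= st, 1))
    if ii.size == 0:
        raise ValueError(f"no feature pair reaches |r| >= {st}; network is empty")
    for i, j in zip(ii, jj):
        rij = float(r[i, j])
        g.add_edge(ids[i], ids[j], r=rij, sign=1 if rij >= 0 else -1, weight=abs(rij))
    return EcoNetwork(graph=g, st=float(st))
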