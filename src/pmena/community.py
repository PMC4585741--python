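"""Community-level statistics: rarefaction, diversity, dissimilarity,
ordination, response ratios, group tests, Mantel tests, and intensity
normalization/aggregation.

Conventions
-----------
* Shannon diversity is reported in nats (natural log).
* Distances default to Bray-Curtis on relative abundances.
* All permutation p-values use p = (1 + #extreme) / (1 + n_perm), so
  p >= 1/(n_perm + 1) always.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform

from .containers import CountTable, TaxonomyMap


# ---------------------------------------------------------------------------
# rarefaction
# ---------------------------------------------------------------------------

def rarefy(table: CountTable, depth: int, seed: int = 0) -> CountTable:
    """Subsample each sample without replacement to exactly `depth` reads."""
    counts = table.counts.to_numpy().astype(np.int64)
    totals = counts.sum(axis=1)
    for sid, total in zip(table.sample_ids, totals):
        if total < depth:
            raise ValueError(
                f"sample {sid!r} has only {total} reads, fewer than depth {depth}"
            )
    rng = np.random.default_rng(seed)
    out = np.vstack(
        [rng.multivariate_hypergeometric(row, depth) for row in counts]
    )
    return CountTable(
        pd.DataFrame(out, index=table.sample_ids, columns=table.feature_ids),
        group=table.group,
    )


def rarefaction_curve(
    table: CountTable, depths, reps: int = 10, seed: int = 0
) -> pd.DataFrame:
    """Mean observed richness per sample at each subsampling depth.

    Depths exceeding a sample's total are truncated (NaN) with a warning.
    """
    depths = list(depths)
    if any(b <= a for a, b in zip(depths, depths[1:])):
        raise ValueError("depths must be strictly increasing")
    rng = np.random.default_rng(seed)
    counts = table.counts.to_numpy().astype(np.int64)
    totals = counts.sum(axis=1)
    result = np.full((len(table.sample_ids), len(depths)), np.nan)
    for i, row in enumerate(counts):
        for j, d in enumerate(depths):
            if d > totals[i]:
                warnings.warn(
                    f"depth {d} exceeds total of sample {table.sample_ids[i]!r}; truncated"
                )
                continue
            rich = [
                int((rng.multivariate_hypergeometric(row, d) > 0).sum())
                for _ in range(reps)
            ]
            result[i, j] = float(np.mean(rich))
    return pd.DataFrame(result, index=table.sample_ids, columns=depths)


# ---------------------------------------------------------------------------
# alpha diversity
# ---------------------------------------------------------------------------

def shannon_pielou(table: CountTable) -> pd.DataFrame:
    """Richness S, Shannon H' (nats) and Pielou evenness J per sample.

    H' = -sum p_i ln p_i over nonzero p; J = H'/ln S (J = 1 when S = 1).
    """
    rel = table.relative_abundance().to_numpy()
    rows = []
    for i, p in enumerate(rel):
        p = p[p > 0]
        s = p.size
        h = float(-(p * np.log(p)).sum())
        j = 1.0 if s == 1 else h / np.log(s)
        rows.append({"richness": s, "shannon": h, "pielou": j})
    return pd.DataFrame(rows, index=table.sample_ids)


# ---------------------------------------------------------------------------
# distances & dissimilarity tests
# ---------------------------------------------------------------------------

def bray_curtis(table: CountTable, relative: bool = True) -> pd.DataFrame:
    """Bray-Curtis distance matrix D(a,b) = sum|x_a - x_b| / sum(x_a + x_b)."""
    x = table.relative_abundance().to_numpy() if relative else table.counts.to_numpy()
    if not relative and (x.sum(axis=1) == 0).any():
        warnings.warn("all-zero samples present; their mutual distance is set to 0")
    with np.errstate(invalid="ignore"):
        d = squareform(pdist(x, metric="braycurtis"))
    d = np.nan_to_num(d, nan=0.0)
    return pd.DataFrame(d, index=table.sample_ids, columns=table.sample_ids)


def _group_indices(group: pd.Series) -> tuple[np.ndarray, list]:
    labels = sorted(group.unique())
    if len(labels) != 2:
        raise ValueError(f"exactly two groups required, got {labels}")
    g = np.asarray([labels.index(v) for v in group])
    if min((g == 0).sum(), (g == 1).sum()) < 2:
        raise ValueError("each group needs at least 2 samples")
    return g, labels


def _mrpp_delta(d: np.ndarray, g: np.ndarray) -> float:
    n = len(g)
    delta = 0.0
    for k in (0, 1):
        idx = np.flatnonzero(g == k)
        if len(idx) < 2:
            raise ValueError("group with fewer than 2 samples")
        sub = d[np.ix_(idx, idx)]
        within = sub[np.triu_indices(len(idx), 1)].mean()
        delta += len(idx) / n * within
    return float(delta)


def _anosim_r(rank_d: np.ndarray, g: np.ndarray, iu) -> float:
    same = (g[iu[0]] == g[iu[1]])
    r_w = rank_d[same].mean()
    r_b = rank_d[~same].mean()
    n = len(g)
    return float((r_b - r_w) / (n * (n - 1) / 4.0))


def _permanova_f(d2: np.ndarray, g: np.ndarray) -> float:
    n = len(g)
    ss_total = d2[np.triu_indices(n, 1)].sum() / n
    ss_within = 0.0
    for k in (0, 1):
        idx = np.flatnonzero(g == k)
        sub = d2[np.ix_(idx, idx)]
        ss_within += sub[np.triu_indices(len(idx), 1)].sum() / len(idx)
    ss_between = ss_total - ss_within
    a = 2
    return float((ss_between / (a - 1)) / (ss_within / (n - a)))


def dissimilarity_tests(
    distance: pd.DataFrame, group: pd.Series, n_perm: int = 999, seed: int = 0
) -> pd.DataFrame:
    """MRPP, ANOSIM and PERMANOVA on one distance matrix.

    Returns a DataFrame indexed by test with columns statistic, p,
    n_permutations. MRPP's delta is extreme when *small*; ANOSIM R and the
    PERMANOVA pseudo-F when *large*.
    """
    if n_perm < 99:
        warnings.warn(f"n_perm={n_perm} is low; p-values are coarse")
    d = distance.to_numpy()
    group = group.loc[distance.index]
    g, _ = _group_indices(group)
    n = len(g)
    iu = np.triu_indices(n, 1)
    rank_d = stats.rankdata(d[iu])
    d2 = d**2

    obs = {
        "MRPP": _mrpp_delta(d, g),
        "ANOSIM": _anosim_r(rank_d, g, iu),
        "PERMANOVA": _permanova_f(d2, g),
    }
    hits = {t: 0 for t in obs}
    rng = np.random.default_rng(seed)
    for _ in range(n_perm):
        gp = rng.permutation(g)
        if _mrpp_delta(d, gp) <= obs["MRPP"]:
            hits["MRPP"] += 1
        if _anosim_r(rank_d, gp, iu) >= obs["ANOSIM"]:
            hits["ANOSIM"] += 1
        if _permanova_f(d2, gp) >= obs["PERMANOVA"]:
            hits["PERMANOVA"] += 1
    rows = {
        t: {
            "statistic": obs[t],
            "p": (1 + hits[t]) / (1 + n_perm),
            "n_permutations": n_perm,
        }
        for t in obs
    }
    return pd.DataFrame(rows).T


# ---------------------------------------------------------------------------
# ordination (CA / DCA)
# ---------------------------------------------------------------------------

def _ca_axis(y: np.ndarray, prev_axes: list, n_segments: int, detrend: bool,
             max_iter: int = 500, tol: float = 1e-10):
    """One correspondence-analysis axis by reciprocal averaging.

    For axes beyond the first, sample scores are either orthogonalized
    (plain CA, detrend=False) or detrended against each previous axis by
    Hill's method of segment means (detrend=True) at every iteration.
    """
    row_w = y.sum(axis=1)
    col_w = y.sum(axis=0)
    total = y.sum()
    x = np.arange(y.shape[0], dtype=float)
    x = (x - np.average(x, weights=row_w)) / max(x.std(), 1.0)
    ev_prev = 0.0
    for _ in range(max_iter):
        col_scores = (y.T @ x) / col_w
        x_new = (y @ col_scores) / row_w
        for prev in prev_axes:
            if detrend:
                x_new = _detrend_by_segments(x_new, prev, row_w, n_segments)
            else:
                proj = np.average(x_new * prev, weights=row_w / total)
                norm = np.average(prev * prev, weights=row_w / total)
                x_new = x_new - proj / norm * prev
        x_new = x_new - np.average(x_new, weights=row_w)
        norm = np.sqrt(np.average(x_new**2, weights=row_w))
        if norm < 1e-14:
            return x_new, 0.0
        ev = norm  # shrinkage per cycle approximates the eigenvalue
        x_new = x_new / norm
        if abs(ev - ev_prev) < tol and np.max(np.abs(x_new - x)) < 1e-8:
            x = x_new
            ev_prev = ev
            break
        x = x_new
        ev_prev = ev
    return x, ev_prev


def _detrend_by_segments(x: np.ndarray, axis: np.ndarray, w: np.ndarray,
                         n_segments: int) -> np.ndarray:
    """Remove the segment-wise mean of x along `axis` (Hill's detrending)."""
    order = np.argsort(axis, kind="stable")
    edges = np.linspace(0, len(x), n_segments + 1).astype(int)
    out = x.copy()
    for a, b in zip(edges[:-1], edges[1:]):
        if b > a:
            idx = order[a:b]
            out[idx] = out[idx] - np.average(out[idx], weights=w[idx])
    return out


def dca(
    table: CountTable, n_axes: int = 4, n_segments: int = 26, detrend: bool = True
) -> pd.DataFrame:
    """Detrended correspondence analysis sample scores.

    Correspondence analysis by reciprocal averaging; axes beyond the first
    are detrended against earlier axes by Hill's segment method (default
    26 segments). Axis 1 equals plain CA axis 1. With ``detrend=False``
    this is plain CA with orthogonalization.
    """
    y = table.counts.to_numpy(dtype=float)
    keep_rows = y.sum(axis=1) > 0
    keep_cols = y.sum(axis=0) > 0
    y = y[np.ix_(keep_rows, keep_cols)]
    if y.shape[0] < 3 or y.shape[1] < 2:
        raise ValueError("table too small for ordination after pruning")
    # independence (rank-1) check: no structure beyond the margins
    expected = np.outer(y.sum(axis=1), y.sum(axis=0)) / y.sum()
    inertia = ((y - expected) ** 2 / expected).sum() / y.sum()
    if inertia < 1e-12:
        raise ValueError("table has zero inertia (independent margins); no axes")
    axes = []
    for _ in range(n_axes):
        x, _ev = _ca_axis(y, axes, n_segments, detrend=detrend)
        axes.append(x)
    scores = np.column_stack(axes)
    out = pd.DataFrame(
        scores,
        index=np.asarray(table.sample_ids)[keep_rows],
        columns=[f"DCA{i+1}" for i in range(n_axes)],
    )
    return out


# ---------------------------------------------------------------------------
# response ratios
# ---------------------------------------------------------------------------

@dataclass
class RRResult:
    """Per-taxon log response ratios with CIs plus taxa seen in one group only."""

    ratios: pd.DataFrame  # index taxon; mean_H, mean_L, RR, se, ci_low, ci_high, call
    one_group_only: pd.DataFrame  # taxon -> group it is present in


def response_ratio(
    table: CountTable,
    taxonomy: TaxonomyMap,
    rank: str = "phylum",
    conf: float = 0.95,
    group_order: tuple[str, str] | None = None,
) -> RRResult:
    """ln(mean_H / mean_L) of relative abundance aggregated at `rank`.

    The standard error uses the delta method on the log of each group
    mean, se^2 = s_H^2/(n_H m_H^2) + s_L^2/(n_L m_L^2); the confidence
    interval uses a Student-t critical value with Welch-Satterthwaite
    degrees of freedom (calibrated at small n, unlike the plain normal
    quantile). A taxon whose mean is zero in one group is reported
    separately rather than given an infinite ratio.
    """
    if table.group is None:
        raise ValueError("table has no group labels")
    g, labels = _group_indices(table.group)
    if group_order is None:
        group_order = (labels[0], labels[1])
    rel = table.relative_abundance()
    tax_labels = taxonomy.labels_at(rank, table.feature_ids)
    agg = rel.T.groupby(tax_labels.values).sum().T  # samples x taxa

    a = agg.loc[table.group == group_order[0]].to_numpy()
    b = agg.loc[table.group == group_order[1]].to_numpy()
    n_a, n_b = a.shape[0], b.shape[0]
    m_a, m_b = a.mean(axis=0), b.mean(axis=0)
    v_a, v_b = a.var(axis=0, ddof=1), b.var(axis=0, ddof=1)

    rows, only = [], []
    for k, taxon in enumerate(agg.columns):
        if m_a[k] == 0 and m_b[k] == 0:
            continue
        if m_a[k] == 0 or m_b[k] == 0:
            only.append(
                {"taxon": taxon, "present_in": group_order[0] if m_a[k] > 0 else group_order[1]}
            )
            continue
        rr = float(np.log(m_a[k] / m_b[k]))
        va = v_a[k] / (n_a * m_a[k] ** 2)
        vb = v_b[k] / (n_b * m_b[k] ** 2)
        se = float(np.sqrt(va + vb))
        if se == 0:
            crit = 0.0
            df = np.inf
        else:
            df = (va + vb) ** 2 / (
                va**2 / max(n_a - 1, 1) + vb**2 / max(n_b - 1, 1)
            )
            crit = float(stats.t.ppf(0.5 + conf / 2.0, df))
        lo, hi = rr - crit * se, rr + crit * se
        call = "ns"
        if lo > 0:
            call = f"enriched_{group_order[0]}"
        elif hi < 0:
            call = f"enriched_{group_order[1]}"
        rows.append(
            {
                "taxon": taxon,
                f"mean_{group_order[0]}": m_a[k],
                f"mean_{group_order[1]}": m_b[k],
                "RR": rr,
                "se": se,
                "ci_low": lo,
                "ci_high": hi,
                "call": call,
            }
        )
    ratios = pd.DataFrame(rows).set_index("taxon") if rows else pd.DataFrame()
    only_df = pd.DataFrame(only).set_index("taxon") if only else pd.DataFrame()
    return RRResult(ratios=ratios, one_group_only=only_df)


# ---------------------------------------------------------------------------
# Mantel test
# ---------------------------------------------------------------------------

def mantel(
    d1: pd.DataFrame | np.ndarray,
    d2: pd.DataFrame | np.ndarray,
    n_perm: int = 999,
    seed: int = 0,
) -> tuple[float, float]:
    """Mantel correlation r_M of two distance matrices with a permutation p.

    r_M is the Pearson correlation of the strictly-upper-triangle entries;
    the null distribution permutes rows and columns of the second matrix
    jointly. The p-value is two-sided (negative correlations count as
    extreme too).
    """
    a = np.asarray(d1, dtype=float)
    b = np.asarray(d2, dtype=float)
    if a.shape != b.shape or a.shape[0] != a.shape[1]:
        raise ValueError("distance matrices must be square and same-shaped")
    n = a.shape[0]
    iu = np.triu_indices(n, 1)
    x, y = a[iu], b[iu]
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant off-diagonal entries; correlation undefined")
    r_obs = float(np.corrcoef(x, y)[0, 1])
    rng = np.random.default_rng(seed)
    xc = x - x.mean()
    denom_x = np.sqrt((xc**2).sum())
    hits = 0
    for _ in range(n_perm):
        p = rng.permutation(n)
        yp = b[np.ix_(p, p)][iu]
        yc = yp - yp.mean()
        r = float((xc @ yc) / (denom_x * np.sqrt((yc**2).sum())))
        if abs(r) >= abs(r_obs) - 1e-12:
            hits += 1
    return r_obs, (1 + hits) / (1 + n_perm)


# ---------------------------------------------------------------------------
# per-feature group tests
# ---------------------------------------------------------------------------

def group_difference_test(
    matrix: pd.DataFrame, group: pd.Series, alpha: float = 0.1,
    equal_var: bool = False,
) -> pd.DataFrame:
    """Two-sample t-test per feature (columns) between two groups.

    Welch by default; with ``equal_var=True`` this is the pooled t-test,
    equivalent to one-way ANOVA for two groups via t^2 = F. Features with
    zero variance in both groups get p = 1 when the means are equal and
    p = 0 otherwise.
    """
    group = group.loc[matrix.index]
    g, labels = _group_indices(group)
    a = matrix.loc[group == labels[0]].to_numpy()
    b = matrix.loc[group == labels[1]].to_numpy()
    with np.errstate(invalid="ignore", divide="ignore"):
        t, p = stats.ttest_ind(a, b, equal_var=equal_var, axis=0)
    mean_diff = a.mean(axis=0) - b.mean(axis=0)
    degenerate = ~np.isfinite(p)
    p = np.where(degenerate, np.where(mean_diff == 0, 1.0, 0.0), p)
    with np.errstate(invalid="ignore"):
        fallback = np.where(mean_diff == 0, 0.0, np.inf * np.sign(mean_diff))
    t = np.where(np.isfinite(t), t, fallback)
    direction = np.where(mean_diff > 0, labels[0], labels[1])
    direction = np.where(mean_diff == 0, "none", direction)
    return pd.DataFrame(
        {"t": t, "p": p, "direction": direction, "significant": p < alpha},
        index=matrix.columns,
    )


# ---------------------------------------------------------------------------
# intensity normalization & aggregation
# ---------------------------------------------------------------------------

def normalize_intensity(table: CountTable) -> CountTable:
    """Scale each sample so its total equals the grand mean of sample totals."""
    totals = table.counts.sum(axis=1)
    if (totals == 0).any():
        bad = list(totals.index[totals == 0])
        raise ValueError(f"all-zero samples cannot be normalized: {bad}")
    target = float(totals.mean())
    scaled = table.counts.mul(target / totals, axis=0)
    return CountTable(scaled, group=table.group)


def aggregate_by_map(
    matrix: pd.DataFrame, mapping: dict | pd.Series
) -> tuple[pd.DataFrame, list]:
    """Sum features into categories; returns (categories x samples, unmapped).

    `matrix` is samples x features; `mapping` sends feature -> category.
    The grand total over mapped features is conserved.
    """
    mapping = dict(mapping)
    if not mapping:
        raise ValueError("empty feature -> category map")
    unmapped = [f for f in matrix.columns if f not in mapping]
    mapped = [f for f in matrix.columns if f in mapping]
    cats = pd.Series({f: mapping[f] for f in mapped})
    agg = matrix[mapped].T.groupby(cats.values).sum()  # categories x samples
    return agg, unmapped
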