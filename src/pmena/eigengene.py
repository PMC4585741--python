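"""Module eigengene analysis.

Each network module is summarized by the first right-singular vector of
its standardized OTU-by-sample log-abundance matrix (the module
eigengene), with the fraction of variance it explains, per-OTU module
memberships, trait-based significance, and module-environment Mantel
tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform

from .community import mantel
from .containers import CountTable, EnvTable


def _log_profiles(table: CountTable, features) -> pd.DataFrame:
    """Log10 relative-abundance profiles (half-minimum pseudocount)."""
    rel = table.relative_abundance()
    nonzero = rel.to_numpy()[rel.to_numpy() > 0]
    pseudo = 0.5 * nonzero.min()
    return np.log10(rel[list(features)] + pseudo)


def _corr_p(r: np.ndarray, n: int) -> np.ndarray:
    """Two-sided p of a Pearson correlation from the t distribution, n-2 df."""
    r = np.clip(r, -1 + 1e-15, 1 - 1e-15)
    t = r * np.sqrt((n - 2) / (1 - r**2))
    return 2 * stats.t.sf(np.abs(t), n - 2)


@dataclass
class ModuleEigengene:
    module_id: object
    eigengene: pd.Series  # unit-norm sample profile
    var_explained: float
    memberships: pd.Series  # OTU -> correlation with the eigengene
    membership_p: pd.Series
    singular_value_fractions: np.ndarray  # sigma_i^2 / sum sigma^2


def module_eigengene(
    table: CountTable,
    module_nodes,
    module_id=None,
    min_size: int = 5,
) -> ModuleEigengene:
    """SVD summary of one module's abundance profiles.

    OTU log-abundance rows are standardized to mean 0, sd 1; the
    eigengene is the first right-singular vector, sign-oriented so the
    mean module membership is positive; variance explained is
    sigma_1^2 / sum sigma_i^2.
    """
    module_nodes = list(module_nodes)
    if len(module_nodes) < min_size:
        raise ValueError(
            f"module has {len(module_nodes)} OTUs, fewer than min_size={min_size}"
        )
    if table.n_samples < 3:
        raise ValueError("at least 3 samples required")
    profiles = _log_profiles(table, module_nodes).T  # OTUs x samples
    sd = profiles.std(axis=1, ddof=0)
    degenerate = list(sd.index[sd == 0])
    if degenerate:
        warnings.warn(f"dropped zero-variance OTUs from module: {degenerate}")
        profiles = profiles.drop(index=degenerate)
        if profiles.shape[0] < 2:
            raise ValueError("too few variable OTUs left in module")
    z = profiles.sub(profiles.mean(axis=1), axis=0).div(
        profiles.std(axis=1, ddof=0), axis=0
    )
    _u, s, vt = np.linalg.svd(z.to_numpy(), full_matrices=False)
    fractions = s**2 / (s**2).sum()
    eig = pd.Series(vt[0], index=table.sample_ids, name=module_id)
    memberships = module_membership(table, eig, features=list(profiles.index))
    if memberships["membership"].mean() < 0:
        eig = -eig
        memberships["membership"] = -memberships["membership"]
    return ModuleEigengene(
        module_id=module_id,
        eigengene=eig,
        var_explained=float(fractions[0]),
        memberships=memberships["membership"],
        membership_p=memberships["p"],
        singular_value_fractions=fractions,
    )


def module_membership(
    table: CountTable, eigengene: pd.Series, features=None
) -> pd.DataFrame:
    """Pearson correlation of each OTU profile with an eigengene, plus p.

    Constant profiles yield NaN membership (undefined correlation).
    """
    features = list(features) if features is not None else table.feature_ids
    profiles = _log_profiles(table, features)
    e = eigengene.loc[table.sample_ids].to_numpy()
    x = profiles.to_numpy()
    xc = x - x.mean(axis=0)
    ec = e - e.mean()
    denom = np.sqrt((xc**2).sum(axis=0) * (ec**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(denom > 0, (xc * ec[:, None]).sum(axis=0) / denom, np.nan)
    p = np.where(np.isnan(r), np.nan, _corr_p(r, table.n_samples))
    return pd.DataFrame({"membership": r, "p": p}, index=features)


def eigengenes_for_partition(
    table: CountTable, partition, min_size: int = 5
) -> dict:
    """Eigengene per module of a partition with at least `min_size` OTUs."""
    out = {}
    for mod in partition.modules_of_min_size(min_size):
        members = [m for m in partition.members(mod) if m in table.counts.columns]
        if len(members) < min_size:
            continue
        out[mod] = module_eigengene(table, members, module_id=mod, min_size=min_size)
    return out


def trait_significance(
    table: CountTable, env: EnvTable, partition=None
) -> tuple[pd.DataFrame, pd.DataFrame | None]:
    """Gene significance GS = |Pearson r(OTU abundance, trait)| per pair.

    Returns (OTU x trait GS matrix, module-mean GS per trait or None).
    Constant traits raise.
    """
    values = env.aligned_to(table.sample_ids)
    constant = [v for v in values.columns if values[v].std(ddof=0) == 0]
    if constant:
        raise ValueError(f"constant traits: {constant}")
    profiles = _log_profiles(table, table.feature_ids)
    x = profiles.to_numpy()
    xc = x - x.mean(axis=0)
    xnorm = np.sqrt((xc**2).sum(axis=0))
    gs = np.empty((len(table.feature_ids), len(values.columns)))
    for j, var in enumerate(values.columns):
        t = values[var].to_numpy()
        tc = t - t.mean()
        denom = xnorm * np.sqrt((tc**2).sum())
        with np.errstate(invalid="ignore", divide="ignore"):
            r = np.where(denom > 0, (xc * tc[:, None]).sum(axis=0) / denom, np.nan)
        gs[:, j] = np.abs(r)
    gs_df = pd.DataFrame(gs, index=table.feature_ids, columns=values.columns)
    module_means = None
    if partition is not None:
        modules = pd.Series(
            {f: partition.assignment.get(f) for f in table.feature_ids}
        ).dropna()
        module_means = gs_df.loc[modules.index].groupby(modules).mean()
    return gs_df, module_means


def module_trait_mantel(
    eigengenes: pd.DataFrame | dict,
    env: EnvTable,
    n_perm: int = 999,
    seed: int = 0,
) -> pd.DataFrame:
    """Mantel tests between module eigengenes and environmental traits.

    Distances are Euclidean: among samples on each eigengene, and on each
    z-scored trait. Returns a row per (module, trait) with signed r_M and
    the two-sided permutation p.
    """
    if isinstance(eigengenes, dict):
        eigengenes = pd.DataFrame(
            {m: e.eigengene for m, e in eigengenes.items()}
        ).T
    samples = list(eigengenes.columns)
    if len(samples) < 4:
        raise ValueError("at least 4 samples required for Mantel tests")
    values = env.aligned_to(samples)
    rows = []
    for mod in eigengenes.index:
        d1 = squareform(pdist(eigengenes.loc[mod].to_numpy()[:, None]))
        for k, var in enumerate(values.columns):
            t = values[var].to_numpy()
            if t.std(ddof=0) == 0:
                raise ValueError(f"constant trait {var!r}")
            tz = (t - t.mean()) / t.std(ddof=0)
            d2 = squareform(pdist(tz[:, None]))
            r_m, p = mantel(d1, d2, n_perm=n_perm, seed=seed)
            rows.append({"module": mod, "trait": var, "r_M": r_m, "p": p})
    return pd.DataFrame(rows)
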