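"""Synthetic two-group community data with planted correlation modules.

The generator emulates the design of a two-group sediment survey: 16
samples in two groups of 8 (heavily vs. less contaminated), each rarefied
to a fixed depth of 13,000 reads, with a few thousand OTUs whose
log-abundances carry planted modular correlation structure, a
group-differential phylum composition, and environmental variables tied to
chosen modules. Ground truth (module membership, latent profiles, links)
is returned alongside so downstream network, modularity and eigengene
stages can be scored for recovery.

Model: for module *m*, a latent sample profile z_m ~ N(0, 1) is drawn;
an OTU *i* planted in *m* has log-abundance offset a_i = lambda_i * z_m +
eps_i with loading lambda_i ~ U(0.7, 1.0) and eps ~ N(0, noise_sd).
Unplanted OTUs receive pure noise of matched variance. Per-sample counts
are multinomial draws of size `depth` from the softmax of baseline +
offset log-abundances, so every sample's total equals the depth exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import RANKS, UNCLASSIFIED, CountTable, EnvTable, TaxonomyMap

#: Environmental variables measured in the emulated survey (ppm; totals for C, N).
ENV_VARIABLES = ("Hg", "As", "Co", "Cd", "Cr", "Ni", "Pb", "Cu", "Mn", "Zn", "N", "C")

#: Phylum relative frequencies used to assign taxonomy (survey-like mix).
DEFAULT_PHYLUM_FREQS = {
    "Proteobacteria": 0.38,
    "Firmicutes": 0.24,
    "Bacteroidetes": 0.08,
    "Acidobacteria": 0.06,
    "Actinobacteria": 0.05,
    "Chloroflexi": 0.05,
    "Crenarchaeota": 0.03,
    "Verrucomicrobia": 0.03,
    "Planctomycetes": 0.03,
    "Gemmatimonadetes": 0.02,
    UNCLASSIFIED: 0.03,
}

#: Multiplicative H-vs-L fold change of expected abundance per phylum.
DEFAULT_GROUP_EFFECT = {
    "Firmicutes": 1.6,
    "Chloroflexi": 1.6,
    "Crenarchaeota": 1.6,
    "Proteobacteria": 0.6,
    "Actinobacteria": 0.6,
}


@dataclass
class GeneratorConfig:
    """Knobs of the synthetic community; defaults mirror the emulated survey."""

    n_samples_per_group: int = 8
    depth: int = 13_000
    n_otus: int = 500
    module_sizes: tuple[int, ...] = (25, 25)
    within_module_cor: float = 0.9
    noise_sd: float | None = None  # derived from within_module_cor when None
    baseline_sd: float = 1.2  # spread of per-OTU baseline log-abundance
    group_effect: dict = field(default_factory=lambda: dict(DEFAULT_GROUP_EFFECT))
    env_linked_modules: dict = field(
        default_factory=lambda: {"Hg": (0, 0.9), "Pb": (0, 0.9), "Zn": (0, 0.9), "C": (0, 0.9)}
    )
    phylum_freqs: dict = field(default_factory=lambda: dict(DEFAULT_PHYLUM_FREQS))
    env_noise_sd: float | None = None  # derived from target |r| when None
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.within_module_cor <= 1.0:
            raise ValueError("within_module_cor must be in [0, 1]")
        if sum(self.module_sizes) > self.n_otus:
            raise ValueError("module sizes sum exceeds n_otus")
        if any(s < 1 for s in self.module_sizes):
            raise ValueError("empty planted module")
        if self.noise_sd is not None and self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.depth < 1 or self.n_otus < 1 or self.n_samples_per_group < 1:
            raise ValueError("depth, n_otus and n_samples_per_group must be positive")
        for var, (mod, r) in self.env_linked_modules.items():
            if not 0 <= mod < len(self.module_sizes):
                raise ValueError(f"env variable {var!r} linked to unknown module {mod}")
            if not 0.0 <= r <= 1.0:
                raise ValueError(f"target |r| for {var!r} outside [0, 1]")

    @property
    def n_modules(self) -> int:
        return len(self.module_sizes)

    def derived_noise_sd(self, mean_loading: float = 0.85) -> float:
        """Noise sd giving the target within-module correlation.

        For two module members with common loading lambda the pairwise
        correlation is lambda^2 / (lambda^2 + sigma^2); invert at the mean
        loading.
        """
        if self.noise_sd is not None:
            return self.noise_sd
        c = self.within_module_cor
        if c >= 1.0:
            return 0.0
        if c <= 0.0:
            return 10.0 * mean_loading
        return mean_loading * float(np.sqrt(1.0 / c - 1.0))


@dataclass
class GroundTruth:
    """Planted structure: module membership, latent profiles, env links."""

    module_of: pd.Series  # OTU -> module id (-1 for unplanted)
    latents: pd.DataFrame  # modules x samples latent profiles
    env_links: dict  # env variable -> (module id, target |r|)
    log_expected: pd.DataFrame | None = None  # samples x OTUs expected log-abundance

    def members(self, module_id: int) -> list[str]:
        return list(self.module_of.index[self.module_of == module_id])

    @property
    def planted_otus(self) -> list[str]:
        return list(self.module_of.index[self.module_of >= 0])


def _assign_taxonomy(otu_ids, phylum_freqs: dict, rng) -> TaxonomyMap:
    phyla = list(phylum_freqs)
    probs = np.asarray([phylum_freqs[p] for p in phyla], dtype=float)
    probs = probs / probs.sum()
    choice = rng.choice(len(phyla), size=len(otu_ids), p=probs)
    rows = []
    for i, otu in enumerate(otu_ids):
        phylum = phyla[choice[i]]
        if phylum == UNCLASSIFIED:
            rows.append({r: UNCLASSIFIED for r in RANKS})
            continue
        domain = "Archaea" if phylum == "Crenarchaeota" else "Bacteria"
        cls = f"{phylum}_c{rng.integers(1, 4)}"
        genus = f"{phylum}_g{rng.integers(1, 6)}"
        rows.append(
            {
                "domain": domain,
                "phylum": phylum,
                "class": cls,
                "order": f"{phylum}_o1",
                "family": f"{phylum}_f1",
                "genus": genus,
            }
        )
    return TaxonomyMap(pd.DataFrame(rows, index=list(otu_ids)))


def generate_dataset(
    config: GeneratorConfig | None = None,
) -> tuple[CountTable, TaxonomyMap, EnvTable, GroundTruth]:
    """Draw one synthetic dataset under `config` (deterministic per seed)."""
    cfg = config or GeneratorConfig()
    rng = np.random.default_rng(cfg.seed)

    n_per = cfg.n_samples_per_group
    sample_ids = [f"H{i+1}" for i in range(n_per)] + [f"L{i+1}" for i in range(n_per)]
    group = pd.Series(["H"] * n_per + ["L"] * n_per, index=sample_ids)
    n_samples = 2 * n_per
    otu_ids = [f"OTU{i+1}" for i in range(cfg.n_otus)]

    taxonomy = _assign_taxonomy(otu_ids, cfg.phylum_freqs, rng)

    # planted module membership: first sum(module_sizes) OTUs, contiguous blocks
    module_of = pd.Series(-1, index=otu_ids, dtype=int)
    start = 0
    for m, size in enumerate(cfg.module_sizes):
        module_of.iloc[start : start + size] = m
        start += size

    latents = rng.standard_normal((cfg.n_modules, n_samples))
    loadings = rng.uniform(0.7, 1.0, size=cfg.n_otus)
    sigma = cfg.derived_noise_sd()
    signal_scale = float(np.sqrt(0.85**2 + sigma**2))  # marginal sd of planted offsets

    baseline = rng.normal(0.0, cfg.baseline_sd, size=cfg.n_otus)
    offsets = rng.normal(0.0, 1.0, size=(n_samples, cfg.n_otus))
    for i in range(cfg.n_otus):
        m = module_of.iloc[i]
        if m >= 0:
            offsets[:, i] = loadings[i] * latents[m] + sigma * offsets[:, i]
        else:
            offsets[:, i] *= signal_scale

    log_abund = baseline[None, :] + offsets
    # group-differential phyla: multiply expected abundance in H by the fold
    phylum_of = taxonomy.labels_at("phylum", otu_ids)
    is_h = (group == "H").to_numpy()
    for phylum, fold in cfg.group_effect.items():
        cols = (phylum_of == phylum).to_numpy()
        if cols.any():
            log_abund[np.ix_(is_h, cols)] += np.log(fold)

    probs = np.exp(log_abund - log_abund.max(axis=1, keepdims=True))
    probs /= probs.sum(axis=1, keepdims=True)
    counts = np.vstack([rng.multinomial(cfg.depth, p) for p in probs])

    table = CountTable(
        pd.DataFrame(counts, index=sample_ids, columns=otu_ids), group=group
    )
    truth = GroundTruth(
        module_of=module_of,
        latents=pd.DataFrame(
            latents, index=list(range(cfg.n_modules)), columns=sample_ids
        ),
        env_links=dict(cfg.env_linked_modules),
        log_expected=pd.DataFrame(log_abund, index=sample_ids, columns=otu_ids),
    )
    env = generate_env(truth, cfg, rng=rng)
    return table, taxonomy, env, truth


def generate_env(
    truth: GroundTruth, config: GeneratorConfig, rng=None
) -> EnvTable:
    """Environmental table with variables tied to planted module latents.

    A linked variable with target |r| = rho is built as
    ``rho * z_m + sqrt(1 - rho^2) * noise`` on the z scale (so the
    population correlation with the module latent equals rho exactly),
    then shifted/scaled to a plausible concentration range. Unlinked
    variables are independent noise.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 7)
    for var, (mod, _r) in truth.env_links.items():
        if mod not in truth.latents.index:
            raise KeyError(f"env variable {var!r} linked to unknown module {mod}")
    sample_ids = list(truth.latents.columns)
    n = len(sample_ids)
    data = {}
    for j, var in enumerate(ENV_VARIABLES):
        if var in truth.env_links:
            mod, rho = truth.env_links[var]
            z = truth.latents.loc[mod].to_numpy()
            z = (z - z.mean()) / z.std()
            x = rho * z + np.sqrt(max(0.0, 1.0 - rho**2)) * rng.standard_normal(n)
        else:
            x = rng.standard_normal(n)
        # scale to a ppm-like positive range; linearity preserves correlations
        data[var] = 50.0 * (j + 1) + 10.0 * (j + 1) * x
    return EnvTable(pd.DataFrame(data, index=sample_ids))
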