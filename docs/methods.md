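# Methods

This note records the models behind `pmena`, the defaults and why they
were chosen, the numerical conventions, and what the synthetic-data
validation does and does not demonstrate.

## Study design emulated

The package targets two-group community surveys: 16 samples split into a
heavily (H) and a less (L) impacted group of 8 replicates each, 16S OTU
counts rarefied to 13,000 reads per sample, an environmental table of
heavy-metal concentrations (Hg, As, Co, Cd, Cr, Ni, Pb, Cu, Mn, Zn, in
ppm) plus total N and C, and optionally a functional-gene intensity
matrix treated as a generic feature table. All stages work for any
two-level design; the defaults encode this layout.

## Community statistics

**Rarefaction** subsamples each sample without replacement to the target
depth using multivariate hypergeometric draws, so totals are conserved
exactly and the expected rarefied richness follows the closed form
E[S] = Σᵢ (1 − C(N−Nᵢ, d)/C(N, d)), which the tests verify by Monte
Carlo.

**Diversity.** Shannon H′ = −Σ pᵢ ln pᵢ is reported in nats (the log
base is a convention; natural log is the package's choice) and Pielou
J = H′/ln S, with J defined as 1 for S = 1.

**Dissimilarity.** Distances default to Bray–Curtis on relative
abundances — the field's default for OTU tables; the choice of metric is
exposed. Because "dissimilarity testing" in this literature spans
several permutation tests, three are computed over one shared seeded
permutation stream: MRPP (weighted mean within-group distance δ, small
values extreme), ANOSIM (rank-based R, large extreme) and PERMANOVA
(pseudo-F on squared distances, large extreme). All permutation
p-values are computed as (1 + #extreme)/(1 + n_perm), so p is never
below 1/(n_perm+1); the default is 999 permutations. The ANOSIM and
PERMANOVA statistics are cross-checked against scikit-bio in the test
suite; MRPP has no installed reference and is verified against its
defining formula.

**DCA.** Correspondence analysis is run by reciprocal averaging; axes
beyond the first are detrended with Hill's method of segment means
(default 26 segments, 4 axes — the conventional decorana defaults).
Axis 1 is identical to plain CA and is checked against an independent
SVD of the chi-square-standardized matrix. A table whose entries equal
the product of its margins has zero inertia and is rejected rather than
ordinated. No installed Python library provides DCA, hence the
in-package implementation.

**Response ratios.** RR = ln(m̄_H/m̄_L) per taxon after summing relative
abundances to the requested rank. The variance follows the delta method
on the log of each group mean (the standard meta-analytic log response
ratio): se² = s²_H/(n_H m̄²_H) + s²_L/(n_L m̄²_L). The confidence
interval uses a Student-t critical value with Welch–Satterthwaite
degrees of freedom rather than the plain normal quantile: with 8
replicates per group the z-interval's true coverage is ≈ 93% (it ignores
the variability of the estimated variances, P(|t₁₄| < 1.96) ≈ 0.93),
while the t-interval is calibrated — the coverage simulation in the
acceptance suite verifies it sits in the binomial band around 95%. Taxa
with a zero mean in one group are listed as "present only in X" rather
than given an infinite ratio.

**Mantel tests** correlate the strictly-upper-triangle entries of two
distance matrices and permute rows and columns of the second jointly.
The p-value is two-sided, since negative distance correlations are
meaningful for module–environment coupling.

**Intensity normalization** rescales each sample so its total equals the
grand mean of sample totals (within-sample proportions preserved), the
usual treatment of array-style intensity matrices before group
comparison.

## RMT network construction

Correlations are Pearson on log₁₀ relative abundances with a
pseudocount of half the smallest nonzero relative abundance added
throughout; the log stabilizes the heavy-tailed abundance distribution
and is common practice for molecular ecological networks. OTUs are
first prevalence-filtered (default: nonzero in at least 5 of a group's 8
replicates).

The similarity threshold is selected from spectral statistics rather
than a fixed cutoff. For each threshold s on a grid (default 0.30–0.99,
step 0.01) the matrix is hard-thresholded at |r| ≥ s, features without
any remaining link are dropped, and the eigenvalues are *unfolded*:
exact duplicates are collapsed, a cubic smoothing spline Ĝ is fit to the
empirical cumulative spectral density, and eᵢ = n·Ĝ(λᵢ), which makes
the mean local spacing 1. The nearest-neighbor spacing histogram (bin
width 0.1 on [0, 3], tail pooled, bins further pooled from the right
until every expected count is at least 5) is tested by chi-square
goodness of fit against the Poisson law e^(−s) and the Wigner surmise
(πs/2)e^(−πs²/4). The chosen st is the smallest grid value whose
Poisson p exceeds 0.05: below the transition the system is correlated
(GOE statistics), above it the surviving blocks are effectively
independent and the superposition of their spectra yields Poisson
spacings. At least 20 distinct eigenvalues are required for a fit;
thresholds that leave fewer are recorded with missing p-values. Both
groups can use their own automatic threshold or be forced to share one,
since published two-group comparisons often impose a common value
(e.g. 0.900) for comparability.

Networks keep every pair with |r| ≥ st as an edge carrying r, its sign,
and weight |r|; isolated features are dropped.

## Topology and null models

Indexes are computed on the unweighted, unsigned graph: avgK = 2L/N,
average local clustering, and mean geodesic distance averaged over
connected pairs only (so fragmented networks get finite values, matching
how published multi-module networks report it). Degree distributions
are fit in log space — ln f = b − γ ln k (power law), with an added
−k/k_c term (truncated) or without the ln k term (exponential) — all by
least squares, with R² reported in log space to match the "linear
correlation" reading of fit quality; the truncated model nests the other
two. Modules come from fast-greedy (Clauset–Newman–Moore) modularity
maximization (networkx implementation) with
Q = Σ_m [l_m/L − (d_m/2L)²]; module counts are reported both in full
and restricted to modules with ≥ 5 members, since small fragments are
usually excluded from downstream summaries.

Null comparison draws degree-preserving rewired graphs (100·L attempted
double-edge swaps each; falls back to Erdős–Rényi when rewiring is
impossible) or Erdős–Rényi graphs with matched N and L. The empirical
index is located in the null ensemble by t = (x − μ_null)/σ_null with a
t reference on n_null − 1 df — the deviation is scaled by the ensemble
spread, not the standard error of the mean, so a network that is itself
a typical null draw is not flagged.

## Module eigengenes

For a module's OTUs, log₁₀ relative-abundance profiles are standardized
to mean 0, sd 1 per OTU (required for the variance-explained
interpretation) and decomposed by SVD. The eigengene is the first
right-singular vector, sign-oriented so the mean module membership is
positive; variance explained is σ₁²/Σσᵢ². Membership is the Pearson
correlation of an OTU with the eigengene, with p from the t distribution
on n−2 df. Modules need at least 5 OTUs to be summarized. Trait-based
gene significance is GS = |r(abundance, trait)|. Module–environment
coupling uses Mantel tests between Euclidean distances on the eigengene
and on each z-scored trait.

## Synthetic communities and what the validation shows

The generator draws, per module m, a latent profile z_m ~ N(0,1) over
samples; member OTU i gets log-abundance offset λᵢ z_m + ε with
λᵢ ~ U(0.7, 1.0) and ε ~ N(0, σ), where σ is derived from the target
within-module correlation c via c = λ̄²/(λ̄² + σ²) (default c = 0.9).
Unplanted OTUs receive matched-variance noise. Baseline log-abundances
are N(0, 1.2), giving a realistic, strongly uneven abundance
distribution. Group effects multiply the expected abundance of chosen
phyla in H (defaults mirror a contamination survey: Firmicutes,
Chloroflexi and Crenarchaeota up; Proteobacteria and Actinobacteria
down). Counts are multinomial per sample from the softmax of the log
abundances at the configured depth, so sample totals are exact.
Environmental variables linked to a module are ρ·z_m + √(1−ρ²)·noise on
the z scale, then affinely mapped to a ppm-like range; defaults link Hg,
Pb, Zn and C to module 0 at |r| = 0.9. Default size: 500 OTUs with two
planted 25-OTU modules — small enough that full threshold scans and
eigen-decompositions run on a desk machine in seconds.

The generator emulates fixed-depth multinomial sampling, modular
correlation, phylum-level group shifts, and environment–module links.
It does **not** simulate sequencing error, chimeras, phylogenetic
autocorrelation, overdispersion beyond the lognormal latent, or
compositional closure effects beyond what the multinomial induces —
passing recovery tests therefore demonstrate correctness of the
algorithms under the stated model, not performance guarantees on
arbitrary real data.

Validation sizes were chosen to keep the full suite in the
tens-of-seconds range: spacing-law calibration uses 500×500 GOE matrices
and 100 seeded runs of 500 exponential spacings; threshold recovery uses
50 seeds of 200-feature block matrices (8 planted blocks, within-block
|r| ≈ 0.95, between-block noise up to |r| = 0.5 — several blocks rather
than two because the Poisson limit arises from superposing many
independent block spectra); statistical calibration uses 200 null
simulations per test and 500 replicates for CI coverage; Mantel power
uses 100 seeds of a reduced 120-OTU configuration.

## Numerical conventions and degenerate inputs

* Permutation p-values: (1 + #extreme)/(1 + n_perm), two-sided for
  Mantel.
* Correlation matrices are symmetrized exactly and the diagonal pinned
  to 1 before eigendecomposition; duplicate eigenvalues are collapsed
  before unfolding because degenerate spectra create zero spacings that
  break the spacing fit.
* Unfolded spectra are forced non-decreasing (cumulative max) before
  differencing.
* Zero-variance features are excluded from correlations and module
  SVDs with a warning; constant traits and constant distance matrices
  raise.
* Two all-zero samples get Bray–Curtis distance 0 with a warning.
* Ties: greedy-modularity module ids are assigned by decreasing size
  then smallest member label; focus-OTU ranking breaks degree ties by
  OTU label.
* All randomness flows through numpy Generators seeded from explicit
  `seed` arguments; CLI runs record seed and parameters in a manifest.

## Known limitations

* The RMT threshold scan can be jumpy on small-sample correlation
  matrices: near the transition the Poisson goodness-of-fit p hovers
  around the 0.05 criterion, and a miss moves the chosen threshold
  substantially higher, fragmenting weaker modules. This mirrors the
  method's behavior on real data, where thresholds are often inspected
  against the scan table (which `select_threshold` always returns)
  rather than taken blindly.
* Modularity and topology ignore edge signs and weights; signed
  modularity is out of scope.
* DCA implements Hill's detrending-by-segments for axes ≥ 2 but not
  decorana's additional nonlinear rescaling of axis lengths; axis-1
  scores are exact CA.
* MRPP uses group-size weights n_g/N; other weightings exist in the
  literature.
* The eigengene sign convention (positive mean membership) is arbitrary
  for modules with balanced positive/negative members.
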