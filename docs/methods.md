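# Methods

This note documents the statistical model behind `commphylo`, the defaults
and why they were chosen, what the synthetic-data generators do and do not
emulate, and the numerical choices a maintainer should know about.

## Dispersion metrics and standardized effect sizes

All dispersion statistics are means over entries of a pairwise species
distance matrix restricted to a quadrat's occupants. Phylogenetic distances
are patristic path lengths on a rooted tree with branch lengths in time
units; trait distances are Euclidean in z-scored (optionally transformed)
trait space. A quadrat with fewer than two species has no pairwise
structure; its metrics are NaN and it is excluded from downstream tests,
with exclusion counts reported in the run log.

Abundance weighting uses products of raw abundances over unordered
heterospecific pairs, which is equivalent to using relative abundances —
scale-invariance is asserted by a property test. MNTD weights each species'
nearest-neighbour distance by that species' abundance.

The standardized effect size of an observed metric against `n_rand` null
draws is (obs − null mean)/null sd, with the sample (n−1) standard
deviation. NRI and NTI carry a −1 factor so that positive values mean
phylogenetic clustering; FD_SES is unsigned so that positive values mean
trait divergence. The rank p-value is (#{null ≤ obs} + 1)/(n_rand + 1),
counting ties conservatively. A quadrat whose null distribution has zero
spread (e.g. a constant distance matrix) gets an undefined SES rather than
an arbitrary zero.

## Null models

**Independent swap** operates on the quadrat × species matrix: two quadrats
and two species are drawn uniformly; if their 2 × 2 occupancy submatrix is a
checkerboard, the abundance values move into the empty cells *within their
species column*. This preserves — exactly — per-quadrat richness,
per-species occurrence frequency, total occupancy, and each species'
abundance multiset. Each null replicate runs a fresh chain of
`swap_burnin` successful swaps (default 1,000) from the observed matrix, so
replicates are not serially correlated. A bounded attempt budget (200 ×
burn-in draws) guards against matrices with no checkerboard (perfectly
nested matrices); the input is then returned with a warning.

**Taxa labels** permutes distance-matrix labels uniformly over the members
of the chosen species pool, making a quadrat's occupants a uniform draw
from the pool while richness and the abundance vector are retained. In the
SES engine this is realized per quadrat as uniform k-subsets of the pool
(the first k slots of a uniform label permutation — the same distribution,
vectorized over replicates), with one deterministic RNG stream per quadrat
spawned from the master seed so parallel or reordered execution cannot
change results.

**Pairing nulls with pools.** The independent swap can never introduce a
species that was not observed, so it is meaningful only for the plot pool;
analyses against a regional pool use the taxa-label null. The `analyze`
pipeline enforces this pairing (and logs it) while leaving both models
available through the library API.

## Species pools, scales, layers

The plot pool is the set of species with nonzero total abundance in the
community matrix; a regional pool is supplied as a species list and must be
a superset of the observed species. Trait standardization uses the active
pool as its population — null draws come from the pool, so z-scores must
too.

Spatial scales aggregate the quadrat lattice into non-overlapping
`b × b`-cell blocks anchored at the plot origin; with 10 m cells, block
edges 1, 2, 5 give 100, 400 and 2500 m². A 5 × 5 lattice is not divisible
by 2, so the 400 m² scale keeps the four complete blocks and discards the
residual 10 m strip — blocks stay spatially independent, which the
per-scale t-test assumes. Layers (tree, shrub) are analysed separately or
merged (`all`) by summing abundances per cell.

## Per-scale and across-scale inference

SES values of all quadrats at a scale — pooled across plots — are tested
against an expectation of zero with a two-tailed one-sample t-test
(α = 0.05 by default); the verdict is clustered/overdispersed (or
divergent/convergent for FD_SES) by the sign of the mean when p < α, else
random. Scales are compared by one-way ANOVA with Tukey's HSD; the compact
letter display assigns one letter per maximal clique of the
"not-significantly-different" graph, so two scales share a letter exactly
when the post-hoc test does not separate them (verified against the
pairwise significance graph by a brute-force test). Kruskal–Wallis with
Dunn's test (Holm-corrected) is available as a rank-based alternative for
clearly non-normal SES distributions. Groups with fewer than two defined
values are lettered "–" and excluded.

## Blomberg's K

With V the Brownian tip covariance (V_ij = root-to-MRCA shared path), the
GLS phylogenetic mean is â = (1ᵀV⁻¹x)/(1ᵀV⁻¹1), MSE0 = (x−â)ᵀ(x−â)/(n−1),
MSE = (x−â)ᵀV⁻¹(x−â)/(n−1), and K is (MSE0/MSE) divided by its Brownian
expectation (tr V − n/(1ᵀV⁻¹1))/(n−1). Solves use a Cholesky factorization
of V computed once and reused across permutations; an explicit-inverse
oracle test pins agreement to 1e-8. If V is singular (duplicate zero-length
tips) a ridge of 1e-10·tr(V)/n is added with a warning. On a star tree K
is exactly 1 for any data — asserted to 1e-9. The permutation test shuffles
tip values and counts K_perm ≥ K_obs (one-sided: signal = more
tree-structured than permuted data). K is not invariant to nonlinear trait
transforms, so the applied transform (default: log10 for seed mass, whose
measured range spans six orders of magnitude; identity for SLA and height)
is recorded in the output alongside the raw trait range.

## Synthetic data: what it emulates, what it does not

- `simulate_yule_tree`: pure-birth tree with crown at time zero and a final
  exponential waiting time after the last speciation (no zero-length tips),
  depth rescaled to 1. This matches the ultrametric, species-level shape of
  a dated barcode phylogeny but not its heavy-tailed branching or
  calibration uncertainty.
- `simulate_bm_traits`: Brownian motion along branches; tip covariance is
  σ²·V (checked by Monte-Carlo against a 3-SE envelope).
  `white_noise_traits` is the no-signal contrast. Measured trait tables are
  produced by affine maps of the simulated values onto realistic field
  ranges (SLA 30.39–440.71 cm²/g; seed mass 0.05–11822.30 g, mapped on the
  log10 scale; height 0.45–8.97 m) — affine on the analysis scale, so
  dispersion and K are unaffected by the cosmetic rescaling.
- `simulate_assembly`: per quadrat, species are drawn sequentially without
  replacement. *random*: uniform weights. *filtering*: weights
  ∝ exp(−strength · d(species, focal)) with one focal species per plot — an
  environmental-optimum proxy that produces clustering without modelling an
  explicit environmental axis. *overdispersion*: each next species weighted
  ∝ exp(+strength · min distance to those already chosen) — a caricature of
  limiting similarity. Strength 0 reduces every mode to uniform sampling
  (chi-square-checked). The default strength of 5 (distances on a depth-1
  tree range up to 2) gives unambiguous direction recovery at 125 quadrats
  and is the documented calibration value used by the acceptance checks.
  Quadrat richness is uniform on 6–14 species, typical woody-species counts
  for 10 m quadrats in semiarid forest; abundances follow a geometric
  rank-abundance series (base 100, ratio 0.7) with Poisson noise, a shape
  SES results are provably insensitive to.
- `make_fixture(paper_scale=True)`: 147-species regional pool, a 51-species
  local candidate pool shared by all plots, 5 plots × 5 × 5 quadrats ×
  2 layers = 250 census rows.

The generators do **not** emulate spatial autocorrelation of environments,
dispersal limitation, intraspecific trait variation, or census error — so
green pipeline tests demonstrate statistical correctness of the machinery,
not ecological realism of any particular verdict on field data.

## Problem sizes used in tests and acceptance checks

Oracle equivalence uses 200 random (tree, community) draws with up to 32
species. Null calibration uses 1,000 random-assembly quadrats against the
147-species pool with 999 randomizations; direction recovery uses 125
quadrats per scenario. K calibration uses 200 Brownian replicates and 500
white-noise replicates on 64-tip trees with 199 permutations each (199
keeps P(p ≤ 0.05) exactly 0.05 under the null on the permutation grid).
Unit tests run reduced-size variants of the same simulations.

## Design choices where the design was open

- Genus-level trees collapse congeners into a polytomy at the age of the
  genus MRCA in the species tree — the only age defined by the input
  without inventing calibration rules. Non-monophyletic genera collapse at
  the MRCA of all members, with a structured warning.
- The 400 m² tiling discards the residual strip (see above) rather than
  overlapping blocks.
- Per-scale t-tests pool sub-quadrats across the five plots.
- The FD randomization defaults to the taxa-label null over the pool;
  shuffling the community matrix instead is available via the null spec.
- Ultrametricity is diagnosed with a relative depth-spread tolerance of
  1e-6; a larger spread warns rather than errors, since rate-smoothed field
  trees carry rounding noise.
- Ties in the compact letter display are broken by ordering groups (and
  cliques) by decreasing mean.

## Known limitations

Occurrence probabilities under the independent swap are not exactly uniform
over all matrices with fixed margins for short chains; the default 1,000
successful swaps per replicate is a pragmatic burn-in, configurable where
mixing is a concern. The SES normal-quantile cutoff (|SES| > 1.96) is
calibrated for approximately normal null distributions; for very small
richness the MNTD null is noticeably skewed and the rank p-value is the
more reliable summary. Blomberg's K assumes the tree is correct and
ultrametric; measurement error in traits biases K downward.
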