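# commphylo

Community phylogenetic and functional dispersion analysis for forest census
data: standardized effect sizes of phylogenetic and trait dispersion under
randomization null models, Blomberg's *K* phylogenetic signal, and
multi-scale / multi-layer / multi-pool assembly inference — plus a
synthetic-data module so the whole pipeline is testable without field data.

## The problem

Whether co-occurring woody species are more closely related (phylogenetic
clustering, the signature of environmental filtering) or more distantly
related (overdispersion, the signature of competitive exclusion) than chance
predicts is the central question of community phylogenetics. The answer
depends on the spatial scale of the census unit, the vertical layer (tree
vs. shrub), the species pool the null model draws from, and whether species
abundances are taken into account. `commphylo` implements that full
inference chain for quadrat-census data: a plot is a grid of contiguous
quadrats (e.g. 5 × 5 cells of 10 m × 10 m), censused per vertical layer,
analysed at nested scales (100, 400, 2500 m²) against a plot-level or
regional species pool.

## The statistics

For each quadrat with species set *S* and abundances *f*, from a pairwise
species distance matrix *d* (patristic distances from a dated phylogeny, or
Euclidean distances in standardized trait space):

- **MPD** = mean of *d(i, j)* over pairs in *S* (abundance-weighted:
  Σ f_i f_j d_ij / Σ f_i f_j over unordered pairs);
- **MNTD** = mean over *i* ∈ *S* of min_{j≠i} *d(i, j)*
  (abundance-weighted by *f_i*);
- **MFD** = the MPD kernel applied to the trait distance matrix.

Each observed value is compared with `n_rand` randomizations (default 999)
under one of two null models: **independent swap** (checkerboard swaps of
the community matrix, preserving quadrat richness and species occurrence
frequency exactly) or **taxa labels** (distance-matrix labels permuted over
the species pool). With null mean *m* and null standard deviation *s*:

- **NRI** = −(MPD_obs − m)/s,  **NTI** = −(MNTD_obs − m)/s
  (positive → clustering, negative → overdispersion);
- **FD_SES** = +(MFD_obs − m)/s
  (positive → trait divergence, negative → convergence).

Per scale, quadrat SES values are tested against an expectation of zero with
a two-tailed one-sample *t*-test; scales are compared by one-way ANOVA +
Tukey HSD and summarised as a compact letter display. Phylogenetic signal in
each trait is quantified by Blomberg's *K* (GLS formulation on the Brownian
covariance of the tree; *K* = 1 is the Brownian expectation) with a
one-sided permutation test.

## Worked example

Simulate a study-scale synthetic data set (147-species regional pool, five
5 × 5-quadrat plots, two layers, random assembly) and analyse it:

```sh
commphylo simulate --outdir fx --paper-scale --seed 7
commphylo analyze --tree fx/tree.nwk --communities fx/communities.csv \
    --traits fx/traits.csv --regional-pool fx/regional_pool.csv \
    --outdir out --seed 7 --n-rand 199
```

`out/scale_report.csv` then holds one row per (layer, pool, index,
weighting, scale). For the whole community (layer `all`), regional pool,
abundance-weighted NRI the run above prints:

```
 scale  n_quadrats  mean_ses    t_stat  p_two_tailed direction letter_group
 100m2         125 -0.057733 -0.773046      0.440966    random            a
 400m2          20 -0.076182 -0.601753      0.554452    random            a
2500m2           5 -0.286848 -1.930011      0.125814    random            a
```

Mean NRI is near zero at every scale, no *t*-test rejects the null, and all
scales share letter `a` — exactly the "phylogenetically random at all
scales" verdict expected for randomly assembled communities. The trait
signal table (`out/signal_k.csv`) for the same run:

```
      trait  range_min  range_max        K   n     p transform
  sla_cm2_g      30.39     440.71 0.792049 147 0.005  identity
seed_mass_g       0.05   11822.30 0.493259 147 0.005     log10
   height_m       0.45       8.97 0.950185 147 0.005  identity
```

Traits evolved under Brownian motion show *K* near 1 with significant
signal at `n_perm = 199` (minimum attainable *p* = 1/200 = 0.005). Running
`commphylo simulate --mode filtering` instead produces significantly
positive NRI (clustering), and `--mode overdispersion` significantly
negative NRI, recovered by the same pipeline.

The same functionality is available as a library
(`commphylo.compute_ses_table`, `commphylo.blomberg_k`,
`commphylo.assemble_report`, ...), and `commphylo validate` checks input
invariants (ultrametricity, matrix validity, pool containment) before a run.

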