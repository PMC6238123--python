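# Methods

`rangephylo` analyses a plot-based plant survey — a rooted, dated
phylogeny of the regional species pool, a plot-by-species abundance
matrix, and per-plot environment (elevation, latitude, longitude) — and
asks whether community composition carries phylogenetic signal along
local (elevation) and broad (latitude/geography) gradients, at the plot
scale and at the habitat scale. This note documents the models, the
numerical choices, and what the synthetic validation does and does not
demonstrate.

## Phylogenetic distances

All metrics are functions of the patristic distance matrix `d(i, j)`:
the sum of branch lengths on the tip-to-tip path. Multifurcating trees
are accepted as-is (patristic distances are well defined on them);
branch lengths of zero are legal, negative lengths are rejected.
Ultrametricity is reported as the max−min root-to-tip depth but not
enforced — a chronogram should be nearly ultrametric, yet nothing below
requires it. Name matching between tree, community matrix and
environment table is exact string matching after trimming whitespace and
replacing spaces with underscores; no fuzzy taxonomy matching is
attempted, so mismatches are dropped loudly rather than guessed at.

## Plot-scale structure: MPD, MNTD and the null model

For the species present in a plot,

- **MPD** — mean of `d` over all unordered distinct pairs ("basal"
  structure, sensitive to deep divergences);
- **MNTD** — mean over species of the distance to the nearest
  co-occurring relative ("terminal" structure, sensitive near the tips).

Both default to presence/absence; abundance weighting is available
(`weighted=True`: product weights on pairs for MPD, abundance weights on
nearest-neighbour terms for MNTD). The weighted MPD averages over
*distinct* pairs; some reference implementations keep the zero-distance
self pairs in the weighted mean, and the test suite checks the exact
conversion between the two conventions.

The null model preserves, for every plot, its species richness and its
multiset of abundance values, and redraws the species identities
uniformly without replacement from the full pool; plots are randomised
independently. The standardised effect size is

    SES = (observed − mean(null)) / sd(null),

with `n_null = 999` by default and a two-sided rank p-value with the
(1 + count)/(n_null + 1) correction. Negative SES = clustering
(co-occurring species closer relatives than expected), positive SES =
overdispersion. SES is invariant to rescaling all branch lengths, so
the time units of the chronogram are immaterial. A tip-label-shuffle
null (one pool relabelling per replicate, preserving co-occurrence
structure) is available behind `null_model="shuffle"`.

Habitat-scale assemblages are element-wise sums of the member plots'
abundance rows; the same pool and null model are applied to the pooled
rows, so plot- and habitat-scale SES are directly comparable.

SES-versus-gradient relations are summarised by ordinary least squares
of per-plot SES on a single predictor (slope, intercept, R², two-sided
slope p), one fit per metric × predictor.

## Habitat delimitation: multivariate regression trees

The habitat classification is a CART-style binary tree whose response is
the whole abundance matrix: node impurity is the sum of squared
deviations of member plots' species vectors from the node mean, and
candidate splits are midpoints between consecutive distinct values of
each numeric predictor (elevation, latitude, optionally longitude). A
maximal tree is grown (`min_leaf = 5`), the weakest-link cost-complexity
sequence is derived, and each candidate size is scored by its
cross-validated relative error

    CVRE = CV prediction SS / total SS about the grand multivariate mean,

averaged over repeated k-fold cross-validation (defaults 10-fold × 50
repeats; fold assignment is seeded). The selected tree minimises mean
CVRE — the minimum rule, not the 1-SE rule — with ties going to the
smaller tree; `R² = 1 − resubstitution relative error` of the selected
tree. On structureless data CVRE is ≈ 1 for every non-trivial size and
the root-only tree is selected. Split ties break by predictor order,
then by the smaller threshold, making fits reproducible. Leaves are
labelled H1..Hk by increasing leaf-mean elevation, then latitude.
Abundances enter untransformed by default; a Hellinger transform
(square-root of row proportions) is available behind a flag. There are
no surrogate splits, no categorical predictors and no missing-value
handling.

## Indicator species: IndVal

For species *s* and habitat *j*: specificity `A = mean abundance in j /
Σ_habitats mean abundance`, fidelity `B = share of j's plots occupied`,
`IndVal = A·B ∈ [0, 1]`, reported on the 0–1 scale (1 = occurs in every
plot of one habitat, absent elsewhere). A species' statistic is its
maximum over habitats; significance comes from permuting the
plot-to-habitat labels (group sizes preserved — the Dufrêne–Legendre
convention) and comparing each species' maximum against its permutation
distribution with the (1 + count)/(n_perm + 1) estimator. Species with
zero total abundance have undefined specificity and are excluded. No
multiple-testing correction is applied by default (a Holm correction is
a one-liner on the output table); the permutation null makes the
per-species test exact, and the suite verifies its size empirically.

## Beta diversity: Dpw, Dnn, Mantel partitioning

Between two assemblages,

- **Dpw** — mean of `d` over all ordered cross pairs, *including* the
  zero self-distances of shared species (the comdist convention; an
  exclude-shared variant would decouple the metric from composition
  overlap);
- **Dnn** — each species' minimum distance into the other assemblage,
  averaged within each direction, then the two directional means
  averaged. This symmetrisation weights both assemblages equally
  regardless of richness; the pooled-minima alternative used by some
  implementations coincides with it at equal richness, and the tests
  check the exact correspondence.

Both are standardised with the same richness-preserving pool
randomisation, applied jointly to every unit in a replicate so that each
pair's null respects both members' richness. Positive SES = assemblages
more phylogenetically distinct than expected.

Geographic distance is the haversine great-circle distance (Earth radius
6,371 km) when longitude is available, otherwise the meridian arc from
latitude alone; elevation distance is the absolute difference in metres.

Association between dissimilarity matrices uses the Mantel statistic
(Pearson correlation of the upper off-diagonal triangles) with
significance from simultaneous row/column permutation; the default
alternative is one-sided "greater", the usual distance-decay hypothesis.
The partial Mantel statistic is the first-order partial correlation
`r_XY·Z`; its null permutes X and recomputes the partial statistic with
`r_YZ` held fixed. The partitioning logic: beta ~ space | environment
indicates dispersal limitation; beta ~ environment | space indicates
environmental filtering. At the habitat scale (4 units, 6 pairs) the
permutation p-value is necessarily coarse — with 4 units only 24
relabellings exist — so habitat-level inference should lean on the
statistic, not the p-value.

## The synthetic survey generator

Because the generator is the source of every validation dataset, its
defaults encode the emulated study design: 236 one-m² plots in four
59-plot elevation zones spanning 1,200–2,200 m, latitudes 36.667–36.883°
N crossed by a river barrier at the latitude midpoint, longitudes
59.283–59.517° E, and four latent habitat types formed by two coarse
elevation bands × the two sides of the barrier. The species pool is a
Yule (pure-birth) tree of 168 tips scaled to depth 1 (crown start, no
stem), with a Brownian trait (root 0, variance = rate × branch length)
supplying a phylogenetically conserved environmental tolerance.

Per-plot richness is Poisson (mean 15, clipped to ≥ 2) drawn from its
own random stream, so richness is *identical across assembly processes
at a given seed* — the null model conditions on richness, and the
generator must not confound process effects with it. Identities are then
drawn without replacement with process-dependent weights:

- **neutral** — uniform;
- **filtering** — Gaussian kernel `exp(−(trait − opt)²/2σ²)` with
  `σ = sd(trait)/(1 + strength)` and `opt` a linear map of elevation
  onto the trait range. `filtering_opt="stepped"` applies the same map
  to the latent band's midpoint elevation, producing block-wise
  composition — the variant used when a recoverable discrete habitat
  structure is wanted;
- **limiting_similarity** — sequential admission rejecting candidates
  closer than a threshold to any resident, the threshold being the
  `q = 0.2·strength/(1 + strength)` quantile of pool pairwise distances.
  The cap at the lowest fifth reflects ultrametric geometry: most pairs
  sit near twice the tree depth, so higher quantiles are infeasible for
  realistic richness. Infeasible plots fall back to the most-distant
  remaining candidate, with a logged warning;
- **dispersal_limitation** — 2-D Gaussian range kernels around uniform
  range centres, with gentle range shrinkage
  (`sd = extent/(1 + strength/8)`) and a hard river barrier: occurrence
  across the latitude break is damped by `exp(−barrier_strength)`
  (default: the process strength). The barrier is a landscape property
  and can be set independently of species vagility via
  `barrier_strength`.

Processes combine multiplicatively via `"filtering+dispersal_limitation"`.
Abundances are i.i.d. geometric (p = 0.3, mean ≈ 3.3) per occurrence —
the abundance distribution is a modelling choice, not an observation.
Everything is deterministic given the scenario seed.

What the generator does *not* emulate: spatially autocorrelated
micro-habitat, climate beyond the linear elevation proxy, grazing or
hydrology, species-abundance distributions with realistic dominance
structure, or observational error. Passing tests therefore demonstrate
the estimators' statistical behaviour under known assembly processes,
not the field realism of any particular dataset.

## Validation design and problem sizes

The validation suite checks, at these deliberately moderate scales:

- exact agreement of MPD/MNTD/Dpw/Dnn/impurity/best-split with
  brute-force enumeration on ≥ 200 random instances each, and exact
  agreement with the R reference implementations (picante, vegan) on a
  small fixture;
- SES calibration under neutrality (200 plots, pool 100, 999 nulls):
  mean within ±0.15, sd within [0.85, 1.15], two-sided rejection within
  [0.02, 0.08];
- process signatures over 10 replicate datasets (60 plots × 60 species):
  filtering → negative mean SES.MPD, limiting similarity → positive
  mean SES.MNTD, each by one-sided sign test;
- habitat recovery (120 plots × 60 species, 5-fold × 5-rep CV): the
  minimum-CVRE tree finds the four latent habitats (Rand index > 0.9)
  in ≥ 8/10 seeds and the root-only tree on neutral data in ≥ 8/10;
- Mantel: empirical size within [0.03, 0.07] over 1,000 independent
  50-unit pairs; dispersal-limitation power (36 plots, SES.Dnn vs
  great-circle distance) in ≥ 8/10 replicates; exact collapse of the
  partial statistic when the conditioner is orthogonalised;
- bitwise reproducibility of a full pipeline run at fixed seeds.

## Known limitations

- The beta-diversity null costs one randomisation per unit pair, so
  plot-level SES matrices on large surveys are the slowest stage; the
  pipeline default is 199 nulls for beta versus 999 for alpha.
- The per-plot uniform pool draw ignores occupancy frequency; frequency-
  weighted ("independent swap"-family) nulls are deliberately out of
  scope.
- The MRT handles numeric predictors only, and CVRE model selection on
  weak structure is intrinsically noisy — the repeated-CV mean reduces
  but does not eliminate selection variability.
- Habitat-level Mantel tests on four units have almost no permutation
  resolution (see above).
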