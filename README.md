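# rangephylo

Community phylogenetics for plot-based plant surveys along environmental
and geographic gradients.

Given a dated phylogeny of a regional species pool, a plot-by-species
abundance matrix, and per-plot environment (elevation, latitude,
longitude), `rangephylo` answers the standard questions of
community-assembly analysis at two spatial scales:

- **Are co-occurring species more or less related than chance?**
  Mean pairwise distance (MPD, "basal" structure) and mean nearest taxon
  distance (MNTD, "terminal" structure) per plot, standardised against a
  richness-preserving null that redraws species identities from the pool:
  `SES = (obs − mean_null)/sd_null`, negative = phylogenetic clustering
  (environmental filtering on conserved tolerances), positive =
  overdispersion (e.g. competitive exclusion of close relatives). SES is
  regressed on elevation and latitude.
- **What are the habitats?** A multivariate regression tree (CART with
  the whole community matrix as response) splits plots on environmental
  thresholds; tree size is selected by minimum cross-validated relative
  error (CVRE), and `R² = 1 − resubstitution relative error`.
- **Which species indicate which habitat?** Dufrêne–Legendre IndVal:
  specificity × fidelity in [0, 1], with a label-permutation test.
- **Is phylogenetic turnover driven by environment or by space?**
  Between-assemblage Dpw/Dnn with the same null model, then Mantel and
  partial Mantel tests of SES matrices against elevation distance and
  great-circle geographic distance: beta ~ space | environment indicates
  dispersal limitation, beta ~ environment | space indicates filtering.

Because such surveys are rarely deposited, the package ships a
first-class synthetic survey generator (`rangephylo.synthetic`) that
emulates a stratified mountainside design — 236 one-m² plots in four
elevation zones over 1,200–2,200 m, a latitudinal river barrier, four
latent habitat types — and assembles communities under known processes
(neutral, filtering, limiting similarity, dispersal limitation, and
combinations). Every estimator is validated against these ground-truth
scenarios; see `docs/methods.md` for the models and their assumptions.

## Worked example

Simulate a four-habitat survey (trait filtering along elevation plus a
hard dispersal barrier at the river), then run each stage:

```python
import numpy as np
import rangephylo as rp

cfg = rp.ScenarioConfig(
    n_species=60, n_plots=120, process="filtering+dispersal_limitation",
    process_strength=3.0, barrier_strength=8.0, filtering_opt="stepped",
    mean_richness=14, seed=5,
)
tree, comm, env, truth = rp.simulate_dataset(cfg)
D = rp.patristic_distances(tree).reorder(list(comm.columns))

model = rp.grow_and_select(comm, env, cv_folds=5, n_cv_reps=5, seed=5)
iv = rp.indval_test(comm, model.leaf_assignment, n_perm=999, seed=5)
ses_mpd = rp.ses("mpd", comm, D, n_null=999, seed=5)
fit = rp.regress_ses(ses_mpd, env, "elevation")

bm = rp.ses_beta(comm.iloc[:40], D, metric="dnn", n_null=199, seed=5)
z = np.nan_to_num(bm.ses); np.fill_diagonal(z, 0.0)
sp = rp.spatial_distances(env.iloc[:40])
simple = rp.mantel(z, sp.geographic, n_perm=999, seed=5)
partial = rp.partial_mantel(z, sp.geographic, sp.elevation, n_perm=999, seed=5)
```

Output (printed by the snippet above with the obvious `print` calls):

```
MRT: 4 habitats, CVRE = 0.672, R^2 = 0.395
elevation <= 1696.3291 (n=120, impurity=23303.9667)
  latitude <= 36.7869 (n=60, impurity=9699.3167)
    leaf H1: n=33 impurity=4880.0606
    leaf H2: n=27 impurity=3199.7037
  latitude <= 36.7779 (n=60, impurity=8973.7500)
    leaf H3: n=34 impurity=3713.3824
    leaf H4: n=26 impurity=2294.6154
significant indicator species (alpha = 0.05): 58 of 60
mean SES.MPD = -2.974; SES.MPD ~ elevation: slope = -3.01e-03, R^2 = 0.265, p = 1.83e-09
Mantel r(SES.Dnn, geographic) = 0.464, p = 0.0010
partial r(SES.Dnn, geographic | elevation) = 0.464, p = 0.0010
```

Reading this: the minimum-CVRE tree recovers the four latent habitats,
splitting first on elevation and then on latitude on both sides, and the
habitat structure is strong enough that nearly every species indicates
its habitat. Trait filtering produces pervasive phylogenetic clustering
(mean SES.MPD ≪ 0) that strengthens with elevation, while the river
barrier produces distance decay of terminal phylogenetic similarity —
the Mantel correlation with geography barely moves when elevation is
held constant, the signature of dispersal limitation rather than
filtering.

## Command line

Every stage is also a subcommand of the `rangephylo` CLI
(`simulate`, `mrt`, `indval`, `alpha`, `beta`, `mantel`), and
`rangephylo all config.yaml` runs the whole pipeline into a run
directory with every table, a content-hash manifest and a log. Runs are
byte-for-byte reproducible at fixed seeds.

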