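# mossgrad

Latitudinal diversity-gradient analysis on gridded landscapes: stacked
ensemble species distribution models (S-SDMs), multisite beta-diversity
partitioning, Lee's *L* bivariate spatial association, and latitudinal band
profiles — with a synthetic-community generator that provides ground truth
for every stage.

## Who this is for

Macroecologists comparing species-richness gradients between taxonomic
groups on an equal-area grid (nominally 100-km pixels) face three recurring
problems: occurrence records are spatially biased by collection effort;
total compositional change must be separated into species *replacement*
and ordered species *loss*; and pixel-wise map comparisons ignore spatial
structure. This package implements the standard computational chain that
addresses all three, end to end, and ships a simulator with two contrasting
community architectures so every stage can be validated against a known
answer.

## The statistics at the core

**Multisite Sørensen partition.** For *n* sites with incidence matrix
rows, let `b_ij` be the number of species in site *i* but not *j*, `S_i`
site richness and `S_T` pooled richness. With
`Smin = Σ_{i<j} min(b_ij, b_ji)`, `Smax = Σ_{i<j} max(b_ij, b_ji)` and
`D = Σ_i S_i − S_T`:

    β_SIM = Smin / (D + Smin)                       (turnover)
    β_SOR = (Smin + Smax) / (2D + Smin + Smax)      (total dissimilarity)
    β_SNE = β_SOR − β_SIM                           (nestedness-resultant)

`β_SIM` reflects replacement independent of richness differences; `β_SNE`
reflects dissimilarity produced by ordered species loss. Because the
measures depend on *n*, regional values are compared through repeated
random 50-pixel subsets (1000 draws by default) and a paired empirical
two-sided p-value.

**Lee's *L*.** With spatial weights `W` and mean-deviations `z_x`, `z_y`,
the local statistic is `L_i = n (Wz_x)_i (Wz_y)_i / (‖z_x‖‖z_y‖)` and the
global statistic is `L = Σ_i L_i / Σ_i (Σ_j w_ij)²`; identity weights
collapse *L* to the Pearson correlation. Per-pixel significance comes from
a Monte Carlo test that jointly permutes the paired observations
(999 permutations, 95% level): pixels are classified Positive / Negative /
not-significant by the rank of the observed local value in its null
distribution.

**Ensemble S-SDMs.** Per species: collinearity screening (drop one of any
predictor pair with |r| > 0.8), three techniques (logistic GLM with
quadratic terms, random forest, a maxent-like weighted logistic), ten
70/30 split-sample replicates scored by AUC and TSS, binarization under
max-TSS and sensitivity = specificity thresholds, and a TSS-weighted
majority vote across all members. Consensus maps are stacked into
potential richness; species with fewer than 15 presences are excluded.

## Worked example

Simulate a community whose northern half is built on ordered species loss
(ranges nested along the temperature gradient) and whose southern half is
built on species replacement, then test the regional contrast:

```python
import numpy as np
import mossgrad as mg

env = mg.make_landscape(n_rows=20, n_cols=20, lat_range=(40, 52), seed=42)
cfg = mg.SimulationConfig(n_species=60, theta_north=1.0, theta_south=0.0,
                          seed=42)
pool = mg.simulate_pool(cfg, env)
truth = mg.simulate_truth(pool, env, seed=43)
regions = mg.split_regions(env.grid, split_latitude=46.0)

north = mg.beta_sample(truth, regions, "north", sites_per_sample=50,
                       n_samples=1000, seed=44)
south = mg.beta_sample(truth, regions, "south", sites_per_sample=50,
                       n_samples=1000, seed=45)
for comp in ("beta_sim", "beta_sne"):
    r = mg.compare_distributions(north, south, comp)
    print(f"{comp}: north median {np.median(north.component(comp)):.3f}, "
          f"south median {np.median(south.component(comp)):.3f}, "
          f"direction {r.direction}, p = {r.p:.3f}")
```

Output:

```
beta_sim: north median 0.458, south median 0.718, direction <, p = 0.001
beta_sne: north median 0.451, south median 0.056, direction >, p = 0.001
```

Turnover is significantly higher in the south and nestedness-resultant
dissimilarity significantly higher in the north — exactly the architecture
the generator was asked for (`theta_north=1` = ordered loss in the north,
`theta_south=0` = replacement in the south). The p-value 0.001 is the
floor of a 1000-resample paired test.

The full chain — biased record sampling, the SDM ensemble, stacking,
Lee's *L* between group maps, beta comparisons and band profiles — runs
from one configuration:

```bash
mossgrad run --seed 7 --out results/run1     # defaults: one 60-species group
mossgrad simulate --rows 20 --cols 20 --species 60 --seed 7 --out sim/
mossgrad sdm --occurrences sim/occurrences.csv --env sim/ --seed 7 --out sdm/
mossgrad beta --matrix sg.csv --samples 1000 --subset 50 --seed 7 --out beta/
mossgrad leel --x a.asc --y b.asc --permutations 999 --seed 7 --out lee/
mossgrad bands --richness sdm/richness_stacked.asc --out bands.csv
```

Each stage writes plain CSV tables and ESRI ASCII rasters; `mossgrad run`
additionally writes the resolved configuration and seed, and two runs with
the same seed produce byte-identical outputs.

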