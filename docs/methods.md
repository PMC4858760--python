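# Methods

This note documents the models, the numerical choices, and what the
synthetic benchmark does and does not demonstrate.

## Spatial frame

All stages share one equal-area lattice (`LatticeGrid`): `n_rows × n_cols`
pixels of edge `pixel_size` (km, nominally 100), stored row-major from the
north-west corner. Row centroids carry latitudes (monotone across rows);
the 46th parallel splits pixels into the north/south regions used by every
regional contrast (pixels whose centroid latitude exceeds the split are
northern). Pixel membership of a point is half-open —
`[x0, x0+s) × [y0, y0+s)` — so boundary points belong deterministically to
the pixel on their lower-left. Ocean/NODATA pixels are excluded from every
statistic rather than zero-filled: zero-filling would fabricate absences.

## Multisite beta-diversity partition

The Sørensen-family multisite measures are computed from the pairwise
building blocks `b_ij` (species in site *i* not in *j*) via matrix algebra
(`A·Aᵀ` for shared species), giving

    β_SIM = Smin / (D + Smin),
    β_SOR = (Smin + Smax) / (2D + Smin + Smax),
    β_SNE = β_SOR − β_SIM,

with `Smin`, `Smax` the summed min/max of `(b_ij, b_ji)` over site pairs
and `D = Σ S_i − S_T`. Species absent from every site in a subset are
dropped from `S_T`: the measure is defined on the realized pool.
Degenerate denominators (identical single-species sites) return 0 by
convention; fewer than two sites or an all-empty matrix raise an error.
The implementation is cross-checked in the test suite against a
brute-force set-operation oracle and against an independent R
implementation (`vegan::nestedbetasor`).

Because multisite dissimilarity depends on the number of sites, regional
and between-group values are compared on equal footing by resampling:
1000 independent without-replacement draws of 50 pixels from each region
(both counts configurable), each draw partitioned separately. Contrasts
use a paired-by-index empirical two-sided p-value: with
`m = #{r : a_r > b_r}` over `R` aligned pairs, `p = 2·min(m/R, 1 − m/R)`,
floored at `1/R`; fully tied distributions report direction `=` with
`p = 1`. Pairing by index was chosen because the two resampled runs are
exchangeable independent sequences; the floor makes the resolution limit
(`1/R`) explicit. Whether pairing or pooling is used changes nothing about
the direction calls and only the granularity of p.

## Lee's L

The bivariate spatial-association statistic is computed from spatially
lagged mean-deviations: `L_i = n·(Wz_x)_i (Wz_y)_i / (‖z_x‖‖z_y‖)`,
`L = Σ L_i / Σ_i (Σ_j w_ij)²`. Properties used as test oracles: identity
weights reduce `L` to Pearson's r exactly; `L` is symmetric in its
arguments and invariant to positive affine rescaling of either map.

Defaults (all configurable): queen contiguity restricted to land pixels,
row-standardized, zero diagonal — standard practice on a lattice.
Significance of the local values uses a Monte Carlo test that **jointly
permutes the paired observations** `(x_i, y_i)` across pixels: the null
preserves the aspatial correlation of the two maps and destroys only the
spatial arrangement, and the same scheme applies at every pixel, which
rank-based classification requires. With 999 permutations and the
observed value included in its own null ranking, a pixel is Positive when
`(#{null ≥ obs} + 1)/1000 ≤ 0.025`, Negative symmetrically. Under iid
inputs the observed rank is uniform, so the two-tailed 95% rule flags 5%
of pixels in expectation; the suite verifies the median rate over 20 seeds
lies in [3%, 7%]. "Rescaled" local maps divide by the maximum |L_i|;
classification operates on ranks and is therefore invariant to any
monotone rescaling.

## Ensemble SDMs and stacking

Collinearity screening is greedy: while any retained pair has |r| > 0.8,
drop — from the worst-offending pair — the variable with the larger mean
absolute correlation to the remaining candidates; constant layers are
excluded up front. The retained set provably contains no pair above the
threshold.

Per species, three techniques are fitted: (1) logistic GLM on linear +
quadratic terms, with a large ridge constant (`C = 1000`) so the fit
approximates the unregularized maximum-likelihood GLM (the default
`C = 1` regularization demonstrably prevents perfect separation of a
separable species); (2) a random forest (100 trees, minimum leaf size 2);
(3) a maxent-like presence/background model implemented as a
class-balanced weighted logistic regression on the same quadratic design.
Background pixels are drawn uniformly from land pixels without a presence
of the focal species, `min(max(n_presences, 1000), n_available)` of them.
Each of the ten replicates holds out a stratified 30% test split; splits
are shared across techniques within a replicate (members of one replicate
see the same data partition), while model-internal randomness is seeded
per (species, technique, replicate) from the master seed. Replicates whose
training split holds fewer than two presences are skipped and logged.

Evaluation uses AUC plus TSS maximized by exhaustive scan over the
observed prediction values (the scan matches the `pred ≥ threshold`
binarization rule exactly — thresholds are always attainable scores); the
second threshold rule picks the score minimizing |sensitivity −
specificity|. Consensus is a weighted majority vote over all
technique × replicate × threshold-rule binary members, weighted by
replicate TSS clipped at zero (configurable to unweighted); an exact tie
votes absence, keeping stacked richness conservative. Stacked potential
richness is the per-pixel sum of consensus maps; the consensus incidence
matrix ("potential composition") feeds the beta-diversity stage, mirroring
the analysis chain the package implements.

## Synthetic communities

The generator produces the study conditions; its defaults are fixed
scientific choices, not tuning knobs.

**Landscape.** Mean temperature decreases linearly northwards
(0.8 °C per degree of latitude from 16 °C at the southern edge);
precipitation runs west–east (oceanic → continental, 900 → 550 mm) so the
two principal climate axes are not collinear — as in Europe, where
temperature is latitudinal but precipitation is longitudinal/oceanic.
Potential evapotranspiration tracks temperature closely (r ≈ 0.99), which
gives the collinearity screen genuine work. Heterogeneity layers (SDs of
temperature, precipitation, PET, altitude) are non-negative smooth random
fields; distance-to-coast and distance-to-refugia complete the classical
driver set for the band analysis. All fields are smooth Gaussian noise
(σ = 2 pixels) scaled by `noise_scale` and fully determined by the seed.

**Species architectures.** The structure mix θ interpolates between two
archetypes. *Ordered loss* (θ = 1): species carry one-sided cold-edge
tolerance limits evenly spaced along the thermal gradient; because limits
are ordered, every range is a subset of the next more cold-tolerant one,
so any set of sites is perfectly nested and multisite turnover is exactly
zero when occupancy is deterministic. *Replacement* (θ = 0): narrow
Gaussian thermal optima evenly spaced along the gradient, breadth
1.5 × spacing, so composition turns over from band to band at roughly
constant richness. `theta_north`/`theta_south` anchor half of the pool in
each region's thermal domain with its own mix, expressing communities
that are loss-structured in one region and replacement-structured in the
other. Occupancy is Bernoulli(suitability) with maximum probability
`1 − noise` (default noise 0.05), giving the SDM stage genuine class
noise; at noise 0 the nested architecture is deterministic.

**Records.** Occurrences are drawn from true presence pixels with
probability proportional to a collection-effort surface; a false presence
can never be emitted. The default scenario draws 24 000 records *with*
replacement on the 20 × 20 / 60-species grid — atlas-style compilations
revisit pixels, and roughly 90% of true presence pixels receive at least
one record — because the method's premise is that the atlas data are
dense but *regionally* biased, not uniformly sparse. The bias-mitigation
benchmark instead uses a sparse regime (3 200 records, 5:1 effort) where
raw record counts visibly understate southern richness.

**SDM candidate predictors.** The ensemble is offered the climatic means
(temperature, precipitation, PET) — the drivers that generate suitability
— while heterogeneity and distance layers remain in the stack as
richness-driver covariates for the band analysis. This mirrors the
field's workflow, where distribution models use macroclimate but richness
models also consider heterogeneity and history.

**What the benchmark does not show.** The generator mimics incidence
patterns, not mechanisms: no dispersal limitation, demography or
speciation; effort surfaces are step functions; niches are separable
Gaussian/threshold responses in at most two drivers. Passing tests
demonstrate that the chain recovers known architecture under these
conditions, not that it would do so for real floras with correlated
niches, range disequilibrium, or effort surfaces correlated with climate.

## Band profiles

Bands are equal strips of projected northing (multiples of the pixel
size), tiling the grid from the northern edge; on the equal-area lattice
the land-pixel count is the area proxy. Both the band sum and the
per-pixel mean of richness are reported. Species–area normalization uses
the Arrhenius form: `normalized = crude × (A_ref/A_band)^z` with `A_ref`
the largest band land area and `z = 0.25` by default (canonical SAR
slope, configurable); equal-area bands are left unchanged for any `z`.
Empty bands are reported but excluded from normalization.

## Determinism and problem sizes

Every stochastic component draws from `numpy` Generators seeded through
`SeedSequence` chains rooted in one master seed (pipeline seed →
group → species → technique → replicate; separate fixed stream keys keep
stages independent). Two runs with the same configuration and seed write
byte-identical tables and rasters, which the suite asserts.

The shipped scenarios are desk-scale by design: directional-recovery runs
use the default 20 × 20 grid with 60 species and the full 1000 × 50
resampling; the bias-mitigation comparison uses 16 × 16 grids with 30
species, 5 replicates and 10 seeds; the determinism check uses 12 × 12
grids with two 12-species groups. These sizes keep a complete validation
run in the minutes range on a single CPU while leaving every algorithmic
path identical to a continental-scale run.

## Known limitations

* The maxent-like member is a weighted logistic model, not the original
  maxent feature-class machinery; it shares the ensemble surface so any
  ≥ 2 members still form a valid consensus.
* Split-sampling is random, not spatially blocked; evaluation scores are
  optimistic under strong spatial autocorrelation.
* The Monte Carlo null for Lee's L permutes pairs jointly; nulls that
  permute one variable only (testing "no cross-association" rather than
  "no spatial structure") would give different p-values.
* ESRI ASCII is the only raster format; coordinate reprojection is out of
  scope — inputs must already share an equal-area grid.
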