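# Methods

This note documents the models, numerical conventions and design
choices behind `phylograin`, in the order data flows through the
pipeline.

## Census conventions and tiling

Stems are points in metres from the southwest plot corner with a species
code and DBH in cm; only stems with DBH strictly above the 1 cm census
floor are admitted. Multi-stemmed trees are assumed collapsed to one row
per tree (largest stem) before ingestion. Life stages are DBH bins:
sapling < 5 cm, juvenile 5–15 cm, adult ≥ 15 cm, with 5 assigned to
juvenile and 15 to adult.

Quadrat grids use half-open cells `[i·s, (i+1)·s)` with the far plot
boundary folded into the last cell — the only convention that partitions
the plot without double counting. Quadrat ids are row-major. Grains of
2.5, 5 and 10 m nest exactly inside the 20 m census blocks, and the
community matrices satisfy exact nesting conservation (the four 2.5 m
children of a 5 m quadrat sum to it, and likewise 5 → 10 m). Quadrats
with no stems are retained as all-zero rows and flagged rather than
dropped, so row indices remain a complete grid.

## Terrain covariates

All windowed metrics use a 3×3 window with *available-neighbor* edge
handling (no padding): edge cells use the five (or three) neighbors
that exist. Horn's eight-neighbor finite differences (with nearest-edge
replication for the derivative stencils) give slope and aspect; the
aspect is folded to `−cos(downslope bearing)`, a continuous southness
score in [−1, 1] (due south +1, due north −1, flat 0), which avoids the
0/360° wrap problem of raw bearings in a linear model. TPI is the focal
elevation minus the mean of the 8 neighbors. TRI is defined here as the
population standard deviation of the 8 neighboring elevations — note
this deviates from Riley's original mean-absolute-difference TRI; the
SD form is the one this package standardizes on. Roughness is the
elevation range of the full 3×3 window, the default of the common
raster toolchains.

Flow direction is D8 steepest descent (drop divided by center distance;
ties take the lowest code; flats and pits take code 0 and terminate
flow). Flow accumulation counts the cells draining through each cell
(self included) by pushing counts down the D8 graph in decreasing
elevation order, which is a valid topological order because flow is
strictly descending. No pit filling or hydrological conditioning is
applied. Because the raw D8 codes (1, 2, 4, …, 128) are categorical,
the regression covariate for "flow direction" is the quadrat mean of
`log10(1 + accumulation)` — a monotone proxy for water convergence and
hence soil moisture. Both the code layer and the accumulation layer are
available.

Quadrat covariates are means of the cell values whose centers fall in
the quadrat (DEM cell size defaults to 5 m, aligned with the census
grid) and are z-scored per grain; a zero-variance covariate is an error
rather than a silent NaN.

## Phylogenetic structure

Cophenetic distances are tip-to-tip path sums on the (pruned) phylogeny;
pruning to the census checklist preserves root-to-tip path lengths by
collapsing unifurcations with summed branch lengths. Faith's PD is
root-inclusive — the branch length of the minimal subtree spanning the
community *and* the root — so single-species quadrats have PD > 0 and
the full pool recovers the total tree length. MPD and MNTD are
presence-based (unweighted); abundance weighting is deliberately not
used, matching the common default.

NRI and NTI are negated standardized effect sizes of MPD and MNTD under
a taxa-label shuffle with 999 randomizations by default. The species
pool is the full column set of the community matrix at that grain and
stage, so saplings are judged against the sapling pool. Because a
taxa-label shuffle maps a k-species community to a uniformly random
k-subset of the pool, the null distribution depends only on k; the
implementation therefore draws one null sample per distinct richness
class (uniform k-subsets) and shares it across quadrats of equal
richness — distributionally identical to shuffling the distance-matrix
labels, and much cheaper. Per-quadrat two-sided p-values come from the
observed value's rank among the null draws, `2·min(lo, hi)` with the
+1 correction.

Quadrats with fewer than two species, or whose null SD is degenerate
(e.g. a community equal to the whole pool, where every shuffle returns
the same MPD up to floating-point noise — a relative 1e-9 floor guards
this), carry NaN effect sizes and a `valid = False` flag; they are
excluded from NRI/NTI models but retained for SR/PD models.

A caveat that matters for interpretation: quadrats within one plot share
the species-abundance realization, so their NRI values are correlated;
the per-quadrat test is exactly calibrated marginally (verified by
simulation: the 5% rejection rate over many independent neutral forests
falls in [0.03, 0.07]), but a single plot's *mean* NRI has a
between-realization spread of several tenths even under neutrality. The
stage summary (mean, SE, t, p per grain × stage) treats quadrats as
independent and should be read accordingly.

## Competition

The Hegyi index sums `(d_j/d_i)/dist_ij` over all stems j within a
circular radius of the focal stem i, taken equal to the analysis grain
(2.5/5/10 m). "Within the specified scale" is read as a radius because a
same-quadrat rule creates edge artifacts at quadrat borders; a
same-quadrat mode (`hegyi_ci_same_quadrat`) is provided for comparison.
Competitors include all species and stages; focal stems are
stage-filtered only when aggregating quadrat means. Neighbor search uses
a KD-tree (near-linear in stems). Coincident stems are a hard error —
clamping a zero distance would corrupt CI unboundedly. No edge
correction is applied at the plot boundary; stems near edges see
truncated neighborhoods, a small negative bias shared by all quadrats
touching the boundary.

## Mixed-effects models

Per response (SR, PD, NRI, NTI) × grain × stage group the package fits,
by REML via `statsmodels.MixedLM`,

    SR/PD  = β0 + β1·CI + β2·Elevation + β3·Aspect + β4·Slope
             + β5·TPI + β6·TRI + β7·Flowdir + (1|group) + ε
    NRI/NTI = the same + β8·SR

The default fixed-predictor set follows the seven-term SR/PD form above
(roughness is computed and carried in the metric table, and
`build_design(include_roughness=True)` adds it, but it is not in the
default set). All predictors — terrain, CI and SR alike — are z-scored
within each design so the β are comparable per-SD effect sizes.

The grouping factor deserves a note: the responses are quadrat-level,
so a per-species random effect cannot apply directly. The default
grouping is the quadrat's *dominant species* (largest summed DBH², i.e.
basal area), which carries species-level baseline differences to
quadrat granularity; grouping by the parent 20 m census block
(`grouping="block"`) is available as a spatial pseudo-replication
control. Random intercepts only: slopes for 8 predictors over ~100
groups are not identifiable at these sizes. Wald t-tests with
residual degrees of freedom give per-coefficient p-values; no multiple
testing correction is applied, and the coefficient grid reports tiers
a/b/c for p < 0.05/0.01/0.001. When the random-intercept variance
estimate hits the zero boundary (below 1e-4 of the residual variance)
or the mixed fit fails, the model falls back to OLS with a warning and
a `method="ols"` flag — at the boundary the two coincide, and
`MixedLM`'s reported fixed effects are unreliable there. Designs with
fewer than 10 rows per predictor refuse to fit.

## Synthetic forests

The generator emulates the study conditions of a censused subtropical
plot: a ~square plot (340 m default), 10⁴–10⁵ stems, ~100 species on a
time-calibrated tree, a right-skewed DBH distribution and a smooth DEM.

- **Phylogeny**: pure-birth (Yule, rate 1) with an explicit final
  waiting interval so all branch lengths are strictly positive, depth
  rescaled to 1.0 (ultrametric, matching a time-calibrated tree).
- **DEM**: planar trend plus Gaussian noise low-passed with a 4-cell
  Gaussian filter, scaled to a peak-to-trough relief amplitude (30 m
  default over 340 m — pronounced microtopography).
- **Abundance**: geometric ranks with ratio 0.93, permuted over species
  — the top four species hold roughly a quarter of stems, a realistic
  dominance structure, with commonness independent of phylogeny.
- **DBH**: 1 + LogNormal(1.4, 1.0) cm, giving ≈50/40/10% expected mass
  in the sapling/juvenile/adult bins (each stage ≥ 5% by construction).
- **Filtering**: a Brownian trait on the tree (the standard
  trait-conservatism model) gives each species an affinity; placement
  probability over DEM cells ∝ exp(intensity × affinity × env), with
  env the z-scored elevation, TPI or log-accumulation layer. Close
  relatives share affinities and therefore cells.
- **Repulsion**: stem locations are uniform; each stem's species is
  drawn sequentially from a softmax `abundance × exp(−intensity ×
  mean relatedness to neighbors within 10 m)`, with relatedness
  `1 − cophenetic/diameter ∈ [0, 1]`. Conditioning the species label
  keeps the penalty discriminative at any density. (An earlier
  location-rejection variant with a summed penalty was abandoned: at
  census densities its best-of-M fallback funneled successive
  same-clade stems into shared low-density basins and *inverted* the
  intended signal.)
- Intensity 0 dispatches every mode to the neutral sampler, so the
  collapse to neutrality is bit-exact. Everything is a pure function of
  its arguments including the seed.

What the generator does *not* emulate: demographic dynamics (growth,
mortality, dispersal limitation), spatial aggregation of recruits,
multi-stemmed trees, measurement error in coordinates or DBH, and
spatially autocorrelated regression residuals. Passing tests therefore
demonstrate correctness of the estimators and the direction of the
injected processes, not robustness to every property of real censuses.

The regression fixture draws the eight standardized predictors i.i.d.
N(0, 1), adds a per-group random intercept and Gaussian noise with
known coefficients; it is the ground truth for coefficient-recovery and
coverage checks.

## Problem sizes and determinism

The acceptance checks use replicate forests of ~100 species and
3000–8000 stems on 70–100 m plots: large enough that every quadrat
grain is populated, small enough that the whole battery runs in a
couple of minutes. Replication across forests matters scientifically,
not just computationally — single-forest mean NRI is dominated by the
shared species-pool draw (see the calibration caveat above), so
direction-of-effect checks average 30 forests and the null calibration
48. The full default pipeline (340 m plot, 20 000 stems, 104 species,
999 randomizations, three grains) runs end to end in well under 15
minutes on one CPU.

Every stochastic component takes an explicit integer seed, and the
pipeline manifest records the config hash and seed; identical
manifests reproduce byte-identical CSV artifacts.
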