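# Methods

This note records the models, parameter choices and numerical
conventions behind the package, and what the synthetic experiments can
and cannot say about real substrate mapping.

## The synthetic shelf

`synth.simulate_bathymetry` builds a depth grid (m, positive down;
land carries negative depth, never nodata, so shoreline derivatives
stay defined) as the sum of

* a planar shelf deepening seaward at `shelf_gradient` (default
  40 m/km — a steep, fjord-adjacent shelf so that a few-kilometre
  domain spans the intertidal through the 200 m+ zone),
* shore-parallel and oblique sinusoidal ridges (`ridge_amplitude`,
  default 8 m) with seeded random phases and wavelengths,
* a fine Gaussian-smoothed noise field whose standard deviation is
  `noise_amplitude` (default 2 m) at the shoreline and halves every
  `decay_scale` metres of depth (default 30 m). The decay encodes the
  field observation that seafloor texture and substrate patchiness
  are greatest nearshore and smooth out under sediment infill at
  depth. The shoreline row is fixed from `land_fraction` (default
  0.15), and the top half of the landmass is clamped above datum so
  the coast is always one connected component.

All outputs are pure functions of their parameter sets including the
seed.

### Substrate truth

`simulate_truth` thresholds a latent seabed-energy index computed from
the true seafloor's predictor stack:

    E = w_f·ẑ(fetch) + w_t·ẑ(tide) + w_s·ẑ(slope) − w_d·ẑ(depth) + ε

where ẑ is the layer rank-normalized over marine cells and centred at
0.5, the weights default to (0.9, 0.5, 0.9, 1.6), and
ε ~ N(0, σ(depth)²) with σ = `noise_sd`·2^(−depth/`decay_scale`)
(`noise_sd` 0.12). Cells become Mud / Sand / Mixed / Rock by the
strictly increasing thresholds (−0.15, 0.10, 0.35): high energy scours
to Rock, low energy deposits Mud. Label noise then flips each marine
cell to a uniformly random other class with probability `label_noise`
(default 0.05). The weights and thresholds were chosen once so that
every class holds 5–60% of marine cells across seeds, the map
imbalance sits near the ~0.17 reported for real coastwide compilations,
and depth dominates the deep zones while slope/fetch structure
dominates nearshore. Because the rule thresholding the noise-free E is
the Bayes-optimal classifier under this model, every experiment has a
computable skill ceiling (`bayes_rule`).

### Measured bathymetry

Real gridded bathymetries carry track-line and interpolation artefacts
that do not decay offshore, and substrate responds to the true terrain
while classifiers only ever see the measured one. `measure_bathymetry`
therefore adds a smoothed artefact field (sd `artefact_amplitude`,
default 1 m, constant with depth) to marine cells after truth
generation; the experiment pipeline derives all model predictors from
this measured grid. This single mechanism produces the
resolution-by-depth interaction: nearshore, real fine-scale structure
dominates the artefacts and the fine model wins; offshore, the truth
is smooth, the fine predictors are artefact-dominated, and the
block-averaged coarse predictors are effectively denoised. Setting
`artefact_amplitude = 0` models a perfect survey and is used where the
question is purely statistical (how close a forest gets to the Bayes
ceiling), since the ceiling is only attainable when the model sees the
same inputs the generative rule thresholds.

### Observation samplers

`sample_observations` draws cells with replacement from the marine
cells inside a depth window, with inclusion probability proportional
to the per-class bias multiplier of the cell's true class; recorded
class and depth are the drawn cell's (so observations inherit only the
truth grid's label noise), and positional jitter is kept only when it
stays within the drawn cell. The default build suite mimics
hydrographic-survey bias — a grab campaign (60% of points, 0–50 m,
Rock bias 3×), a dive campaign (15%, 0–20 m, same bias) and an
unbiased ROV campaign (25%, 20–700 m) — and the independent suite uses
dive (0–20 m), camera (16–60 m) and ROV (> 20 m) windows with unbiased
class inclusion, mirroring the depth envelopes of real campaigns of
those types. With bias multiplier b for one class of map prevalence p,
the expected sample share is bp/(1 − p + bp); the tests recover
configured multipliers from samples to within 10% at n = 50,000.

## Predictor derivation

* Slope: Horn 3×3 finite differences, degrees; edges use
  replicate-padded partial windows (nearshore cells are the point of
  the analysis, so they are kept, at reduced accuracy).
* Curvature: Zevenbergen–Thorne general curvature of the elevation
  surface, in 1/100 m, positive convex.
* Slope std-dev: focal standard deviation of slope, 3×3.
* Rugosity: sec(slope), the surface/planar area ratio of the locally
  fitted plane (≥ 1, 1 when flat).
* BPI: annulus-mean depth minus cell depth (positive = crest), at
  three nested scales; library defaults are radii 0–5, 0–25 and 0–125
  cells, and the experiment config uses 0–5/0–12/0–30 so the broad
  annulus fits comfortably in the simulated domains. Partial annuli at
  edges use the available cells.
* Fetch: sum over 32 equally spaced bearings of the cell-stepped ray
  distance to the first land cell (depth ≤ 0), each ray capped (50 km
  library default; 6 km in the simulated domains, matching their few-
  kilometre extent). Rays that leave the grid count as open ocean.
* Energy grids (tide, circulation): smooth lognormal random fields
  generated at 15× coarser cells and bilinearly resampled onto each
  analysis grid, standing in for averaged circulation-model output.
* Stacks: the fine ("regional") stack carries 11 layers including
  fetch; the coarse ("coastwide") stack 10, without fetch. All layers
  are masked to the marine footprint, and the coarse bathymetry is the
  block mean of the measured fine grid (factor 5, the 20 m vs 100 m
  analogue).

## Observation preparation

Build observations are never aggregated: multiple points in one cell
each keep their row with duplicated predictor values, preserving
sample size. Independent sets are collapsed to one record per occupied
cell (modal class, ties broken Rock > Mixed > Sand > Mud — a fixed
priority toward the rarer, harder classes — mean depth, cell-centre
position) and screened by |recorded − gridded depth| ≤ 50 m. The
67/33 build split is simple random, unstratified, seeded. Depth zones
are Intertidal (≤ 0) then half-open intervals with inclusive upper
bounds at 5, 10, 20, 50, 100 and 200 m.

## Classification

The ensemble is a random forest (scikit-learn) with 1000 trees by
default (200 in the multi-seed experiments, where the weighting and
resolution contrasts are already stable), each grown on a
with-replacement sample of 60% of the training rows, Gini impurity,
and out-of-bag error recorded. The "0.6" sampling fraction is the
per-tree bootstrap fraction, distinct from the 67/33 build split.
Prevalence weighting enters as per-class weights `1 − N_c/N_total` on
the impurity and leaf votes, so errors on rare classes cost more;
`weighting="none"` is the unweighted arm. Labels are encoded
1=Rock … 4=Mud before fitting so prediction ties resolve toward the
lowest code. Predictors are used untransformed and unscreened for
collinearity. Variable importance is reported relative to the top
predictor (p/p_max), with predictors absent from a configuration
(fetch, coastwide) reported as NA.

## Metrics

Confusion matrices are oriented rows = predicted, columns = observed.
With proportions p_ij, predicted margins f and observed margins o:

* OA = Σ p_ii; multi-category TSS = (Σ p_ii − Σ f_i o_i)/(1 − Σ o_i²),
  the Peirce / Hanssen–Kuipers skill score, exactly 0 under
  independence of prediction and observation and equal to
  sensitivity + specificity − 1 for K = 2;
* Quantity = ½ Σ |f_j − o_j|; Exchange = Σ_{i<j} 2·min(p_ij, p_ji);
  Shift = (1 − OA) − Quantity − Exchange. The three components sum to
  total disagreement by construction (verified to 1e−12 on random
  matrices);
* user_i = p_ii/f_i, producer_j = p_jj/o_j, one-vs-rest
  TNR_i = (n − row_i − col_i + c_ii)/(n − col_i); empty-margin ratios
  are reported as 0 with an explicit flag, never dropped silently;
* Imbalance = ½ Σ |p_j − 1/K| / (1 − 1/K), the normalized
  total-variation distance of the prevalence vector from uniform. This
  is this package's interpretation of an "integrated prevalence"
  score; it is not validated against any externally printed imbalance
  values;
* baselines for a uniformly random predictor: TSS₀ = 0, TPR₀ = 1/K,
  TNR₀ = 1 − 1/K. Independent-data evaluations also report
  baseline-adjusted aggregates (TSS − 0, OA − 1/K,
  TNR_macro − (1 − 1/K)).

## Experiment design and problem sizes

`evalx.run_seed` runs one seed end to end: simulate, measure, derive
both stacks, sample build and independent campaigns, split 67/33
before the predictor join (so fine and coarse models share one test
partition of the same observations), fit both weighting arms at both
resolutions, and evaluate overall, per depth zone, and per region
(west/center/east tiles by default). Strata with fewer than 30
evaluable points are flagged `insufficient` rather than scored. A
row-id audit guards the train/test separation, and
Quantity + Exchange + Shift + OA = 1 is asserted for every emitted
stratum.

Problem sizes: the default config uses a 200×200 shelf at 25 m cells
with 4,000 build and 1,200 independent points; the 20-seed paired
experiment behind the weighting and resolution contrasts uses a
300×300 shelf, 6,000 build points and 200 trees; the Bayes-ceiling
check uses 10,000 build points, 400 trees and a clean survey. These
sizes were chosen so each contrast is decided by the mechanism, not by
Monte Carlo luck, while a full run stays in the minutes range on one
core.

## Known limitations

The generator is a statistical stand-in, not a physical model: no
hydrodynamics, no sediment transport, a quasi-straight synthetic
coastline, iid (not spatially correlated) substrate noise, symmetric
label noise, and energy fields that are smooth random surfaces rather
than circulation-model output. Passing tests therefore demonstrate
that the estimation and evaluation machinery behaves correctly under a
known generative process with realistic sampling biases — not that any
particular real shelf satisfies that process. Printed skill values
from real coastal compilations depend on restricted observation
holdings and are deliberately not reproduction targets; the
experiments reproduce directions and structure (weighting effects,
resolution-depth interaction, fit-vs-forecast gaps), not magnitudes.
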