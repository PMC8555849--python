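# benthoscape

Prevalence-weighted multi-class seafloor substrate classification, and a
comprehensive accuracy/error assessment framework, exercised end-to-end
on synthetic shelves with known ground truth.

## The problem

Maps of bottom type (Rock, Mixed, Sand, Mud) underpin benthic habitat
models and marine spatial planning, but substrate observations are
patchy, biased shallow and rocky by the surveys that collect them, and
far too sparse to map directly. The standard remedy is a tree-ensemble
classifier that correlates point observations with bathymetry-derived
terrain predictors (slope, curvature, rugosity, bathymetric position
indices) and seabed-energy proxies (wave fetch, tidal and circulation
speed), then predicts over the full grid. That workflow raises
questions that are hard to answer with real data because the truth is
unknown:

* does weighting classes by prevalence, `w_c = 1 − N_c / N_total`,
  actually fix the over-prediction of the dominant class?
* how does model resolution interact with depth, given that substrate
  heterogeneity decays seaward while survey artefacts in gridded
  bathymetry do not?
* how much lower is predictive power on independent data than fit
  statistics suggest?

`benthoscape` re-creates the whole study design on seeded synthetic
seafloors where the generative process — a latent energy index

```
E = w_f·ẑ(fetch) + w_t·ẑ(tide) + w_s·ẑ(slope) − w_d·ẑ(depth) + ε(depth)
```

thresholded into the four ordered classes, with noise sd halving every
`decay_scale` metres of depth — is known exactly, so every classifier
has a computable Bayes ceiling.

Model performance is scored with a deliberately comprehensive metric
suite on K×K confusion matrices (rows = predicted):

* overall accuracy `OA = Σ p_ii` and the multi-category true skill
  statistic `TSS = (Σ p_ii − Σ f_i o_i) / (1 − Σ o_i²)` (0 for an
  uninformative predictor, 1 for a perfect one; equals
  sensitivity + specificity − 1 for two classes),
* per-class user/producer accuracy and one-vs-rest true negative rate,
* the disagreement decomposition `1 − OA = Quantity + Exchange +
  Shift` (margin mismatch, two-way swaps, residual reallocation),
* a prevalence `Imbalance` score and the no-information baselines
  (TSS₀ = 0, TPR₀ = 1/K, TNR₀ = 1 − 1/K).

## Worked example

The numbered drivers under `analysis/` run the study front to back and
write tidy CSVs under `results/`. The multi-seed weighting experiment:

```
$ python analysis/03_weighting_experiment.py
mean fit metrics over 5 seeds (shared test partition):

metric                   tss     oa  tnr_macro  quantity  exchange  shift  prevalence_l1
resolution weighting
coarse     none        0.447  0.690      0.871     0.085     0.207  0.019          0.168
           prevalence  0.452  0.663      0.872     0.037     0.293  0.007          0.074
fine       none        0.476  0.724      0.880     0.131     0.121  0.024          0.262
           prevalence  0.484  0.706      0.884     0.083     0.197  0.015          0.166

weighted arm has lower Quantity error in 100% of seed x resolution cells
weighted predictions closer to observed prevalence in 100% of cells
```

Reading: prevalence weighting roughly halves Quantity error (the
systematic over-prediction of the over-sampled Rock class) and pulls
predicted class prevalence toward the observed prevalence, while TSS
and overall accuracy barely move — the Quantity reduction is traded
against Exchange. `analysis/04_resolution_by_depth.py` then shows the
fine-resolution model winning in every zone shallower than 50 m and
the coarse model winning below 50 m, and
`analysis/05_independent_evaluation.py` shows forecast skill on
independent dive/camera/ROV-style campaigns falling 0.08–0.25 TSS
below fit.

The same machinery is available as a library
(`benthoscape.synth`, `.terrain`, `.obsprep`, `.classify`, `.metrics`,
`.evalx`) and as a small CLI (`benthoscape simulate | derive | run`).

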