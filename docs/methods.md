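# Methods

## Problem setting and model

`wsisurv` estimates patient-level hazard from histology tiles under weak
supervision: no region annotations exist, only a right-censored follow-up
time `t_m` (months) and event indicator `δ_m` per patient. Tiles inherit
their patient's label. The tile-to-risk map is a small CNN `r = f(i)`
embedded in a proportional-hazards model `h(t|i) = h0(t) exp(f(i))`; the
baseline hazard cancels from Cox's partial likelihood, so training needs
no parametric time model. The loss over a mini-batch is the negative log
partial likelihood with the risk set `R(t_m) = {j : t_j ≥ t_m}` taken
within the batch; because each batch holds at most one tile per patient,
the batch risk sets are meaningful draws of the cohort-level ones. Tied
event times use the Breslow approximation (one shared risk set per tied
group); Efron's correction is available (`ties="efron"`) and matters only
when ties are common, which month-resolution data can produce.

Log-sum-exp terms subtract the running maximum, which also makes the loss
exactly invariant to adding a constant to all risks — the partial
likelihood only identifies risk differences, so predicted risks are
interpreted relatively (per-slide min-max scaling in the heatmaps, median
threshold for stratification).

## Attention

From the last convolutional feature map `F ∈ R^{H×W×D}` the model computes
channel gates `C_att(F) = σ(mean_{H,W} F) ∈ (0,1)^D` and spatial gates
`S_att(F) = σ(mean_D F) ∈ (0,1)^{H×W}`, and fuses by element-wise
summation of the two gated maps, `C_att(F)⊗F + S_att(F)⊗F`. Both gates are
deterministic functions of F with **no learnable parameters**, so the
attention ablation switch changes no parameter count; gradients flow both
through the direct product terms and through the gates. A learnable
variant (`attention_learnable=True`) inserts a 1×1 channel projection
before each pooling for experimentation; it is off by default because the
parameter-free reading keeps model complexity identical with and without
attention. The insertion point is after the final conv block, before
global average pooling.

## Architecture and optimization

The built-in `tiny` backbone is three `3×3 conv → ReLU → 2×2 max-pool`
blocks with 16/32/64 channels, attention fusion, global average pooling,
a 64-unit fully connected ReLU layer and a linear risk output (~29k
parameters, 64×64×3 input). Everything — im2col convolutions, pooling,
attention, backward passes — is implemented on numpy; default compute
precision is float32 (float64 available via `dtype=`, used by the
gradient-verification tests). Named large backbones (resnet18, vgg11bn,
densenet121, alexnet) are recognized configuration values that require a
deep-learning runtime with pretrained architectures and raise a clear
error in this build.

Weights are initialized i.i.d. N(0, 1e-2²), biases 0. The optimizer is an
adaptive-gradient accumulator combined with heavy-ball momentum 0.95
(plain AdaGrad and SGD-momentum are config options): `G += g²;
v ← 0.95·v + lr·g/√G; w ← w − v`, with `lr = 1e-4 · 0.97^epoch`.
Augmentation (each with probability 1/2: flips, right-angle rotations,
hue shift within ±0.05, ≥80%-area crop-and-resize, 2–20%-area random
erasing with uniform noise) is applied on the fly each epoch; magnitudes
were chosen to be label-preserving since tile class is a global texture
property. Every stochastic component is driven by a seed tree, so runs
are bit-reproducible at a fixed thread count. Non-finite losses abort
with a diagnostic rather than training through.

The per-epoch logged loss is the summed batch NLL divided by the number
of events seen that epoch; the unnormalized sum varies with batch
composition and obscures trends.

## Tiling conventions

Coordinates are 0-based, half-open, x rightward, y downward, at the
working magnification; `TissueMask.downsample` maps mask pixels back.
Otsu's threshold maximizes between-class variance over a 256-bin
histogram (computed on the native integer scale for 8-bit input, where
the split is exact); tissue is the dark class including the threshold
level. Tiles default to 50% stride overlap; boxes with tissue fraction
below `min_tissue = 0.5` are dropped (the threshold is exposed because
real cohorts differ in pen marks, folds and sparse biopsies). Per-slide
sampling draws without replacement, topping up with replacement only when
fewer candidates than requested tiles exist. Plain PNG/TIFF rasters are
read directly; pyramidal formats plug in through the reader contract
(`dims`, `read_region`), with average-pooling downsampling when no
pyramid level matches the working magnification.

## Synthetic data: what it does and does not emulate

`generate_slide` paints a pink stroma blob with a wobbled boundary on a
white glass margin and places dark-purple elliptical nuclei by an
inhomogeneous Poisson process whose intensity varies smoothly around the
patient's density `d_i ~ Uniform(5e-4, 3e-3)` nuclei/px². The ground-truth
informativeness map is the Gaussian-smoothed nuclear coverage divided by a
fixed reference (0.25) and clipped to [0,1] — a fixed absolute scale, so
mean informativeness is ordered by density across slides and
`patient_feature` (its mean over tissue) is a monotone image feature.
Event times are `T ~ Exponential(h0 · exp(beta_true · z))` with `z` the
cohort-standardized feature (a Weibull shape parameter generalizes this);
censoring is `C ~ Uniform(0, q)` with `q` solved by bisection so the
expected censored fraction hits `censor_rate` — the generator reproduces
both ~30% and ~59% censoring regimes. Defaults (40 patients, 256-px
slides, h0 = 0.02/month, beta_true = 1.5, 30% censoring) are the study
conditions of the end-to-end tests.

What passing tests therefore show: the pipeline can learn a
density-driven hazard from weak labels, at realistic censoring, and its
risk maps recover the planted spatial signal. What they do not show:
robustness to stain variation, scanner shifts, artifacts, multi-class
tissue morphology, or gigapixel-scale slide handling — real H&E texture
is far richer than this generator.

## Evaluation choices

- **c-index**: a pair is comparable iff the earlier time is an observed
  event and times are untied; tied risks score 1/2. This is the standard
  Harrell rule; it reproduces the 1 / 0 / 0.5 boundary conventions.
- **Median stratification**: risks strictly above the cohort median are
  "high"; values at the median go to "low" for determinism. All-equal
  risks warn and give an all-low cohort.
- **KM / log-rank** are computed through lifelines behind the module
  surface; tests verify them against 1−ECDF and a permutation-null oracle.
- **Cox regression** is Newton–Raphson on the Breslow partial likelihood
  with step-halving; Wald 95% CIs `exp(β ± 1.96·se)`; two-sided normal
  p-values, uncorrected. Monotone likelihood (perfect separation) is
  flagged as non-convergence — detected by coefficient magnitude > 15,
  since the score itself vanishes as β runs away — and returns NaN
  estimates. Univariable mode fits each covariate alone; the per-variable
  c-index uses the fitted linear predictor, which for a single covariate
  equals the c-index of the covariate itself up to orientation.
- The Mantel-Haenszel-style O/E hazard ratio (`logrank_hazard_ratio`)
  annotates two-group KM comparisons and is distinct from regression HRs.

## Problem sizes in the test suite

The end-to-end check trains the `tiny` backbone over a 5-fold
patient-level cross-validation of 40 synthetic patients (30 tiles of
64×64 each, 10 epochs, batch 16), pooling each fold's test-patient median
risks so every patient is scored exactly once; pooling over all 40
patients makes both the prognostic bound (c ≥ 0.65) and the no-signal
control band (0.5 ± 0.1) statistically meaningful, which an 8-patient
single fold would not. Statistical oracles run at n ≤ 2000. Parameter
recovery uses 400-patient cohorts with 64-px slides (the survival process
depends on slide content only through the mean-density feature, which
small slides estimate fine).

## Known limitations

- Only the `tiny` backbone ships; no pretrained weights, so the model
  must learn morphology from the cohort at hand.
- Single-threaded CPU training limits practical cohort sizes to the
  thousands-of-tiles regime.
- No stain normalization or artifact screening; inputs are assumed
  reasonably uniform in appearance.
- Proportionality of hazards is assumed, not diagnosed.
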