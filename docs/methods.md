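# Methods

somaquant quantifies fluorescence and brightfield microscopy of brain
sections at the level of individual cells.  This note documents the models
and procedures implemented, the parameters that matter, what the synthetic
generators emulate, and the numerical choices made where the design was
genuinely open.

## Semantic segmentation network

Cell compartments and RNAscope dots are segmented by a small fully
convolutional network (FCN): five convolutional layers joined by ReLU
activations with a per-pixel softmax output, and a 1x1 convolution between
feature maps 2 and 3 that reduces the kernel count by `reduction_factor`
(default 4), cutting the parameter count of the following layer by a factor
of 16.  There is no striding, pooling or dropout-based downsampling, so the
output class map has exactly the input's resolution and sub-micron dots are
not smoothed away.  Mirror (reflection, no edge duplication) padding
preserves the spatial size at every layer.  The stacked receptive field
`sum(k_i - 1) + 1` must equal `patch_size`, so each pixel's class depends
only on the surrounding `patch_size x patch_size` patch; the default
kernel stack (13, 13, 1x1, 13, 13, 15) gives the default 63-px field.
Per-layer kernel sizes and widths are configuration, not architecture
constants: the dot task ships with a compact preset
(`dot_task_config`: 15-px receptive field, widths 8-16-4-16-16), because a
2-px dot needs little context and the narrow stack trains on one CPU core in
about two minutes.

Training minimises pixel-wise cross-entropy on randomly cropped
`patch_size**2` patches (64 crops per training image per epoch, a choice
that bounds epoch cost deterministically) with Adam at its default settings
(alpha = 0.001, beta1 = 0.9, beta2 = 0.999, eps = 1e-8).  Optional
inverse-frequency class weighting (off by default) counteracts extreme class
imbalance; it is enabled in the dot preset, where the dot class covers
roughly 1% of pixels.  The train/test split operates on whole images, never
patches, to prevent near-duplicate pixels from leaking into the held-out
set.  After every epoch the held-out pixel error is measured on full test
images; training stops once it has not improved for `patience` epochs
(default 10) and the weights of the best epoch are restored, so the reported
stop epoch attains the minimum of the logged test error.  All randomness
(initialisation, crops, splits) derives from one explicit seed.  The whole
network runs in NumPy (im2col + tensordot with row chunking to bound the
buffer at ~32M elements), which is entirely adequate at these network sizes.

Quality is summarised per class as TP/TN/FP/FN in percent of all pixels,
specificity TN/(TN+FP), sensitivity TP/(TP+FN), and the global pixel error.
Metrics with empty denominators are reported as NaN, never as 0.

## Classical post-processing

Five deterministic operators refine the network output:

* **Watershed splitting** — markers are local maxima of the Euclidean
  distance transform, separated by at least `min_peak_distance`
  (default: the expected object radius — ~2-3 px for dots, ~12-15 px for
  somata).  The distance map is smoothed with a 1-px Gaussian before peak
  picking to suppress plateau duplicates; ties break toward the lowest
  (row, col); any connected component left without a peak by the suppression
  gets a marker at its distance-transform argmax, so the flooded regions
  always partition the foreground exactly.
* **Morphological refinement** — dilation/erosion sequences with a disc
  structuring element, used to separate touching somata and smooth ragged
  boundaries.
* **Hole filling** — background components not connected to the image
  border are filled per instance (4-connectivity), since holes inside a
  compartment carry no biological meaning.
* **Target-channel zeroing** — before segmentation the quantified channel
  is set to zero so that cell detection cannot depend on the signal being
  measured; the original image is used for quantification.  Classes that are
  rendered inside the cytoplasm (dots) are folded back into the body support
  before instance separation, since they would otherwise punch holes in it.
* **Background estimation** — mean and SD over pixels below a per-channel
  intensity threshold in every channel (allowed range 10-40 on the 8-bit
  scale; default the midpoint, 25/255) and outside detected target areas.
  Zero qualifying pixels is an error that asks for a higher threshold rather
  than silently returning nonsense.

## Per-cell quantification

Dots intersecting a cell body (nucleus included) are watershed-split,
filtered by a minimum area (default 2 px), and counted per cell; dots outside
every cell are ignored.  Per-cell brightfield transmission is
T = mean(I_t over the body) / I_i with the incident intensity I_i estimated
as the median brightfield value outside all cells; the attenuation 1 - T is
zero over blank background and serves as the neuromelanin proxy.

Relative fluorescence (RF) is the compartment mean intensity divided by the
section background mean, so RF = 1 is background level and the ratio is
invariant under global gain changes.  A fragmented membrane's area-weighted
mean RF equals the plain mean over the union of its fragments, which is what
is computed.  Compartments with more than 1% saturated pixels are flagged
unreliable.  Marker calls threshold the body RF at
`bg_mean + k * bg_sd` on the RF scale; per-animal thresholds normalise
section background means to the animal mean and drop outlier sections by
Tukey fences (1.5 x IQR) — a documented replacement for the ROUT outlier
test available only in commercial software.  Default SD multipliers: DAT 2.0
(midpoint of a cohort-dependent 1.5-2.5 range), D2 1, calbindin 4,
Aldh1A1 5; all per-cohort configuration.

Quality control automates a manual inclusion check through proxies: border
contact, body area bounds, presence of a nucleus with sufficient overlap,
and solidity (fragmentation).  Records are flagged with reasons, never
deleted.

## Anatomical mapping

Coordinates are z-scored (sample SD, ddof = 1) per animal and hemisphere;
the hemisphere-cloud centre becomes (0, 0) and the x sign is flipped on the
left hemisphere so +x points laterally everywhere.  The lateral region is
scaled x strictly greater than 1.5 units; the physical equivalent in um is
cohort-dependent and is reported per group (`um_per_scaled_x`), never
thresholded on.  Sections are binned along bregma as rostral (-3.1, -2.7],
medial (-3.5, -3.1], caudal [-3.9, -3.5] (half-open on the rostral side —
the boundary assignment at -3.1/-3.5 was an open choice).  Co-expression
rates among marker-positive, QC-included cells come with Clopper-Pearson
95% intervals (exact at rates of 0 or 100%); empty strata are flagged
undefined.  Gradient maps z-score RF per animal and exclude the top
`ceil(fraction * n)` values (defaults 0.3% for DAT, 0.005% for TH style
displays) from the display scaling only.

## Stereology

The optical fractionator estimates `N = sum(Q-) * t / (h * asf * ssf)`; its
precision is the Gundersen CE (m = 1) with
`VAR_SRS = (3 (A - s^2) - 4 B + C) / 240` over the ordered section series
and `CE = sqrt(s^2 + VAR_SRS) / s^2`.  The noise variance defaults to the
Poisson nugget `s^2 = sum(Q-)`; under that default the denominator equals
the classical `sum(Q-)`, and the formula is implemented with `s^2` in the
denominator as written, with this coincidence documented rather than
resolved by guessing intent.  Negative `VAR_SRS` (possible in short or
strongly alternating series) is clamped to zero.  Flawed sections are
repaired by averaging their two neighbours; a flawed end section copies its
single neighbour with a warning, and adjacent flawed sections are an error.

## Neuromelanin adjustment model

Detected dot counts follow `Y ~ Binomial(s, p)` with
`p = p_max * logit^-1(g(x))`, `x = -log10 T` (Lambert-Beer: absorber
concentration is proportional to -log10 of transmission), and `g` linear in
x with intercept, age offset and slope indexed by a two-component
(low/high expressing) mixture.  Transmission is
`T ~ Beta(mu_T, kappa)` (mean/precision parameterisation) with
`mu_T = logit^-1(h)`, where h carries component and age effects plus a
per-brain random intercept; the mixture weight is
`theta = logit^-1(theta0 + Delta_age + (1|brain))`.  The trial size is the
number of dot-sized sites fitting the cell area (site area = a 2-px-radius
disc); `p_max` is fixed at 1 by default and estimable via configuration.
The Lambert-Beer factors (path length, extinction coefficient,
concentration) enter only through their product and are not individually
identifiable, so they are not represented separately.

Priors are Normal(0, 5) on all logit-scale coefficients, half-Normal(0, 2)
on the random-effect SDs and Gamma(2, 0.1) on kappa.  The mixture is
identified by ordering the g intercepts (low < high).  Fitting is full MCMC
with the emcee affine-invariant ensemble sampler using
differential-evolution moves (the default stretch move mixes poorly on this
correlated ~30-dimensional posterior), 64 walkers, and 1000 + 1000
burn-in/draw steps by default, initialised in a small ball around an L-BFGS
MAP estimate whose gradient is computed by vectorised central differences.
Convergence is summarised by split-R-hat over four walker groups
(threshold 1.05) and bulk effective sample size; a non-converged fit is
flagged, and the adjustment step refuses flagged fits unless overridden.
Tail quantiles (the 95% credible bounds) converge more slowly than means;
the default chain length was chosen so that interval estimates, not just
point estimates, are stable.

**Constant-T adjustment.**  To remove the NM effect, every cell's
transmission is set to the constant T\* = mean over brains of the fitted
mixture-averaged mu_T, and the observed count is rescaled by the model's
detection-probability ratio p(T\*) / p(T), averaged over the cell's
posterior component membership.  This multiplicative reading keeps data
with a zero fitted slope (or cells already at T\*) exactly unchanged and
corrects darker cells upward when the slope is negative; reproducing
model-expected counts instead would replace observed counts with their
conditional means and change even unaffected data.

## Synthetic data

Generators are pure functions of spec + seed (bit-identical reruns):

* **Cell fields** — disc somata with concentric (slightly offset) nuclei,
  optional membrane rings, Gaussian dot spots (2-px radius, emulating
  sub-resolution RNAscope dots) with a minimum-separation control that can
  also create deliberately fused dots, multiplicative brightfield
  attenuation `I_i * T` per cell, and additive Gaussian noise.  Overlapping
  cell pairs are planted by a configurable touching fraction.
* **IF cohorts** — per-cell tables across animals, hemispheres and
  8 sections spanning bregma -3.9 to -2.7 mm, with a planted marker-negative
  subpopulation (default 5% overall, 7-fold enriched in the planted lateral
  tail), negative somata scaled by an area ratio (default 0.6, i.e. ~40%
  smaller), and a medio-lateral linear RF gradient on the positive cells.
  `render_if_section` rasterises one section so the full imaging pipeline
  (segment, QC, RF, classify, map) can be validated end to end; body
  intensity is background x RF exactly, so the planted RF is recoverable.
* **Section series** — a known true total distributed over sections
  (uniform or skewed caudo-rostral profile) and thinned binomially by
  `asf * ssf * h / t`, supporting fractionator unbiasedness and CE
  behaviour checks.

What the generators do **not** emulate: point-spread functions and chromatic
aberration, autofluorescence, non-disc cell shapes, anisotropic pixels,
tile-scan stitching seams, and staining batch effects.  Passing tests
therefore demonstrate correctness of the algorithms under controlled
conditions, not segmentation performance on real tissue.

## Problem sizes and numerical choices

Validation uses desk-scale sizes: 20 images of 256 x 256 px for the dot
task, ~1000-cell rendered cohorts over 3 animals, 6 brains x 300 cells for
the NM model (20 replicate fits for interval calibration), 500 resamples for
fractionator unbiasedness.  Images are float in [0, 1] after load with the
original bit depth kept for exact round trips; coordinates are 0-based with
x = column, y = row; 4-connectivity is used for components and hole filling;
polygons treat boundary points as inside.  Checkpoints are a single .npz
with a JSON header plus weight arrays.

## Known limitations

* The FCN is CPU-oriented; training at full microscopy scale (hundreds of
  large images) would need an accelerated backend even though the
  architecture is unchanged.
* Membrane attachment assigns fragments to the nearest enclosing body by
  dilation overlap; interdigitated membranes of touching cells can be
  mis-assigned.
* The marker threshold assumes background statistics transfer to the cell
  interior; real tissue autofluorescence violates this more than the
  synthetic fields do.
* With a single age group the age-difference terms are dropped rather than
  regularised away.
* Frequentist coverage of Bayesian credible intervals at a fixed truth is
  only asymptotically nominal; at 6 brains x 300 cells, slope intervals show
  mild one-sided under-coverage consistent with the well-known
  away-from-zero finite-sample bias of logistic slope estimates.
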