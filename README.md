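# somaquant

Per-cell quantification of fluorescence and brightfield microscopy for
dopaminergic-neuron studies: a trainable fully convolutional network (FCN)
for semantic segmentation, classical post-processing, RNAscope dot counting,
compartment-resolved immunofluorescence quantification with
marker-negative classification, anatomical mapping, optical-fractionator
stereology, and a Bayesian model that corrects dot counts for neuromelanin
brightfield attenuation.  Synthetic-data generators with exact ground truth
make the whole pipeline testable without microscope data.

## Who it is for

Labs quantifying labelled neurons in brain sections: how many TH-positive
cells are in a region, how many mRNA molecules (RNAscope dots) each cell
carries, how strongly each compartment expresses a protein relative to
background, where marker-negative subpopulations sit anatomically, and
whether pigment (neuromelanin) is biasing the counts.

## The models at the core

**Segmentation.**  A compact FCN assigns a class to every pixel: five
convolutional layers with ReLU activations and a per-pixel softmax, a 1x1
convolution between feature maps 2 and 3 reducing the kernel count 4-fold,
mirror padding and no downsampling, so output resolution equals input
resolution and the receptive field equals the training patch size (default
63 x 63).  Training: Adam (alpha 0.001, beta1 0.9, beta2 0.999, eps 1e-8) on
random patches, image-level 80/20 train/test split, early stopping on the
held-out pixel error.  Quality: per-class TP/TN/FP/FN (% of pixels),
specificity TN/(TN+FP), sensitivity TP/(TP+FN), global pixel error.

**Stereology.**  Optical fractionator `N = sum(Q-) * t / (h * asf * ssf)`
with the Gundersen coefficient of error (m = 1),
`CE = sqrt(s^2 + VAR_SRS) / s^2`, `VAR_SRS = (3(A - s^2) - 4B + C) / 240`,
where A, B, C are the lag-0/1/2 products of the ordered section counts and
`s^2 = sum(Q-)` by default.

**Neuromelanin adjustment.**  Per cell, dots `Y ~ Binomial(s, p)` with
`p = p_max * logit^-1(g(x))`, `x = -log10 T` (Lambert-Beer), `g` linear in x
per mixture component (low/high expressing) and binarised age; transmission
`T ~ Beta(mu_T, kappa)` with `mu_T = logit^-1(h)` carrying a per-brain
random intercept; mixture weight `logit^-1(theta0 + Delta_age + (1|brain))`.
Fitted by ensemble MCMC (emcee) with Normal(0,5) / half-Normal(0,2) /
Gamma(2, 0.1) priors; counts are adjusted by rescaling to a constant
transmission equal to the mean fitted mu_T over brains.

See `docs/methods.md` for assumptions, defaults and limitations.

## Worked example

Count mRNA dots in synthetic cells and estimate a neuron total
stereologically:

```python
from somaquant.synth import ImageSpec, generate_cell_image
from somaquant.quantify import CellRecord, count_dots
from somaquant.stereology import (SectionCounts, StereologyParams,
                                  optical_fractionator, gundersen_ce)

spec = ImageSpec(shape=(256, 256), n_cells=6, dots_per_cell=25,
                 cell_radius=(16, 20), dot_min_separation=9.0, seed=4)
img, truth = generate_cell_image(spec)
records = [CellRecord(cell_id=c["id"],
                      body_mask=truth.body_labels.labels == c["id"],
                      centroid=c["center"]) for c in truth.cells]
count_dots(img, records, truth.dot_mask, min_dot_area=2, min_peak_distance=3)
for rec in records[:3]:
    print(f"cell {rec.cell_id}: counted {rec.dot_count}, "
          f"planted {truth.dot_count(rec.cell_id)}")

counts = SectionCounts(Q=[118, 205, 260, 240, 177])
params = StereologyParams(t=11.0, h=9.0, asf=0.44, ssf=1.0)
print(f"N  = {optical_fractionator(counts, params):.1f}")
print(f"CE = {gundersen_ce(counts):.4f}")
```

Output:

```
cell 1: counted 12, planted 12
cell 2: counted 8, planted 8
cell 3: counted 10, planted 10
N  = 2777.8
CE = 0.0336
```

The per-cell counts equal the planted truth exactly (dots are well
separated here; fused dots are split by the watershed stage).  The
fractionator extrapolates the 1000 counted cells through the sampling
fractions (t/h = 11/9, asf = 0.44) to ~2778 in the full region, with a 3.4%
coefficient of error — comfortably below the 0.05 commonly required.

A command-line interface mirrors the library (`somaquant train`, `predict`,
`count-dots`, `quantify-if`, `map`, `stereology`, `nm-fit`, `nm-adjust`,
`synth`); run `somaquant --help`.

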