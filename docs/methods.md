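# Methods

This note documents the models, algorithms and design choices behind
`scaffdeg`, in the spirit of the methods documentation of packages such
as statsmodels or scanpy.

## Problem setting

A type I collagen sponge seeded with mesenchymal stem cells is cultured
for 44 days under physiological conditions. Stained sections imaged by
optical microscopy at low magnification show four texturally distinct
regions: the collagen scaffold, the extracellular matrix deposited by
differentiating osteocytes, cell nuclei, and background. Two quantities
are of interest: the growth of the extracellular matrix (a proxy for
cell activity) and the degradation of the scaffold, measured
gravimetrically as percent mass loss. The package estimates both from
images plus mass-loss records, and models the relation between them.

## Texture features

Each pixel is described by 24 features: for the three RGB channels and
the three hue/saturation/brightness channels (hue scaled to [0, 255]),
the raw intensity, the two eigenvalues of the smoothed structure
tensor, and the local histogram entropy.

**Structure tensor.** Partial derivatives are central differences
(`numpy.gradient`) with reflect boundary handling; the tensor entries
are products of derivatives averaged by a Gaussian window of width
σ (default **2 px**). Eigenvalues come from the closed form for
symmetric 2×2 matrices, λ = tr/2 ± sqrt((tr/2)² − det), with the
discriminant clipped at zero — the tensor is positive semidefinite, so
negative discriminants can only be rounding noise. The major eigenvalue
measures total local gradient energy, the minor one isotropy of that
energy. Boundary pixels are computed (not masked) but rely on reflected
values and are lower-confidence.

**Local entropy.** Intensities are binned into **256** equal-width bins
over [0, 256) and the Shannon entropy (−Σ p·log₂p, bits) of the
histogram in a circular neighbourhood of radius **r = 4 px** is
computed per pixel, backed by `skimage.filters.rank.entropy` (verified
in the tests against a brute-force per-pixel histogram oracle to
1e-10). At image borders the neighbourhood is cropped to the image.
Hue is treated as a linear channel; its circular topology is ignored in
binning — a known approximation that only affects hues near the wrap
point (rare in eosin/hematoxylin palettes).

σ and r are not dictated by the imaging physics; the defaults are the
typical trainable-segmentation choices at this magnification and are
exposed on `TextureFeatureExtractor`. The feature order
(channel-major, then intensity/λmax/λmin/entropy) is part of the public
contract; models record it and refuse mismatched stacks.

## Segmentation

A random forest (default **200 trees**, sqrt(F) features per split,
unbounded depth, fixed seed) is trained on a balanced, seeded,
without-replacement sample of labelled pixels (default 400 per class).
Probability maps are the averaged tree votes, so they are nonnegative
and sum to one per pixel by construction; label masks are the per-pixel
argmax with exact ties broken toward the lowest label index
(deterministic, documented). Label encoding is fixed across the
package: 0 background, 1 collagen, 2 extracellular matrix, 3 nuclei.

The thresholding baseline converts to 8-bit luma
(0.299/0.587/0.114 weights) and bands the histogram at 1–3 caller-chosen
cut points; it exists to reproduce the qualitative ordering that texture
-based forests beat pure intensity thresholding whenever class intensity
ranges overlap.

Validation metrics are computed one-vs-rest per class from the 4×4
confusion matrix (rows = real, columns = predicted): TP rate (= recall),
FP rate, precision, F-measure, Matthews correlation, plus
support-weighted averages and overall accuracy (trace/total). Cells
with a 0/0 denominator are reported as 0 and flagged, so weighted
averages stay defined. Cross-validation uses stratified folds and pools
the out-of-fold confusion matrix (a single matrix, not fold averages),
falling back to unstratified folds with a warning when a class has
fewer members than folds. The per-image misclassification score for
one ROI is the square root of the count of discordant one-vs-rest
pixels.

## Object features

Objects are 8-connected components of a binary ROI mask, despeckled at
**min_size = 10 px** (the mask source is silent on a despeckle policy;
without one, speckle dominates mean circularity). Per object:

* area in px and µm²; the default pixel scale is **300/189 µm/px**
  (189 px span 300 µm in the calibrated micrographs), configurable;
* perimeter as the length of the marching-squares contour polygon
  (sub-pixel; for objects with holes the longest contour — the outer
  boundary — is used);
* circularity 4π·area/perimeter², **capped at 1.0** — digital
  perimeters otherwise produce values above 1 for small objects;
* equivalent-ellipse major/minor axes from second central moments
  (4·sqrt of the covariance eigenvalues, the standard moment-based
  definition) and roundness 4·area/(π·major²).

Per-image summaries are arithmetic means over objects plus the modal
value of the 256-bin luma histogram within the ROI (ties toward the
lowest intensity). Zero-object images report NaN means and n_objects=0.

## Degradation kinetics

Mass loss versus time is fitted with a sum of *k* logistic components,
each with asymptote A (% mass loss), inflection time µ (days) and scale
(days). The model is monotone nondecreasing for positive parameters
and saturates at ΣAᵢ. Assumptions: independent, homoscedastic,
zero-mean residuals; a fixed design in time.

**Fitting.** The SSE surface of overlapping mixtures is multimodal, so
fitting is two-stage: seeded differential evolution (population
10×dimension, 300 generations) over box constraints, then bounded
trust-region least squares from the DE solution. Default bounds encode
the physics of a percent mass-loss process over a 44-day experiment:
A ∈ (0, 100], µ ∈ [min t, max t], scale ∈ [0.1, 20] days. Components
are reported sorted by µ, which resolves label-switching and makes the
parameterisation identifiable for well-separated components. Goodness
of fit is the general R² = 1 − SSE/SST (valid for nonlinear fits, may
be negative); standard errors, t and p values come from the linearised
least-squares covariance s²(JᵀJ)⁻¹ with a t reference distribution.

**Bootstrap.** Confidence intervals are percentile intervals from
residual resampling: mean-centred residuals are resampled with
replacement, added to the fitted curve, and the model refitted by
bounded least squares warm-started from the point estimate (the global
search is skipped — each resampled problem is a small perturbation of
the original). Default B = 1000. Failed refits are dropped and
counted; more than 20% failures raises.

A Gompertz curve y(t) = A·exp[−exp((µe/A)(λ−t)+1)] is provided for
completeness; choosing between logistic and Gompertz is left to R²
comparison, with no formal test.

## P-spline GAM

The nonparametric cross-check is a penalized B-spline smoother: a cubic
basis on **L = 10** equally spaced knot intervals over the data range
(knots extended degree steps beyond each boundary, giving L + degree
basis functions and equally spaced Greville points), a second-order
difference penalty on the coefficients, and smoothing λ chosen by
minimising GCV(λ) = n·SSE/(n − tr H)² over a 50-point logarithmic grid
in [1e-6, 1e6]. Because straight lines lie in the penalty nullspace,
an exactly linear signal is reproduced exactly at any λ, and the fitted
values are invariant to affine rescaling of the time axis (the knots
are placed relative to the data range). Prediction clamps inputs to
the training range rather than extrapolating the spline.

## Linear models and relative importance

Mass loss is regressed by OLS on logged features (ln area, ln
circularity, ln mode — all must be strictly positive, enforced with the
offending row named) and group dummies with **CCO as the reference
level**. Inference comes from statsmodels OLS. Rank deficiency is
detected before fitting and raised with the collinear columns named.

The LMG decomposition attributes the model R² to predictors by
averaging each predictor's incremental R² over all p! orderings,
computed via subset enumeration with combinatorial weights (identical
to explicit ordering enumeration, which is retained as a verification
path and cross-checked in the tests). Group dummies enter and leave
together as a single predictor. Exact enumeration is limited to p ≤ 8.
Shares always sum to the full-model R²; they are nonnegative for
uncorrelated predictors but can be negative in suppression scenarios.

Predictive validation assigns rows to k seeded random folds (default
k = 3), refits on the complement and predicts each held-out fold,
returning an observed/predicted/fold table.

## Synthetic data

The generators emulate the study conditions so the pipeline is testable
end to end without measured data:

* **Micrographs**: region geometry comes from quantile-thresholding a
  smooth Gaussian random field (length-scale 12 px), which yields
  connected, irregular regions with near-exact target area fractions;
  nuclei are quasi-elliptical blobs (radius ~4 px) overlaid last — they
  sit on top of tissue in stained sections, so they win overlaps —
  drawn until the nuclei area budget is met. Appearance is a per-class
  hematoxylin–eosin-like base colour plus correlated noise (smoothed
  white noise at a per-class grain length-scale), so classes differ in
  texture, not only colour — the premise that makes entropy and
  structure-tensor features informative. Default composition follows
  the observed trend: over days 0–44 the extracellular-matrix fraction
  grows (0.08 → 0.50 in the demo series) while collagen shrinks
  (0.62 → 0.20). The image noise statistics of the real micrographs
  are not known; the texture parameters are free knobs chosen to be
  plausible, not estimates. Consequently, segmentation accuracies
  measured on synthetic fixtures validate the machinery, not the
  accuracy attainable on real histology (no staining gradients,
  artifacts, focus drift or uneven illumination are simulated).
* **Mass-loss records**: the logistic-mixture mean at the requested
  times plus i.i.d. Gaussian noise; zero noise is exactly on-model.
* **Feature tables**: group labels plus log-uniform draws of
  circularity, mode and area within positive ranges, with mass loss
  computed from the multivariate log-linear predictor plus noise; CCO
  is the dummy-coding reference.

All generators are pure functions of (parameters, seed) — identical
inputs give bit-identical outputs.

## Numerical choices and degenerate inputs

* Structure-tensor discriminants and probability clip at 0; entropy
  treats 0·log 0 as 0 (via the histogram implementation).
* Argmax ties toward the lowest label; histogram-mode ties toward the
  lowest intensity; undefined metric cells report 0 with a flag.
* Mixture fits require at least 3k + 1 observations; the bootstrap
  requires a converged fit.
* GAM accepts duplicate time points (the penalty keeps the system
  well-posed) but requires more distinct values than the penalty order.
* Empty ROI masks give empty object tables; empty-object images give
  NaN means; the grayscale mode of an empty mask is an error.

## Problem sizes

The test-suite and demo problem sizes are deliberately compact: 64–128
px synthetic images, 100–300 forest trees, 45-point mass-loss series,
B = 40–200 bootstrap resamples in tests (B = 1000 remains the analysis
default), and 50-replicate Monte-Carlo checks for recovery and
coverage. These sizes keep every experiment deterministic and quick
while leaving the estimators at their analysis defaults.

## Known limitations

* Per-channel (not joint) entropy histograms; hue circularity ignored.
* The thresholding baseline requires caller-supplied cut points; no
  automatic histogram-valley search is implemented.
* Exact LMG is limited to 8 predictors; ordering sampling is not
  implemented.
* The synthetic micrographs are statistically, not photometrically,
  realistic; transfer of fixture accuracies to real stains is not
  claimed.
* Mixture identifiability degrades when components overlap
  (µ separation below a few scale units); bounds and the sorted-µ
  convention mitigate but cannot remove this.
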