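# Methods

This note documents the model behind `hestain`, the parameters that
matter, the synthetic data the test suite runs on, and the numerical
choices made where the design was genuinely open.

## Model and assumptions

The central assumption is that in an H&E tile at adequate magnification,
pixel color is strongly predictive of tissue structure: hematoxylin
renders nuclei blue-purple and dark, eosin renders cytoplasm pink and
stroma a paler pink, and unstained lumen is near-white.  Inter-slide
stain variability then acts mostly as a *global* color transformation
shared by all structures in an image, while the biologically meaningful
signal lives in *within-structure* color variation.  Normalization
therefore (a) identifies each pixel's structure, (b) moves the
structure's mean color onto a standard target, and (c) carries each
pixel's deviation Δd about its structure mean through the move unchanged.

This assumption fails where colors alias across structures (low
magnification, unusual stains, heavy pigments); the classifier is purely
color-based and applies no spatial regularization, so such pixels are
classified by color alone with low certainty values.

## Color geometry

HSV is cylindrical; hue is an angle.  All clustering and classification
run in the Cartesian embedding `(s·cos 2πh, s·sin 2πh, v)`, an isometry
on each hue circle (hues Δh apart at fixed s, v map to points
`2·s·sin(π·Δh)` apart).  The standard hexcone RGB↔HSV conversion is used.
On inversion, achromatic points (s = 0) get hue 0 by convention so tests
are deterministic.  Images are floating point in [0, 1] end to end;
8-bit quantization happens only at file write.

Hue is *wrapped* modulo 1 wherever outputs are constrained (normalization
and noise injection); clipping an angle would tear red hues at the wrap.
Saturation and value are clipped to [0, 1].  A `clip_hue` flag provides
the literal all-channel clamp for comparison.

## Tunable parameters

| parameter | default | units | rationale |
|---|---|---|---|
| `k` (color count) | 10 | clusters | the intra/inter variance-ratio curve plateaus near 10 on H&E tiles; beyond it, extra clusters buy little separation at the cost of more assignment effort |
| `C` (SVM box constraint) | 1 | — | standard soft-margin stiffness; adequate for the large, nearly separable pixel training sets this pipeline produces |
| `purity_threshold` | 0.9 | fraction | a cluster is auto-assigned only when ≥ 90 % of its pixels share a ground-truth class, mimicking a human labeling only unambiguous colors |
| `bins` (MI estimator) | 64 | per channel | resolves 8-bit channel structure without starving the histogram; see the estimator-regime caveat below |
| `max_train_per_stage` | 10 000 | points | cap on SVM fit size; a seeded stratified subsample keeps kernel-SVM training tractable on full tiles with no measurable accuracy cost on nearly separable data |

k-means uses k-means++ seeding, 10 restarts (best objective kept), at
most 300 Lloyd iterations, and a centroid-shift tolerance of 1e-6 as the
convergence test; with a fixed seed the result is deterministic.
`reduce_colors` refuses `k` larger than the number of distinct pixel
colors.  Above one million pixels, clustering fits on a seeded subsample
and predicts labels for all pixels (logged when active).

## The cascade and its certainty structure

Three binary linear SVMs split, in order: white vs tissue, stroma vs
epithelium, nuclei vs cytoplasm — each trained only on the classes that
reach its node.  Distances are geometric (`(w·x + b)/‖w‖`), making
certainty values comparable across stages and invariant to rescaling of
`w`.  Ties at exactly zero distance route to the stage's first-named
branch.

The four-channel certainty stack is filled as: the winning class channel
receives the (positive) distance to the hyperplane that decided the
class; each losing channel receives minus the distance to the hyperplane
at which that class's branch was rejected.  Exactly one channel per
pixel is positive, and the class map equals the argmax of the *signed*
channels.  Note the magnitudes of losing channels are stage-specific: a
nucleus pixel far from the white/tissue boundary carries a large negative
white channel, possibly larger in magnitude than its own positive
channel, so an argmax of absolute values would *not* recover the class
map — per-channel absolute values are a visualization device, not a
classifier.

A caveat on tiny training sets: with a single point per class, the
one-vs-rest stages are 1-vs-3 problems where the soft margin at C = 1 can
prefer paying slack on the singleton (cost 2C) over separating (cost
2/d² for hull separation d, and d < 1 is forced inside the unit
cylinder).  Real training sets are thousands of pixels per class, where
this degeneracy is impossible in the separable regime.

## Normalization details

Structure means use the circular mean for hue (direction of summed unit
vectors; `scipy.stats.circmean`) and arithmetic means for saturation and
value.  Δd is a per-channel 3-vector; its hue component is the circular
difference wrapped to [−0.5, 0.5).  Cohort targets average per-image
structure means (hue circularly) across images.  For unclipped pixels the
remap conserves Δd exactly, which makes it idempotent and makes each
structure's post-normalization mean equal its target; only
saturation/value clipping (rare for interior targets) breaks these
identities.  Pixels of a class missing from the target palette pass
through unchanged with a warning.

## Evaluation machinery

*Variability.*  Inter-image variability is the population standard
deviation (divide by n) across images of per-image structure means, per
class and channel; circular std (`scipy.stats.circstd`, resultant-vector
based) for hue.  Hue is omitted for white space, where near-zero
saturation makes hue meaningless.  Intra-image variability is the
population std of pixel colors within each structure.  The headline
summary is the *fold reduction* pre/post per (class, channel); on clean
synthetic data, where classification is essentially perfect and nothing
clips, post-normalization variability collapses to float rounding and
the reported fold reductions become astronomically large — the honest
limit of the model the generator implements, not a realistic value for
tissue.

*NMI.*  Mutual information uses the plug-in joint-histogram estimator
with 64 bins per channel; the hue–saturation plane is treated as one 2-D
variable (64² = 4096 states), and `MI(X, X)` is the entropy of X's
binned distribution, so `NMI(X, X) = 1` identically.  The plug-in
estimator is upward-biased by roughly (occupied joint cells)/(2N ln 2)
bits; with 4096-state variables this is material below ~10⁵ pixels.  The
noise-calibration curve (NMI against Gaussian-noise-added copies over
σ ∈ {0.001, 0.005, 0.01, 0.05, 0.1, 0.5}) is therefore computed on
512×512 tiles in the test suite, where bias is small relative to signal
and the curve is monotone in σ; on very small tiles the hue–sat curve's
tail turns upward purely from estimator bias.

## Synthetic data

`generate_layout` draws an oriented stroma band with a wavy edge, smooth
elliptical lumen blobs, and small elliptical nuclei (kept off the lumen),
with cytoplasm elsewhere; all four classes must be present or the
geometry is rejected.  `render_tile` colors each class with a base HSV
color, adds a per-image global HSV shift, then per-pixel isotropic
Gaussian noise (σ = 0.02 default), wraps/clips, and converts to RGB.
Default base colors — white (0, 0.02, 0.97), stroma (0.97, 0.15, 0.85),
nuclei (0.70, 0.55, 0.35), cytoplasm (0.92, 0.35, 0.75) — give pairwise
Cartesian separations ≥ 0.2, ten times the default pixel noise.
Cohorts draw per-image shifts i.i.d. Gaussian (σ_shift = 0.05 per
channel default) with child seeds derived from one master seed;
generation is bit-reproducible.  A multiplicative value-channel drift
variant exists behind a flag.

What the generator does *not* emulate: spatial color mixing at structure
boundaries (every pixel is pure class color plus noise), chromatic
aberration, focus or compression artifacts, within-class color gradients,
and structures beyond the four classes (lymphocytes, blood, markings).
Consequently, passing tests demonstrate the pipeline's correctness under
its own model — global drift plus i.i.d. noise around well-separated
class colors — and calibrate its machinery, but do not bound
classification accuracy or residual variability on real tissue, where
mixed pixels and overlapping class colors make both worse.

## Problem sizes

The test suite and the acceptance script run at desk scale: 128²–512²
tiles, cohorts of 5–20 images at 256².  These sizes put every estimator
in its valid regime (see the MI note above) while keeping a full run in
the order of a minute; the pipeline itself is linear in pixel count and
applies unchanged to larger tiles.

## Known limitations

- Purely color-based classification cannot disambiguate structures that
  share colors; the certainty channels flag, but do not fix, such pixels.
- The cluster-to-structure assignment is the accuracy bottleneck: a wrong
  assignment trains the cascade on wrong labels.  `auto_assign` needs
  ground truth and therefore only serves synthetic or annotated data.
- Fold-reduction figures on synthetic cohorts measure the idealized
  limit (see above) and should not be quoted as expected performance on
  scanner data.
- Clipping breaks Δd conservation for pixels whose target ± deviation
  leaves [0, 1]; with near-achromatic white targets, white-space
  saturation is the usual casualty.
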