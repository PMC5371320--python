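# hestain

Structure-centric color normalization for hematoxylin & eosin (H&E)
histology images.

Staining variability is ubiquitous in digital pathology: differences in
tissue preparation, stain batches, and scanners shift the colors of
otherwise comparable slides, which degrades any downstream analysis that
reads pixel color or intensity.  `hestain` normalizes H&E tiles not by
modeling stain optics but by exploiting the correlation between color and
tissue structure: colors are anchored to the biological elements they
belong to, and those anchors are moved onto a standardized palette.

## Method

For an RGB tile (channels in [0, 1]):

1. **Color reduction.**  Convert to HSV and embed in Cartesian
   coordinates, `(x, y, z) = (s·cos 2πh, s·sin 2πh, v)`, so Euclidean
   distance respects hue circularity.  k-means (default `k = 10`) reduces
   the image to k representative colors.  The mean intra-/inter-cluster
   variance ratio as a function of k is the diagnostic for choosing k: it
   declines and plateaus near 10 clusters for typical H&E tiles.
2. **Structure assignment.**  Each cluster color is mapped to one of four
   tissue elements — white space/lumen, stroma, nuclei, cytoplasm — or
   left unassigned when it mixes elements.  Assignments are supplied as a
   JSON file, or derived automatically from ground-truth label maps
   (purity-threshold majority vote) for synthetic data.
3. **Pixel classification.**  Assigned-cluster pixels train three linear
   soft-margin SVMs (box constraint `C = 1`) arranged as a decision tree:
   white vs tissue, then stroma vs epithelium, then nuclei vs cytoplasm.
   Every pixel is routed through the tree and carries a four-channel
   certainty stack of signed geometric distances to the deciding
   hyperplanes — positive for its class, negative for the rejected ones.
4. **Color normalization.**  Per image and tissue element, measure the
   mean HSV color (hue circularly).  Each pixel's deviation about its
   element mean, **Δd**, is preserved while the mean itself is replaced
   by a target color:

   `out(p) = target(class(p)) + Δd(p)`, then saturation/value are clipped
   to [0, 1] and hue wraps modulo 1.

   Targets default to the mean structure colors of a reference cohort.

Evaluation utilities measure the inter-image standard deviation of
structure means before/after normalization (fold-reduction report), the
within-structure std that normalization should preserve, and the
normalized mutual information `NMI = MI(X, Y) / MI(X, X)` between the
original and transformed images (value channel, and the 2-D
hue–saturation plane), plus a Gaussian-noise calibration curve for
interpreting NMI scores.

A synthetic generator produces four-structure H&E-like tiles with
ground-truth label maps, per-image global stain shifts, and per-pixel
noise, so the entire pipeline can be exercised and validated without
external data.

## Worked example

```python
import hestain as hs
from hestain.metrics import inter_image_variability, nmi

# six synthetic tiles with per-image stain drift (sigma 0.05 per channel)
spec = hs.CohortSpec(n_images=6, shape=(128, 128),
                     sigma_shift=0.05, sigma=0.02, seed=0)
cohort = hs.generate_cohort(spec)

# full pipeline: k-means, auto-assignment, SVM cascade, normalization
results, targets = hs.normalize_cohort(
    [c[0] for c in cohort], truth_labels=[c[1] for c in cohort], seed=1)

report = hs.VariabilityReport(
    pre=inter_image_variability([(r.hsv, r.classified) for r in results]),
    post=inter_image_variability([(r.normalized, r.classified) for r in results]))
nuc = hs.TissueClass.NUCLEI
print("nuclei value std pre :", round(report.pre[nuc]["val"], 4))
print("nuclei value std post:", round(report.post[nuc]["val"], 6))
scores = nmi(results[0].hsv, results[0].normalized)
print("NMI value channel    :", round(scores["value"], 3))
print("NMI hue-sat plane    :", round(scores["hue_sat"], 3))
```

prints

```
nuclei value std pre : 0.0261
nuclei value std post: 0.0
NMI value channel    : 0.834
NMI hue-sat plane    : 0.811
```

The inter-image spread of the mean nuclear value (≈ 0.026, reflecting the
simulated stain drift) collapses to numerical zero after normalization —
on synthetic tiles the cascade classifies essentially every pixel
correctly, so each structure's mean lands exactly on its target.  The NMI
scores say that roughly 80 % of the original image's (binned) information
is still present in the normalized image; a flat class→target mapping
without Δd scores far lower.

The same pipeline is available from the shell:

```sh
hestain synth cohort/ --n 6 --size 128 --seed 0
hestain normalize cohort/img_000.png --truth cohort/lbl_000.png --out out/img0
hestain evaluate --pre cohort/ --post normd/ --out reports/run1
```

## Scope

`hestain` operates on tiles, not whole slides; it assumes H&E color
statistics and magnification high enough (≥ 10×) that colors are not
aliased across structures.  It does not perform stain deconvolution,
histogram matching, or ICC color management.
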