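"""Deviation-preserving color normalization.

Once every pixel carries a tissue class, normalization is a three-step
remap performed per image in HSV coordinates:

1. measure each tissue element's mean color in the image (hue circularly);
2. move every pixel to the target color of its class, carrying along the
   pixel's deviation ``dd`` from its element's mean;
3. constrain the result — saturation and value clip to [0, 1], hue wraps
   modulo 1 (it is circular; an optional flag clips it instead).

Because ``dd`` is conserved for unclipped pixels, within-structure
variation — the part of the image that carries biological detail —
survives the remap, while the between-image stain differences carried by
the structure means are removed.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import circmean

from .assign import TissueClass
from .classify import ClassifiedImage
from .color import hue_difference, validate_hsv, wrap_hue

__all__ = [
    "TargetColors",
    "structure_means",
    "derive_targets",
    "deviation_field",
    "normalize_image",
    "normalize_without_deviation",
]

_CLASS_NAMES = {
    TissueClass.WHITE: "white",
    TissueClass.STROMA: "stroma",
    TissueClass.NUCLEI: "nuclei",
    TissueClass.CYTOPLASM: "cytoplasm",
}


@dataclass
class TargetColors:
    """One HSV anchor color per tissue class.

    The choice of targets is arbitrary in principle — any standardized
    palette works — but the white target should be near-achromatic
    (a warning is raised when its saturation is not).
    """

    colors: dict[TissueClass, np.ndarray]

    def __post_init__(self) -> None:
        self.colors = {
            cls: np.asarray(c, dtype=float) for cls, c in self.colors.items()
        }
        for cls, c in self.colors.items():
            if c.shape != (3,):
                raise ValueError(f"target for {cls.name} must be an HSV triplet")
            if c.min() < 0 or c.max() > 1:
                raise ValueError(f"target for {cls.name} outside [0, 1]")
        white = self.colors.get(TissueClass.WHITE)
        if white is not None and white[1] > 0.15:
            warnings.warn(
                f"white target saturation {white[1]:.3f} is not near 0; "
                "white space will look tinted"
            )

    def to_dict(self) -> dict:
        return {_CLASS_NAMES[c]: col.tolist() for c, col in self.colors.items()}

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def load(cls, path) -> "TargetColors":
        with open(path) as fh:
            data = json.load(fh)
        name_to_class = {v: k for k, v in _CLASS_NAMES.items()}
        return cls(colors={name_to_class[n]: np.asarray(v) for n, v in data.items()})


def structure_means(
    image: np.ndarray, classified: ClassifiedImage
) -> dict[TissueClass, np.ndarray]:
    """Mean HSV color of each tissue element present in the image.

    Saturation and value use arithmetic means; hue uses the circular mean
    (direction of the summed unit vectors), so e.g. nuclei hues 0.95 and
    0.05 average to 0.0, not 0.5.  Classes with no pixels are skipped with
    a warning.
    """
    hsv = validate_hsv(image)
    if hsv.shape[:2] != classified.shape:
        raise ValueError("image and classification shapes differ")
    means: dict[TissueClass, np.ndarray] = {}
    for cls in TissueClass:
        mask = classified.mask(cls)
        if not np.any(mask):
            warnings.warn(f"class {cls.name} has no pixels; skipped")
            continue
        px = hsv[mask]
        h = circmean(px[:, 0], high=1.0)
        means[cls] = np.array([h % 1.0, px[:, 1].mean(), px[:, 2].mean()])
    if not means:
        raise ValueError("no classified pixels in image")
    return means


def derive_targets(
    pairs: list[tuple[np.ndarray, ClassifiedImage]]
) -> TargetColors:
    """Average per-image structure means across a cohort into target colors.

    This mirrors deriving the standard palette from a reference image set;
    hue is averaged circularly.  A class absent from every image is an
    error.
    """
    if not pairs:
        raise ValueError("empty image list")
    per_class: dict[TissueClass, list[np.ndarray]] = {c: [] for c in TissueClass}
    for image, classified in pairs:
        for cls, mean in structure_means(image, classified).items():
            per_class[cls].append(mean)
    colors = {}
    for cls, means in per_class.items():
        if not means:
            raise ValueError(f"class {cls.name} absent from every image")
        arr = np.stack(means)
        colors[cls] = np.array(
            [
                circmean(arr[:, 0], high=1.0) % 1.0,
                arr[:, 1].mean(),
                arr[:, 2].mean(),
            ]
        )
    return TargetColors(colors=colors)


def deviation_field(
    image: np.ndarray,
    classified: ClassifiedImage,
    means: dict[TissueClass, np.ndarray] | None = None,
) -> np.ndarray:
    """Per-pixel signed HSV deviation ``dd`` about the pixel's structure mean.

    The hue component is a circular difference in [-0.5, 0.5); by
    construction the per-structure mean of ``dd`` is ~0 in every channel.
    """
    hsv = validate_hsv(image)
    if means is None:
        means = structure_means(hsv, classified)
    dd = np.zeros_like(hsv)
    for cls, mean in means.items():
        mask = classified.mask(cls)
        dd[mask, 0] = hue_difference(hsv[mask, 0], mean[0])
        dd[mask, 1] = hsv[mask, 1] - mean[1]
        dd[mask, 2] = hsv[mask, 2] - mean[2]
    return dd


def normalize_image(
    image: np.ndarray,
    classified: ClassifiedImage,
    targets: TargetColors,
    clip_hue: bool = False,
) -> np.ndarray:
    """Remap an image onto the target colors, preserving per-pixel deviation.

    For every pixel ``p`` of class ``c``::

        out(p) = target(c) + dd(p),    dd(p) = in(p) - mean_c(image)

    computed per HSV channel (hue circularly), then constrained: s and v
    clip to [0, 1]; hue wraps modulo 1 unless ``clip_hue``.  Pixels whose
    class has no target color pass through unchanged with a warning.
    """
    hsv = validate_hsv(image)
    means = structure_means(hsv, classified)
    dd = deviation_field(hsv, classified, means=means)
    out = hsv.copy()
    for cls in means:
        mask = classified.mask(cls)
        if cls not in targets.colors:
            warnings.warn(f"no target color for class {cls.name}; passed through")
            continue
        out[mask] = targets.colors[cls] + dd[mask]
    return wrap_hue(out, clip_hue=clip_hue)


def normalize_without_deviation(
    image: np.ndarray,
    classified: ClassifiedImage,
    targets: TargetColors,
) -> np.ndarray:
    """Map every pixel flat onto its class target (the no-``dd`` control).

    The output contains at most one color per class; all within-structure
    detail is discarded.  Used to show that classification alone does not
    preserve image information.
    """
    hsv = validate_hsv(image)
    out = hsv.copy()
    for cls in TissueClass:
        mask = classified.mask(cls)
        if not np.any(mask):
            continue
        if cls not in targets.colors:
            warnings.warn(f"no target color for class {cls.name}; passed through")
            continue
        out[mask] = targets.colors[cls]
    return wrap_hue(out)
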