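"""Quantitative evaluation of color normalization.

Three families of measurements:

* **Inter-/intra-image variability** — the standard deviation of
  per-structure mean colors across a cohort (how much stain variation
  remains between images), and the per-structure pixel standard deviation
  within an image (how much detail-bearing variation is preserved).
  Hue statistics are circular; hue is omitted for white space, where
  near-zero saturation makes hue meaningless.

* **Normalized mutual information (NMI)** — the mutual information
  between the unnormalized image X and a transformed image Y, expressed
  as a fraction of the self-information of X:

      NMI = MI(X, Y) / MI(X, X)

  so that Y = X scores exactly 1.  MI uses a plug-in joint-histogram
  estimator (64 bins per channel by default); the value channel is scored
  on its own and hue/saturation jointly as a 2-D plane.

* **Noise calibration** — NMI between an image and Gaussian-noise-added
  copies of itself over a grid of sigma values, which anchors NMI scores
  to a visually interpretable amount of corruption.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import circstd

from .assign import TissueClass
from .classify import ClassifiedImage
from .color import validate_hsv, wrap_hue

__all__ = [
    "PAPER_SIGMA_GRID",
    "NoiseParams",
    "VariabilityReport",
    "mutual_information",
    "nmi",
    "add_hsv_noise",
    "noise_nmi_curve",
    "inter_image_variability",
    "intra_image_variability",
    "variability_report",
]

#: standard sigma grid for the noise-NMI calibration curve
PAPER_SIGMA_GRID = (0.001, 0.005, 0.01, 0.05, 0.1, 0.5)

_CHANNELS = ("hue", "sat", "val")


@dataclass(frozen=True)
class NoiseParams:
    """Isotropic Gaussian HSV noise: standard deviation and RNG seed."""

    sigma: float
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")


def _bin_codes(data: np.ndarray, bins: int) -> tuple[np.ndarray, int]:
    """Quantize [0, 1] columns to integer codes; multi-column data is
    flattened to a single joint code (bins^d states)."""
    arr = np.asarray(data, dtype=float)
    if arr.ndim == 1:
        arr = arr[:, None]
    idx = np.clip((arr * bins).astype(np.int64), 0, bins - 1)
    codes = idx[:, 0]
    states = bins
    for col in range(1, arr.shape[1]):
        codes = codes * bins + idx[:, col]
        states *= bins
    return codes, states


def mutual_information(X: np.ndarray, Y: np.ndarray, bins: int = 64) -> float:
    """Plug-in mutual information (bits) between paired pixel rasters.

    ``X`` and ``Y`` are channel rasters of matching shape with values in
    [0, 1]; a trailing axis of length 2 is treated as a joint 2-D variable
    (the hue-saturation plane).  Each variable is quantized to ``bins``
    levels per channel and MI is computed from the joint histogram of
    paired pixels.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if X.shape != Y.shape:
        raise ValueError(f"shape mismatch: {X.shape} vs {Y.shape}")
    if bins < 2:
        raise ValueError("bins must be >= 2")
    d = X.shape[-1] if X.ndim >= 1 and X.shape[-1] == 2 and X.ndim > 1 else 1
    xcol = X.reshape(-1, d) if d == 2 else X.reshape(-1)
    ycol = Y.reshape(-1, d) if d == 2 else Y.reshape(-1)
    xc, xs = _bin_codes(xcol, bins)
    yc, _ = _bin_codes(ycol, bins)

    n = len(xc)
    joint = xc * np.int64(xs) + yc
    cells, counts = np.unique(joint, return_counts=True)
    px = np.bincount(xc, minlength=xs) / n
    py = np.bincount(yc, minlength=xs) / n
    p = counts / n
    mi = np.sum(p * np.log2(p / (px[cells // xs] * py[cells % xs])))
    return float(max(mi, 0.0))


def nmi(X: np.ndarray, Y: np.ndarray, bins: int = 64) -> dict[str, float]:
    """Normalized mutual information per channel group.

    Returns ``{"value": MI(Xv, Yv)/MI(Xv, Xv), "hue_sat": ...}`` where the
    hue-saturation entry uses the 2-D joint of (h, s).  ``MI(X, X)`` is the
    entropy of X's binned distribution; a constant X makes NMI undefined.
    """
    Xh = validate_hsv(X)
    Yh = validate_hsv(Y)
    if Xh.shape != Yh.shape:
        raise ValueError("images must share a shape")
    out = {}
    for name, sel in (("value", np.s_[..., 2]), ("hue_sat", np.s_[..., :2])):
        self_mi = mutual_information(Xh[sel], Xh[sel], bins=bins)
        if self_mi == 0.0:
            raise ValueError(
                f"MI(X, X) = 0 for channel group '{name}' (constant image); "
                "NMI undefined"
            )
        out[name] = mutual_information(Xh[sel], Yh[sel], bins=bins) / self_mi
    return out


def add_hsv_noise(
    image: np.ndarray,
    params: NoiseParams | None = None,
    *,
    sigma: float | None = None,
    seed: int = 0,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Add i.i.d. Gaussian noise to every HSV channel.

    Hue wraps modulo 1; saturation and value clip to [0, 1] (the same
    constraint convention as normalization).  ``sigma = 0`` is the
    identity.  Deterministic for a fixed seed.
    """
    if params is None:
        if sigma is None:
            raise ValueError("provide NoiseParams or sigma=")
        params = NoiseParams(sigma=sigma, seed=seed)
    hsv = validate_hsv(image)
    if params.sigma == 0:
        return hsv
    if rng is None:
        rng = np.random.default_rng(params.seed)
    noisy = hsv + rng.normal(0.0, params.sigma, size=hsv.shape)
    return wrap_hue(noisy)


def noise_nmi_curve(
    image: np.ndarray,
    sigmas: tuple[float, ...] = PAPER_SIGMA_GRID,
    seed: int = 0,
    bins: int = 64,
) -> list[tuple[float, float, float]]:
    """NMI between an image and noise-added copies over a sigma grid.

    Returns ``[(sigma, nmi_value, nmi_hue_sat), ...]`` in the given sigma
    order; nonincreasing in sigma in expectation.
    """
    if any(s < 0 for s in sigmas):
        raise ValueError("sigmas must be >= 0")
    hsv = validate_hsv(image)
    rng = np.random.default_rng(seed)
    out = []
    for s in sigmas:
        noisy = add_hsv_noise(hsv, NoiseParams(sigma=float(s), seed=seed), rng=rng)
        scores = nmi(hsv, noisy, bins=bins)
        out.append((float(s), scores["value"], scores["hue_sat"]))
    return out


def _class_channel_stats(values: np.ndarray) -> dict[str, float]:
    """Population stds of an (n, 3) HSV sample; hue circular."""
    return {
        "hue": float(circstd(values[:, 0], high=1.0)),
        "sat": float(np.std(values[:, 1])),
        "val": float(np.std(values[:, 2])),
    }


def inter_image_variability(
    cohort: list[tuple[np.ndarray, ClassifiedImage]]
) -> dict[TissueClass, dict[str, float]]:
    """Across-image std of per-structure mean colors.

    For each tissue class and channel, the population standard deviation
    over images of that image's structure mean (circular std for hue).
    Hue is omitted for white space.  Classes absent from every image are
    omitted with a warning.
    """
    from .normalize import structure_means

    if len(cohort) < 2:
        raise ValueError("need at least 2 images")
    per_class: dict[TissueClass, list[np.ndarray]] = {c: [] for c in TissueClass}
    for image, classified in cohort:
        for cls, mean in structure_means(image, classified).items():
            per_class[cls].append(mean)
    report: dict[TissueClass, dict[str, float]] = {}
    for cls, means in per_class.items():
        if len(means) < 2:
            warnings.warn(f"class {cls.name} present in <2 images; omitted")
            continue
        stats = _class_channel_stats(np.stack(means))
        if cls == TissueClass.WHITE:
            stats.pop("hue")
        report[cls] = stats
    return report


def intra_image_variability(
    image: np.ndarray, classified: ClassifiedImage
) -> dict[TissueClass, dict[str, float]]:
    """Within-image, per-structure pixel color std (hue circular).

    Hue is omitted for white space.  Used to verify that normalization
    preserves within-structure variability.
    """
    hsv = validate_hsv(image)
    report: dict[TissueClass, dict[str, float]] = {}
    for cls in TissueClass:
        mask = classified.mask(cls)
        if not np.any(mask):
            warnings.warn(f"class {cls.name} has no pixels; omitted")
            continue
        stats = _class_channel_stats(hsv[mask])
        if cls == TissueClass.WHITE:
            stats.pop("hue")
        report[cls] = stats
    return report


@dataclass
class VariabilityReport:
    """Pre/post inter-image stds and their fold reductions.

    ``reduction[cls][chan] = pre / post`` where defined (post > 0);
    entries with post == 0 are reported as ``inf``.
    """

    pre: dict[TissueClass, dict[str, float]]
    post: dict[TissueClass, dict[str, float]]
    reduction: dict[TissueClass, dict[str, float]] = field(init=False)

    def __post_init__(self) -> None:
        self.reduction = {}
        for cls, chans in self.pre.items():
            if cls not in self.post:
                continue
            self.reduction[cls] = {}
            for chan, pre_std in chans.items():
                post_std = self.post[cls].get(chan)
                if post_std is None:
                    continue
                self.reduction[cls][chan] = (
                    pre_std / post_std if post_std > 0 else float("inf")
                )

    def min_reduction(
        self, classes: tuple[TissueClass, ...] | None = None
    ) -> float:
        """Smallest fold reduction over the given classes (default: the
        three stained tissue classes, white excluded)."""
        if classes is None:
            classes = (TissueClass.STROMA, TissueClass.NUCLEI, TissueClass.CYTOPLASM)
        vals = [
            r
            for cls in classes
            if cls in self.reduction
            for r in self.reduction[cls].values()
        ]
        if not vals:
            raise ValueError("no reduction factors available")
        return min(vals)

    def to_dict(self) -> dict:
        def conv(d):
            return {cls.name.lower(): dict(ch) for cls, ch in d.items()}

        return {
            "pre": conv(self.pre),
            "post": conv(self.post),
            "reduction": conv(self.reduction),
        }


def variability_report(
    pre_cohort: list[tuple[np.ndarray, ClassifiedImage]],
    post_cohort: list[tuple[np.ndarray, ClassifiedImage]],
) -> VariabilityReport:
    """Compare inter-image variability before and after normalization."""
    return VariabilityReport(
        pre=inter_image_variability(pre_cohort),
        post=inter_image_variability(post_cohort),
    )
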