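"""Synthetic H&E-like tiles with ground truth.

Generates four-structure tiles — lumen/white space (smooth bright blobs),
stroma (an oriented fibrous band), nuclei (small filled ellipses) and
cytoplasm (everything else) — with:

* per-class base HSV colors approximating H&E appearance (hematoxylin
  makes nuclei blue-purple and dark; eosin makes cytoplasm pink and
  stroma a paler pink; lumen is near-white);
* a per-image global HSV shift emulating between-slide stain and scanner
  drift (the variability normalization is meant to remove);
* per-pixel isotropic Gaussian HSV noise emulating within-structure
  texture (the variability normalization is meant to keep).

Every function is deterministic given its seed; cohorts derive per-image
child seeds from a master seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.draw import ellipse

from .assign import TissueClass
from .color import hsv_to_rgb, wrap_hue

__all__ = [
    "DEFAULT_BASE_COLORS",
    "TissueGeometry",
    "StainProfile",
    "TissueLayout",
    "CohortSpec",
    "generate_layout",
    "render_tile",
    "generate_cohort",
]

#: default per-class base colors (HSV); chosen to mimic H&E at ~20x
DEFAULT_BASE_COLORS: dict[TissueClass, tuple[float, float, float]] = {
    TissueClass.WHITE: (0.0, 0.02, 0.97),
    TissueClass.STROMA: (0.97, 0.15, 0.85),
    TissueClass.NUCLEI: (0.70, 0.55, 0.35),
    TissueClass.CYTOPLASM: (0.92, 0.35, 0.75),
}


@dataclass(frozen=True)
class TissueGeometry:
    """Layout parameters; defaults give plausible proportions at 256x256.

    ``nuclei_density`` is nuclei per pixel, so counts scale with tile area.
    """

    nuclei_density: float = 1.2e-3
    nucleus_radius: tuple[float, float] = (2.5, 5.5)
    lumen_count: int = 3
    lumen_radius: tuple[float, float] = (12.0, 30.0)
    stroma_fraction: float = 0.30

    def nuclei_count(self, shape: tuple[int, int]) -> int:
        return int(round(self.nuclei_density * shape[0] * shape[1]))


@dataclass(frozen=True)
class StainProfile:
    """Coloring of one tile: base colors, a global HSV shift, pixel noise.

    ``multiplicative_value`` switches the value channel from an additive
    shift to a gain ``v * (1 + shift_v)``, emulating exposure-like drift.
    """

    base_colors: dict[TissueClass, tuple[float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_BASE_COLORS)
    )
    shift: tuple[float, float, float] = (0.0, 0.0, 0.0)
    sigma: float = 0.02
    multiplicative_value: bool = False

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        white_s = self.base_colors[TissueClass.WHITE][1]
        if white_s > 0.05:
            raise ValueError("white base saturation must be <= 0.05")


@dataclass
class TissueLayout:
    """Ground-truth class raster plus the geometry that produced it."""

    labels: np.ndarray  # (H, W) TissueClass codes
    geometry: TissueGeometry
    seed: int

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape

    def class_fractions(self) -> dict[TissueClass, float]:
        n = self.labels.size
        return {
            cls: float(np.sum(self.labels == cls)) / n for cls in TissueClass
        }


@dataclass(frozen=True)
class CohortSpec:
    """A population of tiles sharing base colors but drifting in stain.

    Per-image global shifts are i.i.d. Gaussian(0, sigma_shift^2) per HSV
    channel; layouts differ between images (child seeds from the master).
    """

    n_images: int = 20
    shape: tuple[int, int] = (256, 256)
    base_colors: dict[TissueClass, tuple[float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_BASE_COLORS)
    )
    sigma_shift: float = 0.05
    sigma: float = 0.02
    seed: int = 0
    geometry: TissueGeometry = field(default_factory=TissueGeometry)

    def __post_init__(self) -> None:
        if self.n_images < 1:
            raise ValueError("n_images must be >= 1")
        if self.sigma_shift < 0 or self.sigma < 0:
            raise ValueError("sigmas must be >= 0")


def generate_layout(
    shape: tuple[int, int] = (256, 256),
    geometry: TissueGeometry | None = None,
    seed: int = 0,
) -> TissueLayout:
    """Draw a random tissue layout; deterministic given ``seed``.

    Raises on infeasible geometry (any structure crowded out entirely, or
    zero nuclei/lumen/stroma requested — all four classes must appear).
    """
    if geometry is None:
        geometry = TissueGeometry()
    H, W = shape
    if H < 64 or W < 64:
        raise ValueError("tile must be at least 64x64")
    if geometry.nuclei_count(shape) < 1:
        raise ValueError("geometry requests zero nuclei; all four classes required")
    if geometry.lumen_count < 1:
        raise ValueError("geometry requests zero lumen blobs")
    if not (0.0 < geometry.stroma_fraction < 1.0):
        raise ValueError("stroma_fraction must be in (0, 1)")

    rng = np.random.default_rng(seed)
    labels = np.full(shape, int(TissueClass.CYTOPLASM), dtype=np.int64)

    # stroma: oriented band with a wavy, fiber-like edge
    theta = rng.uniform(0, 2 * np.pi)
    yy, xx = np.mgrid[0:H, 0:W]
    axial = (np.cos(theta) * xx + np.sin(theta) * yy) / max(H, W)
    ortho = (-np.sin(theta) * xx + np.cos(theta) * yy) / max(H, W)
    wobble = 0.04 * np.sin(2 * np.pi * rng.uniform(1.5, 3.5) * ortho + rng.uniform(0, 2 * np.pi))
    t = axial + wobble
    labels[t <= np.quantile(t, geometry.stroma_fraction)] = int(TissueClass.STROMA)

    # lumen: smooth elliptical cavities
    for _ in range(geometry.lumen_count):
        r0, c0 = rng.uniform(0, H), rng.uniform(0, W)
        ra, rb = rng.uniform(*geometry.lumen_radius, size=2)
        rr, cc = ellipse(r0, c0, ra, rb, shape=shape, rotation=rng.uniform(0, np.pi))
        labels[rr, cc] = int(TissueClass.WHITE)

    # nuclei: small filled ellipses, kept off the lumen
    placed = 0
    for _ in range(geometry.nuclei_count(shape) * 10):
        if placed >= geometry.nuclei_count(shape):
            break
        r0, c0 = rng.uniform(0, H), rng.uniform(0, W)
        if labels[int(r0), int(c0)] == int(TissueClass.WHITE):
            continue
        ra, rb = rng.uniform(*geometry.nucleus_radius, size=2)
        rr, cc = ellipse(r0, c0, ra, rb, shape=shape, rotation=rng.uniform(0, np.pi))
        labels[rr, cc] = int(TissueClass.NUCLEI)
        placed += 1

    layout = TissueLayout(labels=labels, geometry=geometry, seed=seed)
    fractions = layout.class_fractions()
    absent = [cls.name for cls, f in fractions.items() if f == 0.0]
    if absent:
        raise ValueError(f"infeasible geometry: classes crowded out: {absent}")
    return layout


def render_tile(
    layout: TissueLayout,
    profile: StainProfile | None = None,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Color a layout: base(class) + global shift + per-pixel noise, in HSV.

    Hue wraps, saturation/value clip, then the tile converts to RGB.
    Returns ``(rgb, truth_labels)``.
    """
    if profile is None:
        profile = StainProfile()
    rng = np.random.default_rng(seed)
    base = np.zeros(layout.shape + (3,), dtype=float)
    for cls, color in profile.base_colors.items():
        base[layout.labels == int(cls)] = color

    shift = np.asarray(profile.shift, dtype=float)
    hsv = base.copy()
    hsv[..., 0] += shift[0]
    hsv[..., 1] += shift[1]
    if profile.multiplicative_value:
        hsv[..., 2] *= 1.0 + shift[2]
    else:
        hsv[..., 2] += shift[2]
    if profile.sigma > 0:
        hsv += rng.normal(0.0, profile.sigma, size=hsv.shape)
    hsv = wrap_hue(hsv)
    return hsv_to_rgb(hsv), layout.labels.copy()


def generate_cohort(
    spec: CohortSpec,
) -> list[tuple[np.ndarray, np.ndarray, StainProfile]]:
    """Generate a cohort of tiles with i.i.d. per-image stain shifts.

    Returns ``[(rgb, truth_labels, profile), ...]``; bit-identical on
    repeat calls with the same spec.
    """
    master = np.random.default_rng(spec.seed)
    # draw all child seeds and shifts up front so per-image work is independent
    child_seeds = master.integers(0, 2**31 - 1, size=(spec.n_images, 2))
    shifts = master.normal(0.0, spec.sigma_shift, size=(spec.n_images, 3))
    out = []
    for i in range(spec.n_images):
        layout = generate_layout(spec.shape, spec.geometry, seed=int(child_seeds[i, 0]))
        profile = StainProfile(
            base_colors=dict(spec.base_colors),
            shift=tuple(shifts[i]),
            sigma=spec.sigma,
        )
        rgb, truth = render_tile(layout, profile, seed=int(child_seeds[i, 1]))
        out.append((rgb, truth, profile))
    return out
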