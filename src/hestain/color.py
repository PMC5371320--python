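"""Color-space primitives.

All rasters are floating-point arrays of shape ``(H, W, 3)`` with every
channel in ``[0, 1]``; 8-bit quantization happens only at file write.
Hue is circular and treated modulo 1.

Because HSV is a cylindrical coordinate system, Euclidean distance on raw
``(h, s, v)`` triplets is meaningless near the hue wrap.  Both the k-means
color reduction and the linear SVM cascade therefore operate in a Cartesian
embedding of the HSV cone::

    x = s * cos(2 pi h),   y = s * sin(2 pi h),   z = v

which is an isometry on each hue circle: two hues separated by ``dh`` at
fixed ``(s, v)`` map to points ``2 * s * sin(pi * dh)`` apart.
"""

from __future__ import annotations

import numpy as np
from skimage import color as _skcolor

__all__ = [
    "validate_rgb",
    "validate_hsv",
    "rgb_to_hsv",
    "hsv_to_rgb",
    "hsv_to_cartesian",
    "cartesian_to_hsv",
    "wrap_hue",
    "hue_difference",
    "read_rgb",
    "write_rgb",
]

_TWO_PI = 2.0 * np.pi


def validate_rgb(image: np.ndarray) -> np.ndarray:
    """Check an (H, W, 3) RGB raster with channels in [0, 1]; return float64."""
    arr = np.asarray(image, dtype=float)
    if arr.ndim != 3 or arr.shape[-1] != 3:
        raise ValueError(f"expected (H, W, 3) RGB raster, got shape {arr.shape}")
    if arr.shape[0] < 1 or arr.shape[1] < 1:
        raise ValueError("empty image")
    if not np.all(np.isfinite(arr)):
        raise ValueError("non-finite channel values in RGB image")
    if arr.min() < 0.0 or arr.max() > 1.0:
        raise ValueError("RGB channel values outside [0, 1]")
    return arr


def validate_hsv(image: np.ndarray) -> np.ndarray:
    """Check an (H, W, 3) HSV raster; wraps hue into [0, 1), requires s, v in [0, 1]."""
    arr = np.asarray(image, dtype=float)
    if arr.ndim != 3 or arr.shape[-1] != 3:
        raise ValueError(f"expected (H, W, 3) HSV raster, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise ValueError("non-finite channel values in HSV image")
    sv = arr[..., 1:]
    if sv.min() < 0.0 or sv.max() > 1.0:
        raise ValueError("saturation/value outside [0, 1]")
    out = arr.copy()
    out[..., 0] = np.mod(out[..., 0], 1.0)
    return out


def rgb_to_hsv(image: np.ndarray) -> np.ndarray:
    """Convert an RGB raster in [0, 1] to HSV (hexcone model), hue in [0, 1)."""
    arr = validate_rgb(image)
    hsv = _skcolor.rgb2hsv(arr)
    hsv[..., 0] = np.mod(hsv[..., 0], 1.0)
    return hsv


def hsv_to_rgb(image: np.ndarray) -> np.ndarray:
    """Inverse hexcone conversion; output clipped to [0, 1]."""
    arr = validate_hsv(image)
    return np.clip(_skcolor.hsv2rgb(arr), 0.0, 1.0)


def hsv_to_cartesian(hsv: np.ndarray) -> np.ndarray:
    """Embed HSV triplets (..., 3) into the Cartesian cone (x, y, z)."""
    arr = np.asarray(hsv, dtype=float)
    h, s, v = arr[..., 0], arr[..., 1], arr[..., 2]
    ang = _TWO_PI * h
    return np.stack([s * np.cos(ang), s * np.sin(ang), v], axis=-1)


def cartesian_to_hsv(points: np.ndarray, tol: float = 1e-9) -> np.ndarray:
    """Invert :func:`hsv_to_cartesian`.

    Achromatic points (``s == 0``) get hue 0 by convention so the inverse is
    deterministic.  Radii exceeding 1 by more than ``tol`` are a domain error;
    tiny numerical excesses are clamped.
    """
    arr = np.asarray(points, dtype=float)
    x, y, z = arr[..., 0], arr[..., 1], arr[..., 2]
    s = np.hypot(x, y)
    if s.max(initial=0.0) > 1.0 + tol:
        raise ValueError("point outside the HSV cylinder (x^2 + y^2 > 1)")
    s = np.minimum(s, 1.0)
    h = np.mod(np.arctan2(y, x) / _TWO_PI, 1.0)
    h = np.where(s > 0, h, 0.0)
    return np.stack([h, s, z], axis=-1)


def wrap_hue(hsv: np.ndarray, clip_hue: bool = False) -> np.ndarray:
    """Constrain an HSV raster to valid range.

    Hue wraps modulo 1 (it is circular); saturation and value clip to [0, 1].
    ``clip_hue=True`` clips hue instead of wrapping, for callers that want a
    literal all-channel clamp.
    """
    out = np.array(hsv, dtype=float, copy=True)
    if clip_hue:
        out[..., 0] = np.clip(out[..., 0], 0.0, 1.0)
    else:
        out[..., 0] = np.mod(out[..., 0], 1.0)
    out[..., 1:] = np.clip(out[..., 1:], 0.0, 1.0)
    return out


def hue_difference(h: np.ndarray, ref: np.ndarray | float) -> np.ndarray:
    """Signed circular hue difference ``h - ref`` wrapped into [-0.5, 0.5)."""
    return np.mod(np.asarray(h, dtype=float) - ref + 0.5, 1.0) - 0.5


def read_rgb(path) -> np.ndarray:
    """Read an 8-bit PNG/TIFF image as an RGB raster in [0, 1] (alpha dropped)."""
    import imageio.v3 as iio

    raw = np.asarray(iio.imread(path))
    if raw.ndim == 2:
        raw = np.stack([raw] * 3, axis=-1)
    if raw.shape[-1] == 4:
        raw = raw[..., :3]
    if raw.dtype == np.uint8:
        return raw.astype(float) / 255.0
    if raw.dtype == np.uint16:
        return raw.astype(float) / 65535.0
    return validate_rgb(raw)


def write_rgb(path, image: np.ndarray) -> None:
    """Write an RGB raster in [0, 1] as an 8-bit image (PNG/TIFF by extension)."""
    import imageio.v3 as iio

    arr = validate_rgb(image)
    iio.imwrite(path, np.round(arr * 255.0).astype(np.uint8))
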