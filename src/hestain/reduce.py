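"""Color reduction by k-means in Cartesian HSV.

An H&E tile typically needs only a handful of colors to represent its
tissue structures; reducing the image to ``k`` representative colors
(default 10) is the first stage of the normalization pipeline.  Clustering
runs on the Cartesian embedding of HSV so that Euclidean distance — the
k-means objective — respects hue circularity.

The intra/inter-cluster variance ratio is the diagnostic for choosing
``k``: it decreases as ``k`` grows and plateaus once the natural color
divisions of the tissue are resolved.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import KMeans

from .color import cartesian_to_hsv, hsv_to_cartesian, validate_hsv

__all__ = [
    "ClusteredImage",
    "VarianceRatioCurve",
    "reduce_colors",
    "cluster_variance_ratio",
    "variance_curve",
]

log = logging.getLogger(__name__)

#: above this pixel count, k-means runs on a seeded subsample (logged)
SUBSAMPLE_THRESHOLD = 1_000_000


@dataclass
class ClusteredImage:
    """Per-pixel cluster labels plus the k cluster centroid colors.

    Centroids are stored both in Cartesian coordinates (the clustering
    space) and as HSV colors (for display and serialization).
    """

    labels: np.ndarray  # (H, W) int
    centroids_cartesian: np.ndarray  # (k, 3)
    centroids_hsv: np.ndarray = field(init=False)
    k: int = 10
    #: (N, 3) Cartesian source pixels, kept so variance diagnostics can be
    #: computed without the original image; dropped on serialization
    points: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.centroids_hsv = cartesian_to_hsv(self.centroids_cartesian)
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.centroids_cartesian.shape != (self.k, 3):
            raise ValueError("centroid array must have shape (k, 3)")

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape

    def recolored(self) -> np.ndarray:
        """The k-color HSV image: every pixel replaced by its centroid."""
        return self.centroids_hsv[self.labels]

    def member_counts(self) -> np.ndarray:
        return np.bincount(self.labels.ravel(), minlength=self.k)

    def save(self, label_path, meta_path) -> None:
        """Write the label raster (8-bit PNG/TIFF) and centroids/k as JSON."""
        import imageio.v3 as iio

        if self.k > 255:
            raise ValueError("label raster serialization supports k <= 255")
        iio.imwrite(label_path, self.labels.astype(np.uint8))
        meta = {"k": self.k, "centroids_hsv": self.centroids_hsv.tolist()}
        with open(meta_path, "w") as fh:
            json.dump(meta, fh, indent=2)

    @classmethod
    def load(cls, label_path, meta_path) -> "ClusteredImage":
        import imageio.v3 as iio

        labels = np.asarray(iio.imread(label_path)).astype(int)
        with open(meta_path) as fh:
            meta = json.load(fh)
        cart = hsv_to_cartesian(np.asarray(meta["centroids_hsv"], dtype=float))
        return cls(labels=labels, centroids_cartesian=cart, k=int(meta["k"]))


@dataclass
class VarianceRatioCurve:
    """Mean intra/inter-cluster variance ratio as a function of k."""

    entries: list[tuple[int, float]]
    seeds: list[int]

    @property
    def ks(self) -> list[int]:
        return [k for k, _ in self.entries]

    @property
    def ratios(self) -> list[float]:
        return [r for _, r in self.entries]


def _count_distinct_colors(flat: np.ndarray, cap: int) -> int:
    """Number of distinct rows in ``flat``, early-exiting once ``cap`` is reached."""
    # Checking the first few thousand pixels is almost always enough.
    for n in (4096, len(flat)):
        distinct = len(np.unique(flat[:n], axis=0))
        if distinct >= cap:
            return distinct
    return distinct


def reduce_colors(
    image: np.ndarray,
    k: int = 10,
    seed: int = 0,
    n_init: int = 10,
    max_iter: int = 300,
) -> ClusteredImage:
    """Cluster an HSV image into ``k`` representative colors.

    k-means runs on the Cartesian embedding with k-means++ seeding,
    ``n_init`` restarts (best objective kept) and at most ``max_iter``
    Lloyd iterations per restart.  Deterministic for a fixed ``seed``.

    Raises a ``ValueError`` when ``k`` exceeds the number of distinct
    pixel colors (the clustering would be degenerate).
    """
    hsv = validate_hsv(image)
    if k < 1:
        raise ValueError("k must be >= 1")
    points = hsv_to_cartesian(hsv).reshape(-1, 3)
    if _count_distinct_colors(points, k) < k:
        raise ValueError(f"k={k} exceeds the number of distinct pixel colors")

    fit_points = points
    if len(points) > SUBSAMPLE_THRESHOLD:
        rng = np.random.default_rng(seed)
        idx = rng.choice(len(points), SUBSAMPLE_THRESHOLD, replace=False)
        fit_points = points[idx]
        log.info("k-means subsampling active: %d of %d pixels", len(fit_points), len(points))

    km = KMeans(
        n_clusters=k,
        init="k-means++",
        n_init=n_init,
        max_iter=max_iter,
        tol=1e-6,
        random_state=seed,
    ).fit(fit_points)
    labels = km.predict(points) if fit_points is not points else km.labels_
    return ClusteredImage(
        labels=labels.reshape(hsv.shape[:2]),
        centroids_cartesian=km.cluster_centers_,
        k=k,
        points=points,
    )


def cluster_variance_ratio(clustered: ClusteredImage, points: np.ndarray | None = None) -> float:
    """Mean over clusters of intra-cluster / inter-cluster variance.

    For each cluster: intra-variance is the mean squared Cartesian distance
    of its member pixels to the centroid; inter-variance is the mean squared
    distance from that centroid to the other ``k - 1`` centroids.  Empty
    clusters are excluded with a warning.

    ``points`` may supply the (N, 3) Cartesian pixel matrix explicitly;
    otherwise the source pixels retained on the ``ClusteredImage`` are used.
    """
    if clustered.k < 2:
        raise ValueError("variance ratio requires k >= 2")
    if points is None:
        points = clustered.points
    if points is None:
        raise ValueError(
            "source pixels unavailable (deserialized ClusteredImage); pass points="
        )
    labels = clustered.labels.ravel()
    centroids = clustered.centroids_cartesian
    ratios = []
    for c in range(clustered.k):
        members = points[labels == c]
        if len(members) == 0:
            warnings.warn(f"cluster {c} is empty; excluded from variance ratio")
            continue
        intra = float(np.mean(np.sum((members - centroids[c]) ** 2, axis=1)))
        others = np.delete(centroids, c, axis=0)
        inter = float(np.mean(np.sum((others - centroids[c]) ** 2, axis=1)))
        ratios.append(intra / inter)
    if not ratios:
        raise ValueError("no nonempty clusters")
    return float(np.mean(ratios))


def variance_curve(
    image: np.ndarray,
    ks: list[int],
    seeds: list[int] | None = None,
) -> VarianceRatioCurve:
    """Evaluate the intra/inter variance ratio across cluster counts.

    Per ``k`` the ratio is averaged over the k-means ``seeds``
    (default: the single seed 0); entries are returned ordered by ``k``.
    """
    if seeds is None:
        seeds = [0]
    if any(k < 2 for k in ks):
        raise ValueError("variance curve requires all k >= 2")
    hsv = validate_hsv(image)
    points = hsv_to_cartesian(hsv).reshape(-1, 3)
    entries = []
    for k in sorted(ks):
        vals = []
        for seed in seeds:
            clustered = reduce_colors(hsv, k=k, seed=seed)
            vals.append(cluster_variance_ratio(clustered, points=points))
        entries.append((k, float(np.mean(vals))))
    return VarianceRatioCurve(entries=entries, seeds=list(seeds))
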