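"""Linear-SVM decision-tree cascade over Cartesian HSV.

Three binary soft-margin linear SVMs, arranged as a decision tree, carry a
pixel from color to tissue class:

    stage 1:  white space  vs  tissue (stroma + nuclei + cytoplasm)
    stage 2:  stroma       vs  epithelial tissue (nuclei + cytoplasm)
    stage 3:  nuclei       vs  cytoplasm

Every stage keeps its hyperplane ``(w, b)`` and reports *geometric* signed
distances ``(w . x + b) / ||w||``, so certainty values are comparable
across stages and invariant to rescaling of ``w``.  The classification of
a pixel comes with a four-channel certainty stack: the winning class
channel holds the (positive) distance to the hyperplane that decided the
class; each losing channel holds minus the distance to the hyperplane at
which that class's branch was rejected.  Exactly one channel is positive
per pixel (zero on a hyperplane), and negative values flag classes the
pixel is unlikely to belong to.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.svm import SVC

from .assign import TissueClass, TrainingSet
from .color import hsv_to_cartesian, validate_hsv

__all__ = [
    "LinearStage",
    "CascadeClassifier",
    "ClassifiedImage",
    "train_cascade",
    "classify_image",
    "render_certainty",
]

#: stage -> (positive class/branch, negative branch members)
_STAGE_SPLITS = (
    (TissueClass.WHITE, (TissueClass.STROMA, TissueClass.NUCLEI, TissueClass.CYTOPLASM)),
    (TissueClass.STROMA, (TissueClass.NUCLEI, TissueClass.CYTOPLASM)),
    (TissueClass.NUCLEI, (TissueClass.CYTOPLASM,)),
)


@dataclass
class LinearStage:
    """One hyperplane of the cascade, with its distance normalizer."""

    w: np.ndarray  # (3,)
    b: float
    norm: float

    def signed_distance(self, X: np.ndarray) -> np.ndarray:
        """Geometric signed distance; positive = the stage's first-named class."""
        return (X @ self.w + self.b) / self.norm


@dataclass
class CascadeClassifier:
    """The three trained stages plus the soft-margin box constraint used."""

    stages: tuple[LinearStage, LinearStage, LinearStage]
    C: float = 1.0


def _fit_stage(
    X: np.ndarray,
    y_binary: np.ndarray,
    C: float,
    max_train: int | None,
    rng: np.random.Generator,
) -> LinearStage:
    pos = int(np.sum(y_binary == 1))
    neg = int(np.sum(y_binary == -1))
    if pos == 0 or neg == 0:
        raise ValueError("cascade stage has a single-class training set")
    if max_train is not None and len(y_binary) > max_train:
        # stratified seeded subsample; keeps at least one point per side
        keep = np.zeros(len(y_binary), dtype=bool)
        for side in (1, -1):
            idx = np.flatnonzero(y_binary == side)
            n_side = max(1, int(round(max_train * len(idx) / len(y_binary))))
            keep[rng.choice(idx, min(n_side, len(idx)), replace=False)] = True
        X, y_binary = X[keep], y_binary[keep]
    svc = SVC(kernel="linear", C=C)
    svc.fit(X, y_binary)
    w = svc.coef_[0].astype(float)
    b = float(svc.intercept_[0])
    return LinearStage(w=w, b=b, norm=float(np.linalg.norm(w)))


def train_cascade(
    training: TrainingSet,
    C: float = 1.0,
    max_train_per_stage: int | None = 10_000,
    seed: int = 0,
) -> CascadeClassifier:
    """Fit the three-stage cascade on a labeled training set.

    Parameters
    ----------
    training
        Labeled Cartesian color points; all four classes must be present.
    C
        Soft-margin box constraint shared by the three SVMs (default 1).
    max_train_per_stage
        Cap on points fed to each SVM fit; beyond it a seeded stratified
        subsample is used.  ``None`` disables subsampling.
    """
    if C <= 0:
        raise ValueError("box constraint C must be positive")
    rng = np.random.default_rng(seed)
    stages = []
    X, y = training.X, training.y
    for pos_class, neg_classes in _STAGE_SPLITS:
        neg_codes = [int(c) for c in neg_classes]
        mask = (y == int(pos_class)) | np.isin(y, neg_codes)
        yb = np.where(y[mask] == int(pos_class), 1, -1)
        stages.append(_fit_stage(X[mask], yb, C, max_train_per_stage, rng))
    return CascadeClassifier(stages=tuple(stages), C=C)


@dataclass
class ClassifiedImage:
    """Per-pixel tissue class plus the four-channel certainty stack."""

    class_map: np.ndarray  # (H, W) TissueClass codes
    certainty: np.ndarray  # (H, W, 4) signed geometric distances

    @property
    def shape(self) -> tuple[int, int]:
        return self.class_map.shape

    def deciding_distance(self) -> np.ndarray:
        """Distance to the hyperplane that decided each pixel (>= 0)."""
        return np.take_along_axis(
            self.certainty, self.class_map[..., None], axis=-1
        )[..., 0]

    def mask(self, cls: TissueClass) -> np.ndarray:
        return self.class_map == int(cls)


def classify_image(cascade: CascadeClassifier, image: np.ndarray) -> ClassifiedImage:
    """Route every pixel through the decision tree.

    Ties at distance exactly 0 go to the stage's positive (first-named)
    branch, so the routing is deterministic.
    """
    hsv = validate_hsv(image)
    shape = hsv.shape[:2]
    X = hsv_to_cartesian(hsv).reshape(-1, 3)
    s1, s2, s3 = (stage.signed_distance(X) for stage in cascade.stages)

    white = s1 >= 0
    stroma = ~white & (s2 >= 0)
    epithelial = ~white & ~stroma
    nuclei = epithelial & (s3 >= 0)
    cyto = epithelial & ~nuclei

    class_map = np.empty(len(X), dtype=np.int64)
    class_map[white] = TissueClass.WHITE
    class_map[stroma] = TissueClass.STROMA
    class_map[nuclei] = TissueClass.NUCLEI
    class_map[cyto] = TissueClass.CYTOPLASM

    cert = np.empty((len(X), 4), dtype=float)
    # WHITE channel: deciding distance for white pixels (+s1); branch
    # rejected at stage 1 for everyone else (s1 < 0 there, i.e. -|s1|).
    cert[:, TissueClass.WHITE] = s1
    # STROMA: rejected at stage 1 for white pixels, else stage-2 distance.
    cert[:, TissueClass.STROMA] = np.where(white, -s1, s2)
    # NUCLEI: stage-1 rejection for white, stage-2 rejection for stroma,
    # else the deciding stage-3 distance.
    cert[:, TissueClass.NUCLEI] = np.where(white, -s1, np.where(stroma, -s2, s3))
    # CYTOPLASM: as nuclei but on the negative side of stage 3.
    cert[:, TissueClass.CYTOPLASM] = np.where(white, -s1, np.where(stroma, -s2, -s3))

    return ClassifiedImage(
        class_map=class_map.reshape(shape),
        certainty=cert.reshape(shape + (4,)),
    )


def render_certainty(classified: ClassifiedImage) -> np.ndarray:
    """Per-class certainty images for visualization.

    Returns an (H, W, 4) stack: within each class mask, the magnitude of
    the deciding distance scaled to [0, 1] by that channel's maximum; zero
    outside the class.
    """
    out = np.zeros_like(classified.certainty)
    for cls in TissueClass:
        mask = classified.mask(cls)
        vals = np.where(mask, np.abs(classified.certainty[..., int(cls)]), 0.0)
        peak = vals.max()
        if peak > 0:
            out[..., int(cls)] = vals / peak
        else:
            out[..., int(cls)] = vals
    if out.max() == 0:
        warnings.warn("all certainty values are zero")
    return out
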