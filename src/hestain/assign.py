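"""Associating reduced colors with tissue structures.

Each of the k cluster colors is mapped to one of four tissue elements —
white space/lumen, stroma, nuclei, or cytoplasm — or left unassigned when
the color is shared by several elements.  Assigned clusters supply the
labeled training pixels for the SVM cascade.

Assignments come from a JSON file (``load_assignment``) or, when ground
truth is available (synthetic tiles), from majority-vote purity
(``auto_assign``).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from enum import IntEnum

import numpy as np

from .reduce import ClusteredImage

__all__ = [
    "TissueClass",
    "UNASSIGNED",
    "ColorAssignment",
    "TrainingSet",
    "load_assignment",
    "build_training_set",
    "auto_assign",
]


class TissueClass(IntEnum):
    """The four tissue elements, in cascade order."""

    WHITE = 0  # white space / lumen
    STROMA = 1
    NUCLEI = 2
    CYTOPLASM = 3


#: sentinel for clusters whose color mixes tissue elements
UNASSIGNED = None

_NAME_TO_CLASS = {
    "white": TissueClass.WHITE,
    "stroma": TissueClass.STROMA,
    "nuclei": TissueClass.NUCLEI,
    "cytoplasm": TissueClass.CYTOPLASM,
}
_CLASS_TO_NAME = {v: k for k, v in _NAME_TO_CLASS.items()}


@dataclass
class ColorAssignment:
    """Mapping from cluster id to a :class:`TissueClass` (or ``None``).

    Valid assignments cover every cluster id in ``{0..k-1}`` and give each
    of the four tissue classes at least one cluster (the cascade needs
    training pixels on every side of every split).
    """

    mapping: dict[int, TissueClass | None]
    k: int

    def __post_init__(self) -> None:
        missing = sorted(set(range(self.k)) - set(self.mapping))
        extra = sorted(set(self.mapping) - set(range(self.k)))
        if missing:
            raise ValueError(f"assignment missing cluster ids: {missing}")
        if extra:
            raise ValueError(f"assignment has unknown cluster ids: {extra}")
        assigned = {c for c in self.mapping.values() if c is not None}
        for cls in TissueClass:
            if cls not in assigned:
                raise ValueError(
                    f"class {_CLASS_TO_NAME[cls]} has no assigned cluster"
                )

    def clusters_for(self, cls: TissueClass) -> list[int]:
        return [cid for cid, c in self.mapping.items() if c == cls]

    def to_dict(self) -> dict:
        return {
            "k": self.k,
            "assignment": {
                str(cid): (_CLASS_TO_NAME[c] if c is not None else "unassigned")
                for cid, c in sorted(self.mapping.items())
            },
        }

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


@dataclass
class TrainingSet:
    """Labeled Cartesian color points for cascade training."""

    X: np.ndarray  # (N, 3) Cartesian HSV points
    y: np.ndarray  # (N,) TissueClass codes

    def __len__(self) -> int:
        return len(self.y)

    @property
    def class_counts(self) -> dict[TissueClass, int]:
        return {cls: int(np.sum(self.y == cls)) for cls in TissueClass}


def load_assignment(path) -> ColorAssignment:
    """Read and validate a cluster-to-class assignment JSON file.

    Schema: ``{"k": int, "assignment": {"<cluster_id>": "white|stroma|
    nuclei|cytoplasm|unassigned"}}``.
    """
    with open(path) as fh:
        data = json.load(fh)
    if "k" not in data or "assignment" not in data:
        raise ValueError("assignment file must contain 'k' and 'assignment'")
    k = int(data["k"])
    mapping: dict[int, TissueClass | None] = {}
    unknown = []
    for key, name in data["assignment"].items():
        cid = int(key)
        name = str(name).lower()
        if name == "unassigned":
            mapping[cid] = None
        elif name in _NAME_TO_CLASS:
            mapping[cid] = _NAME_TO_CLASS[name]
        else:
            unknown.append((cid, name))
    if unknown:
        raise ValueError(f"unknown class names in assignment: {unknown}")
    return ColorAssignment(mapping=mapping, k=k)


def build_training_set(
    clustered: ClusteredImage, assignment: ColorAssignment
) -> TrainingSet:
    """Turn every pixel of every assigned cluster into a labeled training point.

    Unassigned clusters contribute nothing; the result must contain at least
    one point per tissue class.
    """
    if assignment.k != clustered.k:
        raise ValueError(
            f"assignment is for k={assignment.k} but image has k={clustered.k}"
        )
    if clustered.points is None:
        raise ValueError("ClusteredImage lacks source pixels")
    labels = clustered.labels.ravel()
    # cluster id -> class code, -1 for unassigned
    lut = np.full(clustered.k, -1, dtype=int)
    for cid, cls in assignment.mapping.items():
        if cls is not None:
            lut[cid] = int(cls)
    y = lut[labels]
    mask = y >= 0
    X = clustered.points[mask]
    y = y[mask]
    for cls in TissueClass:
        if not np.any(y == cls):
            raise ValueError(f"no training pixels for class {_CLASS_TO_NAME[cls]}")
    return TrainingSet(X=X, y=y)


def auto_assign(
    clustered: ClusteredImage,
    truth_labels: np.ndarray,
    purity_threshold: float = 0.9,
) -> ColorAssignment:
    """Assign clusters from a ground-truth label raster by majority purity.

    A cluster is assigned to a tissue class when at least
    ``purity_threshold`` of its pixels carry that class in ``truth_labels``;
    otherwise it is left unassigned, mirroring a human who only labels
    colors that clearly belong to a single element.
    """
    if not (0.5 < purity_threshold <= 1.0):
        raise ValueError("purity_threshold must be in (0.5, 1]")
    truth = np.asarray(truth_labels)
    if truth.shape != clustered.labels.shape:
        raise ValueError("truth raster shape does not match cluster labels")
    mapping: dict[int, TissueClass | None] = {}
    flat_clusters = clustered.labels.ravel()
    flat_truth = truth.ravel()
    for cid in range(clustered.k):
        member_truth = flat_truth[flat_clusters == cid]
        if len(member_truth) == 0:
            mapping[cid] = None
            continue
        counts = np.bincount(member_truth, minlength=len(TissueClass))
        modal = int(np.argmax(counts))
        if counts[modal] / len(member_truth) >= purity_threshold:
            mapping[cid] = TissueClass(modal)
        else:
            mapping[cid] = None
    try:
        return ColorAssignment(mapping=mapping, k=clustered.k)
    except ValueError as exc:
        raise ValueError(
            f"{exc}; consider lowering purity_threshold (got {purity_threshold})"
        ) from exc
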