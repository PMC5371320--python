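"""End-to-end orchestration: reduce -> assign -> train -> classify -> normalize.

Single-image and cohort drivers used by the CLI and by evaluation runs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .assign import ColorAssignment, TrainingSet, auto_assign, build_training_set
from .classify import CascadeClassifier, ClassifiedImage, classify_image, train_cascade
from .color import rgb_to_hsv
from .normalize import TargetColors, derive_targets, normalize_image, structure_means
from .reduce import ClusteredImage, reduce_colors

__all__ = ["PipelineResult", "run_pipeline", "normalize_cohort"]


@dataclass
class PipelineResult:
    """Everything produced for one image by the full pipeline."""

    hsv: np.ndarray
    clustered: ClusteredImage
    assignment: ColorAssignment
    training: TrainingSet
    cascade: CascadeClassifier
    classified: ClassifiedImage
    normalized: np.ndarray | None = None  # HSV; set when targets were given

    def structure_means(self):
        return structure_means(self.hsv, self.classified)


def run_pipeline(
    rgb: np.ndarray,
    k: int = 10,
    C: float = 1.0,
    seed: int = 0,
    assignment: ColorAssignment | None = None,
    truth_labels: np.ndarray | None = None,
    purity_threshold: float = 0.9,
    targets: TargetColors | None = None,
    clip_hue: bool = False,
    max_train_per_stage: int | None = 10_000,
) -> PipelineResult:
    """Run the full pipeline on one RGB tile.

    The cluster-to-structure assignment comes either from an explicit
    :class:`ColorAssignment` or, when ground-truth labels are available
    (synthetic tiles), from purity-based auto-assignment.  When
    ``targets`` is given the normalized image is produced as well.
    """
    if assignment is None and truth_labels is None:
        raise ValueError("need either an assignment or truth labels")
    hsv = rgb_to_hsv(rgb)
    clustered = reduce_colors(hsv, k=k, seed=seed)
    if assignment is None:
        assignment = auto_assign(clustered, truth_labels, purity_threshold)
    training = build_training_set(clustered, assignment)
    cascade = train_cascade(
        training, C=C, max_train_per_stage=max_train_per_stage, seed=seed
    )
    classified = classify_image(cascade, hsv)
    normalized = None
    if targets is not None:
        normalized = normalize_image(hsv, classified, targets, clip_hue=clip_hue)
    return PipelineResult(
        hsv=hsv,
        clustered=clustered,
        assignment=assignment,
        training=training,
        cascade=cascade,
        classified=classified,
        normalized=normalized,
    )


def normalize_cohort(
    images: list[np.ndarray],
    truth_labels: list[np.ndarray] | None = None,
    assignments: list[ColorAssignment] | None = None,
    targets: TargetColors | None = None,
    k: int = 10,
    C: float = 1.0,
    seed: int = 0,
    purity_threshold: float = 0.9,
) -> tuple[list[PipelineResult], TargetColors]:
    """Classify a cohort, derive shared targets, and normalize every image.

    When ``targets`` is None the targets are the cohort's own mean
    structure colors (per-image means averaged across images), mirroring
    the derivation of a standard palette from a reference image set.
    """
    n = len(images)
    results = []
    for i in range(n):
        results.append(
            run_pipeline(
                images[i],
                k=k,
                C=C,
                seed=seed + i,
                assignment=assignments[i] if assignments else None,
                truth_labels=truth_labels[i] if truth_labels else None,
                purity_threshold=purity_threshold,
            )
        )
    if targets is None:
        targets = derive_targets([(r.hsv, r.classified) for r in results])
    for r in results:
        r.normalized = normalize_image(r.hsv, r.classified, targets)
    return results, targets
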