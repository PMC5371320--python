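"""Shared fixtures: synthetic tiles and pipeline runs reused across tests."""

from __future__ import annotations

import numpy as np
import pytest

import hestain as hs
from hestain.classify import ClassifiedImage


@pytest.fixture(scope="session")
def tile():
    """One 128x128 synthetic tile with a mild stain shift: (rgb, truth, profile)."""
    layout = hs.generate_layout((128, 128), seed=101)
    profile = hs.StainProfile(shift=(0.02, -0.03, 0.015), sigma=0.02)
    rgb, truth = hs.render_tile(layout, profile, seed=102)
    return rgb, truth, profile


@pytest.fixture(scope="session")
def pipeline_result(tile):
    """Full pipeline (k=10, C=1, auto-assignment) on the shared tile."""
    rgb, truth, _ = tile
    return hs.run_pipeline(rgb, k=10, C=1.0, seed=103, truth_labels=truth)


@pytest.fixture(scope="session")
def small_cohort():
    """Five 128x128 tiles with inter-image stain drift: list of (rgb, truth, profile)."""
    spec = hs.CohortSpec(
        n_images=5, shape=(128, 128), sigma_shift=0.05, sigma=0.02, seed=201
    )
    return hs.generate_cohort(spec)


@pytest.fixture(scope="session")
def normalized_cohort(small_cohort):
    """Pipeline results + cohort-derived targets for the small cohort."""
    results, targets = hs.normalize_cohort(
        [c[0] for c in small_cohort],
        truth_labels=[c[1] for c in small_cohort],
        seed=202,
    )
    return results, targets


def make_classified(class_map: np.ndarray) -> ClassifiedImage:
    """A ClassifiedImage with the given class raster and dummy certainty."""
    cm = np.asarray(class_map, dtype=np.int64)
    return ClassifiedImage(class_map=cm, certainty=np.zeros(cm.shape + (4,)))
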