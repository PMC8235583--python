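"""Shared fixtures: small simulated protocols and datasets.

Heavy simulated datasets are session-scoped so the whole suite pays for
them once.  All sizes are deliberately scaled down from the full
21-subject / 5-minute protocol; the structure (6 bouts, 3 views, 3
activities) is unchanged.
"""

from __future__ import annotations

import numpy as np
import pytest

import kinemet as km
from kinemet.harness import ViewDataset, build_datasets


@pytest.fixture(scope="session")
def subject() -> km.SubjectProfile:
    return km.SubjectProfile(subject_id="T000", sex="female", age=22.0, weight=60.0, body_fat=21.0)


@pytest.fixture()
def walk_bout() -> km.ActivityBout:
    return km.ActivityBout("walking", 4.8, duration=0.5)


@pytest.fixture()
def side_view() -> km.CameraView:
    return km.CANONICAL_VIEWS[0]


@pytest.fixture()
def noiseless_params() -> km.MotionParams:
    return km.MotionParams(sway_sd=0.0, drift_amplitude=0.0, sensor_noise_sd=0.0)


@pytest.fixture(scope="session")
def small_protocol() -> km.Protocol:
    """4 subjects, 1.5-minute bouts, full 6-bout / 3-view structure."""
    return km.Protocol().scaled(n_subjects=4, duration=1.5)


@pytest.fixture(scope="session")
def datasets(small_protocol) -> dict[str, ViewDataset]:
    """Preprocessed per-view feature datasets of the small protocol."""
    return build_datasets(small_protocol, seed=0, discard_min=0.4, keep_min=1.0)


@pytest.fixture(scope="session")
def side_dataset(datasets) -> ViewDataset:
    """12k stratified rows of the side view (the SVM-accuracy regime)."""
    return datasets["side"].subsample(12000, seed=0)


@pytest.fixture(scope="session")
def regression_split(datasets):
    """A fixed train/test split of 6000 side-view rows for regression tests."""
    ds = datasets["side"].subsample(6000, seed=0)
    rng = np.random.default_rng(7)
    perm = rng.permutation(len(ds))
    n_test = len(ds) // 5
    test, train = perm[:n_test], perm[n_test:]
    return ds, train, test
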