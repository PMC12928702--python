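"""Shared fixtures: a small but accurate membrane-profile classifier and
reusable synthetic inputs, generated once per session."""

import numpy as np
import pytest

from scstrain import cryoem, synthetic


@pytest.fixture(scope="session")
def small_classifier():
    """MLP trained on a reduced profile dataset; accurate enough (>98%) for
    segmentation tests while keeping the suite fast."""
    ds = cryoem.make_training_set(n_pos=3000, n_neg=18000, seed=1234)
    clf, acc = cryoem.train_classifier(ds, seed=1234)
    assert acc > 0.95
    return clf


@pytest.fixture(scope="session")
def flat_bilayer_frames():
    spec = synthetic.DeformationSpec(
        box_x=20.0, box_y=20.0, n_lipids_per_leaflet=800, noise_sd=0.05, seed=11
    )
    return synthetic.make_membrane_frames(spec, 10)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)
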