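"""Shared fixtures.

The expensive fixtures (trained models on the standard phantom cohort) are
session-scoped and only built when a test actually requests them, so the
light unit tests stay fast.
"""

from __future__ import annotations

import numpy as np
import pytest

from brainacn.model import ACNConfig, build_model
from brainacn.phantom import PhantomConfig, generate_cohort
from brainacn import training as tr

FIXTURE_GRID = (32, 40, 32)
EFFICACY_SEEDS = (0, 1, 2)


def stack(volumes):
    return np.stack([v.voxels for v in volumes])


@pytest.fixture(scope="session")
def fixture_cohort():
    """The standard training cohort: n=600, 2 sites, 2 genders, seed 0."""
    vols, subs = generate_cohort(PhantomConfig(n_subjects=600, seed=0))
    return stack(vols), subs


@pytest.fixture(scope="session")
def heldout_cohort():
    """An independent evaluation cohort from the same distribution."""
    vols, subs = generate_cohort(PhantomConfig(n_subjects=200, seed=100))
    return stack(vols), subs


@pytest.fixture(scope="session")
def adversarial_models(fixture_cohort):
    """Full ACN trained on the standard cohort, one model per seed."""
    x, subs = fixture_cohort
    models = {}
    for seed in EFFICACY_SEEDS:
        model = build_model(ACNConfig.phantom_profile(), FIXTURE_GRID, seed=seed)
        model, _ = tr.train(model, x, subs, seed=seed)
        models[seed] = model
    return models


@pytest.fixture(scope="session")
def baseline_models(fixture_cohort):
    """Same backbone without mixed modules (no adversarial confound removal)."""
    x, subs = fixture_cohort
    models = {}
    for seed in EFFICACY_SEEDS:
        model = build_model(
            ACNConfig.phantom_profile(confound_factors=()), FIXTURE_GRID, seed=seed
        )
        model, _ = tr.train(model, x, subs, seed=seed)
        models[seed] = model
    return models


@pytest.fixture(scope="session")
def tiny_trained_model():
    """A small, quickly trained model for prediction/checkpoint tests."""
    cfg = PhantomConfig(n_subjects=48, grid_shape=(16, 16, 16), seed=3)
    vols, subs = generate_cohort(cfg)
    model = build_model(
        ACNConfig.phantom_profile(channels_per_block=(2, 2, 4), embedding_dim=6, epochs=3),
        (16, 16, 16),
        seed=0,
    )
    model, history = tr.train(model, stack(vols), subs, seed=0)
    return model, stack(vols), subs, history
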