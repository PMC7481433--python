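"""Shared fixtures.

Heavy artifacts (a small trained classifier, the end-to-end phantom runs)
are session-scoped so the expensive training happens once per test run.
"""

from __future__ import annotations

import numpy as np
import pytest

from ggnav.phantom import PhantomSpec, generate_cohort
from ggnav.pipeline import run_pipeline
from ggnav.slice_classifier import TrainConfig, train_classifier


@pytest.fixture(scope="session")
def small_spec() -> PhantomSpec:
    """Compact phantom spec used by fast unit tests."""
    return PhantomSpec(n_patients=6, image_size=200, signal_separation=2.0,
                       seed=11)


@pytest.fixture(scope="session")
def small_cohort(small_spec):
    stacks, manifest = generate_cohort(small_spec)
    return stacks, manifest


@pytest.fixture(scope="session")
def trained_classifier():
    """Classifier trained on a small high-separation phantom cohort."""
    train = generate_cohort(PhantomSpec(n_patients=12, image_size=200,
                                        signal_separation=2.0, seed=21))[0]
    val = generate_cohort(PhantomSpec(n_patients=6, image_size=200,
                                      signal_separation=2.0, seed=22))[0]
    clf, history = train_classifier(train, val, TrainConfig(seed=5))
    return clf, history, train, val


@pytest.fixture(scope="session")
def e2e_runs():
    """Three seeded end-to-end runs at the standard benchmark size
    (60 train / 20 test phantoms, signal separation 2)."""
    return {seed: run_pipeline(seed=seed) for seed in (1, 2, 3)}


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
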