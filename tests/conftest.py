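"""Shared fixtures: desk-scale datasets and trained detectors.

The heavyweight fixtures are session-scoped and lazy, so unit-test-only
selections never pay for dataset generation.  Desk scale means 64^2 lattices
with 2500 attempted flips per snapshot (the same 0.61 sweeps/snapshot rate as
10^4 flips on a 128^2 lattice), 200 runs per class, and at most 50 training
epochs.
"""

from __future__ import annotations

import warnings
from typing import NamedTuple

import numpy as np
import pytest

from latticeews.indicators import featurize_dataset
from latticeews.lattice import generate_ising_dataset
from latticeews.network import CNNLSTMClassifier, TrainingConfig
from latticeews.pipeline import train_test_split_runs
from latticeews.systems import generate_percolation_dataset, generate_vegetation_dataset

DESK = dict(side_length=64, flips_per_snapshot=2500)
RUNS_PER_CLASS = 200
FEAT_SEED = 5


def _make_ising(order: str, seed: int):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return generate_ising_dataset(
            order, RUNS_PER_CLASS, RUNS_PER_CLASS, seed=seed, **DESK
        )


@pytest.fixture(scope="session")
def ising_second():
    """Desk-scale second-order (temperature-ramp) Ising dataset."""
    return _make_ising("second", seed=101)


@pytest.fixture(scope="session")
def ising_first():
    """Desk-scale first-order (field-ramp) Ising dataset."""
    return _make_ising("first", seed=102)


class TrainedStack(NamedTuple):
    model: CNNLSTMClassifier
    test_features: object
    test_runs: list
    train_features: object


def _train_full(runs):
    train_runs, test_runs = train_test_split_runs(runs, 0.1, seed=7)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        train_features = featurize_dataset(train_runs, lead=100, seed=FEAT_SEED)
        test_features = featurize_dataset(test_runs, lead=0, seed=FEAT_SEED)
    model = CNNLSTMClassifier(seed=0)
    model.fit(
        train_features.X,
        train_features.y,
        TrainingConfig(max_epochs=50, patience=8, seed=0),
    )
    return TrainedStack(model, test_features, test_runs, train_features)


@pytest.fixture(scope="session")
def trained_second(ising_second):
    """Full-channel detector trained on second-order runs, with its held-out
    test features (lead 0), test runs and training features."""
    return _train_full(ising_second)


@pytest.fixture(scope="session")
def trained_first(ising_first):
    return _train_full(ising_first)


@pytest.fixture(scope="session")
def vegetation_runs():
    """Out-of-sample desertification runs (50 transition + 50 null)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return generate_vegetation_dataset(50, 50, seed=201)


@pytest.fixture(scope="session")
def percolation_runs():
    """Out-of-sample site-percolation runs (50 transition + 50 null)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return generate_percolation_dataset(50, 50, seed=202)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
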