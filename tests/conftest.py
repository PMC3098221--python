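"""Shared fixtures: small synthetic datasets generated at test time."""

from __future__ import annotations

import numpy as np
import pytest

from msuaflow import pipeline, synthdata
from msuaflow.preprocess import UNLABELED


def small_schedule():
    """A shortened trial (~20 s) for fast unit tests."""
    return [
        (UNLABELED, 2.0),
        ("train_choice", 2.0),
        ("train_reward", 1.0),
        (UNLABELED, 2.0),
        ("train_choice", 2.0),
        ("train_reward", 1.0),
        (UNLABELED, 1.0),
        ("delay", 10.0),
        ("test_choice", 2.0),
        ("test_reward", 1.0),
        (UNLABELED, 2.0),
        ("test_choice", 2.0),
        ("test_reward", 1.0),
        (UNLABELED, 1.0),
    ]


@pytest.fixture(scope="session")
def small_params():
    return synthdata.SynthParams(
        n_units=8, n_trials=4, epoch_schedule=small_schedule(), seed=11
    )


@pytest.fixture(scope="session")
def small_dataset(small_params):
    return synthdata.generate_dataset(small_params)


@pytest.fixture(scope="session")
def small_prepared(small_dataset):
    return pipeline.prepare(small_dataset)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
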