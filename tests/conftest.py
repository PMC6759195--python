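"""Shared fixtures: toy network, ground truth, and the (expensive)
noise-free multi-start kinetic fit reused across tests."""

import warnings

import numpy as np
import pytest

from kfitlab.elementary import decompose
from kfitlab.synth import (
    ToySpec,
    make_toy_network,
    sample_ground_truth,
    simulate_dataset,
)

warnings.filterwarnings("ignore", category=RuntimeWarning)


@pytest.fixture(scope="session")
def toy_model():
    return make_toy_network(ToySpec(seed=1))


@pytest.fixture(scope="session")
def toy_net(toy_model):
    return decompose(toy_model)


@pytest.fixture(scope="session")
def toy_truth(toy_model, toy_net):
    return sample_ground_truth(toy_model, seed=3, net=toy_net)


@pytest.fixture(scope="session")
def noise_free_training(toy_model, toy_truth):
    train, _ = simulate_dataset(toy_model, toy_truth, noise_cv=0.0, seed=0)
    return train


@pytest.fixture(scope="session")
def kinetic_fit_results(toy_model, toy_net, noise_free_training):
    """Best-of-20 multi-start fit on noise-free synthetic training data."""
    from kfitlab.kinetic import KineticModel

    km = KineticModel(toy_model, noise_free_training, net=toy_net)
    return km.fit(n_starts=20, seed=7)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2026)
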