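import numpy as np
import pytest

from memdecode.decoder import DecoderConfig, fit_ensemble
from memdecode.synthesize import SimConfig, sample_intensities, simulate_trials

# Desk-scale conditions: 20 neurons (12 CA3 / 8 CA1), 150 trials,
# 2 s window, 10 ms bins — a typical recording session at desk cost.
DESK_SIM = SimConfig(seed=7)

# Desk-scale decoder settings used by the heavier pipeline tests: a
# four-rung resolution ladder of compact-support (piecewise-constant)
# bases, 10 bagging replicas, 8-point penalty grid, 5x3 nested CV.
DESK_DECODER = DecoderConfig(
    knot_ladder=(7, 15, 31, 63),
    order=1,
    n_replicas=10,
    n_lambda=8,
    lambda_min=1e-3,
    outer_folds=5,
    inner_folds=3,
    tol=1e-6,
    max_iter=2000,
    seed=0,
)

# Tiny configuration for fast structural tests of the full pipeline.
TINY_SIM = SimConfig(n_neurons=8, n_trials=60, seed=3)
TINY_DECODER = DecoderConfig(
    knot_ladder=(3, 7),
    order=1,
    n_replicas=2,
    n_lambda=5,
    lambda_min=1e-3,
    outer_folds=3,
    inner_folds=2,
    tol=1e-6,
    max_iter=2000,
    seed=0,
)


@pytest.fixture(scope="session")
def desk_dataset():
    intensities = sample_intensities(DESK_SIM)
    tensor, labels = simulate_trials(intensities, DESK_SIM)
    return intensities, tensor, labels


@pytest.fixture(scope="session")
def desk_decoder(desk_dataset):
    _, tensor, labels = desk_dataset
    return fit_ensemble(tensor, labels, DESK_DECODER)


@pytest.fixture(scope="session")
def tiny_dataset():
    intensities = sample_intensities(TINY_SIM)
    tensor, labels = simulate_trials(intensities, TINY_SIM)
    return intensities, tensor, labels


@pytest.fixture(scope="session")
def tiny_decoder(tiny_dataset):
    _, tensor, labels = tiny_dataset
    return fit_ensemble(tensor, labels, TINY_DECODER)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
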