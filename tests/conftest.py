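import numpy as np
import pytest

import pcptox as p
from pcptox.inhibition import inhibition_to_frame
from pcptox.kinetics import slopes_to_frame


@pytest.fixture(scope="session")
def calib():
    return p.calibrate_generator()


@pytest.fixture(scope="session")
def training_design():
    return p.enumerate_training_design()


@pytest.fixture(scope="session")
def validation_design():
    return p.enumerate_validation_design()


@pytest.fixture(scope="session")
def noisy_training(calib, training_design):
    """One seeded noisy training dataset shared across tests (648 traces)."""
    return p.simulate_study(training_design, calib, p.NoiseModel(), seed=101)


@pytest.fixture(scope="session")
def clean_training(calib, training_design):
    """Noise-free training dataset: slopes equal the ground truth exactly."""
    return p.simulate_study(training_design, calib, p.NoiseModel(0.0, 0.0), seed=0)


@pytest.fixture(scope="session")
def noisy_slopes(noisy_training):
    return p.fit_all(noisy_training)


@pytest.fixture(scope="session")
def clean_slopes(clean_training):
    return p.fit_all(clean_training)


@pytest.fixture(scope="session")
def noisy_slope_df(noisy_slopes):
    return slopes_to_frame(noisy_slopes, "training")


@pytest.fixture(scope="session")
def noisy_inhibition_df(noisy_slopes):
    return inhibition_to_frame(p.pair_with_controls(noisy_slopes))


@pytest.fixture(scope="session")
def clean_inhibition_df(clean_slopes):
    return inhibition_to_frame(p.pair_with_controls(clean_slopes))


@pytest.fixture()
def rng():
    return np.random.default_rng(7)
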