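import numpy as np
import pytest

import teadtc as t
from teadtc.synth import ExperimentDesign, default_profiles, generate_experiment


@pytest.fixture(scope="session")
def small_design():
    """Reduced layout (3 varieties x 7 occasions x 2 reps, 120 bands) for fast tests."""
    return ExperimentDesign(
        varieties=("QN36", "QN1", "QN21"),
        replicates_per_cell=2,
        n_bands=120,
        wavelength_step=5.0,
        seed=42,
    )


@pytest.fixture(scope="session")
def small_experiment(small_design):
    return generate_experiment(small_design)


@pytest.fixture(scope="session")
def default_experiment():
    """One full-size synthetic experiment (280 x 360), shared across tests."""
    return generate_experiment(ExperimentDesign(seed=7))


@pytest.fixture(scope="session")
def default_dtc(default_experiment):
    _, physio, _ = default_experiment
    normalized = t.orient_and_normalize(physio)
    critic = t.critic_weights(normalized)
    return t.compute_dtc(normalized, critic, meta=physio[["sample_id", "variety", "stage"]])


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
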