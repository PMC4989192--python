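import numpy as np
import pytest

from posterp import (BehaviorProfile, NoiseModel, PipelineConfig,
                     ProfileJitter, TaskConfig, generate_event_sequence)
from posterp.pipeline import null_calibration, recover


@pytest.fixture(scope="session")
def quiet_noise():
    """No stochastic EEG at all: forward model only."""
    return NoiseModel(broadband_sd_uv=0.0, alpha_band_amplitude_uv=0.0,
                      artifact_rate=0.0)


@pytest.fixture(scope="session")
def default_events():
    return generate_event_sequence(seed=123)


@pytest.fixture(scope="session")
def small_task():
    """Reduced schedule for fast end-to-end smoke tests."""
    return TaskConfig(n_blocks=3)


@pytest.fixture(scope="session")
def recovery_table():
    """Parameter recovery across 20 replicate cohorts at the full study
    scale (n = 36 subjects, 10 x 80 trials, 8-channel montage).

    Session-scoped: shared by the recovery property tests and the
    acceptance checks (a few minutes of simulation).
    """
    return recover(PipelineConfig(), n_replicates=20, seed=7)


@pytest.fixture(scope="session")
def null_rejection():
    """False-positive rate of the condition contrast over 200
    condition-blind replicate cohorts (n = 12, 2 channels)."""
    return null_calibration(n_replicates=200, seed=3)
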