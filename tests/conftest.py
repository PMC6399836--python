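import numpy as np
import pytest
from hypothesis import settings

import myointent as mi

settings.register_profile("repro", derandomize=True, database=None,
                          deadline=None)
settings.load_profile("repro")


@pytest.fixture(scope="session")
def quiet_config():
    """Small, fully deterministic generator config with no noise or jitter:
    latent torques are exactly envelope x direction row."""
    return mi.GeneratorConfig(
        n_participants=1, trials_per_class=3, seed=7,
        synergy_coupling=0.0, torque_noise_sd=0.0,
        amplitude_jitter=0.0, direction_jitter_rel=0.0,
        direction_jitter_abs=0.0, activation_jitter=0.0,
        powerline_amplitude=0.0)


@pytest.fixture(scope="session")
def high_snr_config():
    """Separable study conditions: no synergy coupling, low trial-to-trial
    variability, modest sensor noise."""
    return mi.GeneratorConfig(
        n_participants=2, trials_per_class=3, seed=42,
        synergy_coupling=0.0, torque_noise_sd=0.3,
        amplitude_jitter=0.02, direction_jitter_rel=0.02,
        direction_jitter_abs=0.1, activation_jitter=0.05)


@pytest.fixture(scope="session")
def high_snr_cohort(high_snr_config):
    trials = mi.generate_dataset(high_snr_config)
    by = {}
    for t in trials:
        by.setdefault(t.participant_id, []).append(t)
    return by


@pytest.fixture(scope="session")
def prepared_participant(high_snr_config, high_snr_cohort):
    return mi.prepare_participant(high_snr_cohort["P01"],
                                  high_snr_config.geometry)


def group_by_participant(trials):
    by = {}
    for t in trials:
        by.setdefault(t.participant_id, []).append(t)
    return by
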