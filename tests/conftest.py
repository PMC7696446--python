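import numpy as np
import pytest

from cgmforecast import FramingSpec, PatientParams, simulate_trace


@pytest.fixture
def flat_params():
    """All stochastic and periodic generator terms switched off."""
    return PatientParams(
        patient_id="FLAT", basal_level=150.0, circadian_amplitude=0.0,
        meal_magnitude_mean=0.0, process_noise_sd=0.0, sensor_noise_sd=0.0,
        dropout_rate=0.0, meal_magnitude_cv=0.0, meal_time_jitter_min=0.0,
    )


@pytest.fixture
def flat_trace(flat_params):
    return simulate_trace(flat_params, 1)


@pytest.fixture
def learnable_params():
    """Noiseless sinusoid-plus-meals patient used for learnability checks.

    The slow meal responses and the circadian sinusoid are both linearly
    extrapolable from a 35-minute window, so the optimal short-horizon
    predictor is far below the persistence baseline.
    """
    return PatientParams(
        patient_id="SMOOTH", circadian_amplitude=40.0, meal_magnitude_mean=40.0,
        meal_rise_tau=45.0, meal_decay_tau=150.0, process_noise_sd=0.0,
        sensor_noise_sd=0.0, dropout_rate=0.0, meal_magnitude_cv=0.0,
        meal_time_jitter_min=0.0, seed=3,
    )


@pytest.fixture
def default_spec():
    return FramingSpec()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
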