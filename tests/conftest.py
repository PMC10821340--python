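"""Shared fixtures: small simulated trials, generated at test time."""

import numpy as np
import pytest

from eewalk.simulator import (
    Activity,
    BodyLocation,
    BreathSeries,
    IMURecording,
    Subject,
    Trial,
    TrialCondition,
    generate_subject,
    simulate_trial,
    standard_conditions,
)


@pytest.fixture(scope="session")
def subject():
    return generate_subject(7, "S1")


@pytest.fixture(scope="session")
def walk_condition():
    return TrialCondition(Activity.LEVEL_WALK, 4.0, 0.0, duration_s=600.0, standing_margin_s=60.0)


@pytest.fixture(scope="session")
def run_condition():
    return TrialCondition(Activity.LEVEL_RUN, 7.5, 0.0, duration_s=480.0, standing_margin_s=60.0)


@pytest.fixture(scope="session")
def walk_trial(subject, walk_condition):
    """One noisy walking trial with shank and chest recordings."""
    return simulate_trial(
        subject, walk_condition, seed=5,
        locations=[BodyLocation.SHANK, BodyLocation.CHEST],
    )


@pytest.fixture(scope="session")
def clean_walk_trial(subject, walk_condition):
    """Walking trial with noise-free breath data (IMU noise unchanged)."""
    return simulate_trial(
        subject, walk_condition, seed=5,
        locations=[BodyLocation.SHANK], breath_noise_sd=0.0,
    )


def make_dummy_trial(subject, condition, n_samples=1200, fs=100.0, seed=0):
    """Cheap hand-built trial for bookkeeping tests (no gait content)."""
    rng = np.random.default_rng(seed)
    rec = IMURecording(
        location=BodyLocation.SHANK,
        sample_rate_hz=fs,
        accel=rng.normal(0, 0.05, (n_samples, 3)) + [0, 0, 9.81],
        gyro=rng.normal(0, 0.05, (n_samples, 3)),
    )
    times = np.arange(1.0, condition.duration_s, 3.0)
    vo2 = np.full(len(times), 1000.0)
    breaths = BreathSeries(times_s=times, vo2_ml_min=vo2, vco2_ml_min=0.85 * vo2)
    return Trial(
        subject=subject,
        condition=condition,
        recordings={BodyLocation.SHANK: rec},
        breaths=breaths,
        latent_ee_w=300.0,
    )
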