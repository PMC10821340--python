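"""Simulator: determinism, cohort statistics, metabolic monotonicity,
signal bookkeeping and cadence recovery."""

import numpy as np
import pytest

from eewalk import metabolic
from eewalk.simulator import (
    Activity,
    BodyLocation,
    Subject,
    TrialCondition,
    generate_breaths,
    generate_imu,
    generate_subject,
    latent_metabolic_rate,
    standard_conditions,
    standard_protocol,
    standing_metabolic_rate,
    stride_frequency_hz,
)


class TestGenerateSubject:
    def test_deterministic_per_seed(self):
        assert generate_subject(7, "a") == generate_subject(7, "a")
        assert generate_subject(7, "a") != generate_subject(8, "a")

    def test_cohort_statistics(self):
        ws = [generate_subject(s).weight_kg for s in range(1000)]
        hs = [generate_subject(s).height_m for s in range(1000)]
        # sampling error on the mean of 1000 draws: sd/sqrt(n) ~ 0.2 kg
        assert abs(np.mean(ws) - 72.8) < 1.0
        assert abs(np.mean(hs) - 1.73) < 0.02

    def test_clip_bounds_strict(self):
        for s in range(500):
            subj = generate_subject(s)
            assert 50.0 < subj.weight_kg < 100.0
            assert 1.5 < subj.height_m < 2.0

    def test_invalid_anthropometrics_rejected(self):
        with pytest.raises(ValueError):
            Subject(id="x", weight_kg=20.0, height_m=1.7)
        with pytest.raises(ValueError):
            Subject(id="x", weight_kg=70.0, height_m=2.5)


class TestLatentMetabolicRate:
    def test_standing_hand_value(self):
        # 70 kg standing: 3.5 mL/kg/min -> Brockway at RER 0.85
        subj = Subject(id="x", weight_kg=70.0, height_m=1.7)
        ee = standing_metabolic_rate(subj)
        assert ee == pytest.approx(83.3, abs=0.1)
        assert ee / 70.0 == pytest.approx(1.19, abs=0.01)

    def test_monotone_in_speed(self, subject):
        w = dict(duration_s=600.0, standing_margin_s=60.0)
        slow = TrialCondition(Activity.LEVEL_WALK, 4.0, 0.0, **w)
        fast = TrialCondition(Activity.LEVEL_WALK, 6.0, 0.0, **w)
        assert latent_metabolic_rate(fast, subject) > latent_metabolic_rate(slow, subject)

    def test_monotone_in_grade(self, subject):
        w = dict(duration_s=600.0, standing_margin_s=60.0)
        ees = [
            latent_metabolic_rate(
                TrialCondition(Activity.INCLINE_WALK, 4.0, g, **w) if g else
                TrialCondition(Activity.LEVEL_WALK, 4.0, 0.0, **w),
                subject,
            )
            for g in (0.0, 3.0, 6.0)
        ]
        assert ees[0] < ees[1] < ees[2]

    def test_negative_speed_rejected(self):
        with pytest.raises(ValueError):
            TrialCondition(Activity.LEVEL_WALK, -1.0, 0.0)


class TestGenerateBreaths:
    def test_times_strictly_increasing(self, walk_condition, subject):
        b = generate_breaths(walk_condition, subject, seed=3)
        assert np.all(np.diff(b.times_s) > 0)
        assert b.times_s[0] >= 0 and b.times_s[-1] <= walk_condition.duration_s

    def test_noise_free_settles_to_plateau(self, walk_condition, subject):
        b = generate_breaths(walk_condition, subject, seed=3, noise_sd=0.0)
        plateau = latent_metabolic_rate(walk_condition, subject)
        start, end = metabolic.steady_state_window(walk_condition)
        mask = (b.times_s >= start) & (b.times_s < end)
        ee = metabolic.ee_series(b).ee_w[mask]
        # 240 s into activity = 8 time constants: fully settled
        assert abs(np.mean(ee) - plateau) / plateau < 0.03

    def test_noisy_mean_near_plateau(self, walk_condition, subject):
        b = generate_breaths(walk_condition, subject, seed=11, noise_sd=0.05)
        gt = metabolic.trial_ground_truth(b, walk_condition)
        plateau = latent_metabolic_rate(walk_condition, subject)
        start, end = metabolic.steady_state_window(walk_condition)
        n = np.sum((b.times_s >= start) & (b.times_s < end))
        assert abs(gt.ee_w - plateau) / plateau < 3 * 0.05 / np.sqrt(n)

    def test_deterministic(self, walk_condition, subject):
        b1 = generate_breaths(walk_condition, subject, seed=9)
        b2 = generate_breaths(walk_condition, subject, seed=9)
        np.testing.assert_array_equal(b1.vo2_ml_min, b2.vo2_ml_min)


class TestGenerateIMU:
    def test_sample_counts(self, walk_condition, run_condition, subject):
        walk = generate_imu(walk_condition, subject, BodyLocation.SHANK, 1)
        assert walk.n_samples == 60000
        run = generate_imu(run_condition, subject, BodyLocation.SHANK, 1)
        assert run.n_samples == 48000

    def test_active_gyro_dominates_standing(self, walk_condition, subject):
        rec = generate_imu(walk_condition, subject, BodyLocation.SHANK, 2)
        fs = rec.sample_rate_hz
        active = rec.gyro[int(120 * fs):int(480 * fs)]
        standing = rec.gyro[: int(60 * fs)]
        rms = lambda a: np.sqrt(np.mean(a.astype(float) ** 2))
        assert rms(active) > 5 * rms(standing)

    def test_unknown_location_rejected(self, walk_condition, subject):
        with pytest.raises(ValueError):
            generate_imu(walk_condition, subject, "ankle", 1)

    def test_gravity_offset_in_standing_accel(self, walk_condition, subject):
        rec = generate_imu(walk_condition, subject, BodyLocation.CHEST, 2)
        standing_az = rec.accel[: int(60 * rec.sample_rate_hz), 2]
        assert np.mean(standing_az) == pytest.approx(9.81, abs=0.05)

    def test_cadence_spectral_recovery(self, walk_trial, walk_condition):
        """Dominant spectral peak during steady walking matches programmed cadence."""
        rec = walk_trial.recordings[BodyLocation.SHANK]
        fs = rec.sample_rate_hz
        start, end = metabolic.steady_state_window(walk_condition)
        seg = rec.gyro[int(start * fs):int(end * fs), 1].astype(float)
        spec = np.abs(np.fft.rfft(seg - seg.mean()))
        freqs = np.fft.rfftfreq(len(seg), 1.0 / fs)
        f_peak = freqs[np.argmax(spec)]
        f_prog = stride_frequency_hz(walk_condition)
        assert abs(f_peak - f_prog) / f_prog < 0.05


class TestStandardProtocol:
    def test_trial_count_and_condition_multiset(self):
        trials = standard_protocol(2, seed=1, locations=[BodyLocation.SHANK])
        assert len(trials) == 16
        expected = sorted(c.label for c in standard_conditions())
        for sid in ("S01", "S02"):
            labels = sorted(t.condition.label for t in trials if t.subject.id == sid)
            assert labels == expected

    def test_seed_changes_order_not_multiset(self):
        t1 = standard_protocol(1, seed=1, locations=[BodyLocation.SHANK])
        t2 = standard_protocol(1, seed=2, locations=[BodyLocation.SHANK])
        assert sorted(t.condition.label for t in t1) == sorted(t.condition.label for t in t2)

    def test_stride_durations_within_validity_band(self):
        """Every protocol condition's programmed stride duration is physiologic."""
        for cond in standard_conditions():
            assert 0.5 <= 1.0 / stride_frequency_hz(cond) <= 2.0

    def test_rejects_empty_cohort(self):
        with pytest.raises(ValueError):
            standard_protocol(0, seed=1)
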