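"""Filtering, resampling, windowing and scaling contracts."""

import numpy as np
import pytest

from eewalk.preprocess import (
    WindowSet,
    apply_scalers,
    extract_windows,
    fit_scalers,
    lowpass_filter,
    resample,
    window_starts,
)
from eewalk.simulator import BodyLocation, IMURecording


def sine(freq, fs, dur=10.0):
    t = np.arange(int(dur * fs)) / fs
    return np.sin(2 * np.pi * freq * t)


class TestLowpassFilter:
    def test_dc_gain_unity(self):
        x = np.full((1000, 2), 3.7)
        y = lowpass_filter(x, fs=100.0)
        np.testing.assert_allclose(y, x, atol=1e-9)

    def test_passband_sinusoid_preserved(self):
        # |H(1 Hz)|^2 = 1/(1+(1/6)^8) ~ 1 for the zero-phase cascade
        y = lowpass_filter(sine(1.0, 100.0), fs=100.0)
        amp = np.max(np.abs(y[200:-200]))
        assert abs(amp - 1.0) < 0.01

    def test_stopband_sinusoid_suppressed(self):
        # |H(20 Hz)|^2 = 1/(1+(20/6)^8) ~ 6.6e-5
        y = lowpass_filter(sine(20.0, 100.0), fs=100.0)
        assert np.max(np.abs(y[200:-200])) < 1e-3

    def test_too_short_signal_rejected(self):
        with pytest.raises(ValueError):
            lowpass_filter(np.zeros((10, 3)), fs=100.0)

    def test_too_low_rate_rejected(self):
        with pytest.raises(ValueError):
            lowpass_filter(np.zeros((1000, 3)), fs=10.0)


class TestResample:
    def _rec(self, sig, fs=100.0):
        sig = np.column_stack([sig] * 6)
        return IMURecording(location=BodyLocation.SHANK, sample_rate_hz=fs,
                            accel=sig[:, :3], gyro=sig[:, 3:])

    def test_identity_at_source_rate(self):
        rec = self._rec(sine(2.0, 100.0))
        out = resample(rec, 100.0)
        np.testing.assert_array_equal(out.accel, rec.accel)

    def test_sample_count(self):
        rec = self._rec(np.zeros(60000))
        assert resample(rec, 60.0).n_samples == 36000

    def test_smooth_signal_error_small(self):
        rec = self._rec(sine(2.0, 100.0))
        out = resample(rec, 60.0)
        t = np.arange(out.n_samples) / 60.0
        err = np.max(np.abs(out.accel[:, 0].astype(float) - np.sin(2 * np.pi * 2.0 * t)))
        assert err < 0.01

    def test_upsampling_rejected(self):
        rec = self._rec(np.zeros(1000))
        with pytest.raises(ValueError):
            resample(rec, 200.0)


class TestExtractWindows:
    @pytest.mark.parametrize("seq,expected", [(2.0, 239), (6.0, 235)])
    def test_window_counts(self, walk_trial, seq, expected):
        ws = extract_windows(walk_trial, BodyLocation.SHANK, seq, 100.0, 1.0)
        assert len(ws) == expected
        assert ws.x.shape[1] == int(seq * 100)

    def test_window_length_at_other_rates(self, walk_trial):
        ws = extract_windows(walk_trial, BodyLocation.SHANK, 2.0, 60.0, 1.0)
        assert ws.x.shape == (239, 120, 6)

    def test_target_is_trial_ground_truth(self, walk_trial):
        from eewalk import metabolic
        ws = extract_windows(walk_trial, BodyLocation.SHANK, 2.0, 100.0, 2.0)
        gt = metabolic.trial_ground_truth(walk_trial.breaths, walk_trial.condition)
        assert np.all(ws.y_w == gt.ee_w)
        np.testing.assert_array_equal(
            ws.subject_features,
            np.tile([walk_trial.subject.weight_kg, walk_trial.subject.height_m], (len(ws), 1)),
        )

    def test_count_formula_matches_enumeration(self):
        """floor((S-L)/hop)+1 against a brute-force placement oracle."""
        rng = np.random.default_rng(0)
        for _ in range(50):
            S = rng.uniform(10, 300)
            L = rng.uniform(1, S)
            hop = rng.uniform(0.25, 10)
            brute = 0
            s = 0.0
            while s + L <= S + 1e-12:
                brute += 1
                s += hop
            assert len(window_starts(S, L, hop)) == brute

    def test_window_longer_than_interval_rejected(self, walk_trial):
        with pytest.raises(ValueError):
            extract_windows(walk_trial, BodyLocation.SHANK, 500.0, 100.0, 1.0)


class TestScalers:
    @pytest.fixture()
    def train_set(self, walk_trial):
        return extract_windows(walk_trial, BodyLocation.SHANK, 2.0, 100.0, 2.0)

    def test_standardization_and_minmax(self, train_set):
        # windows of one trial share a target; mix two trials' worth by jitter
        ws = WindowSet(
            x=train_set.x,
            y_w=train_set.y_w + np.linspace(0, 50, len(train_set)),
            subject_features=train_set.subject_features
            + np.linspace(0, 5, len(train_set))[:, None],
            meta=train_set.meta,
        )
        sp = fit_scalers(ws)
        scaled = apply_scalers(ws, sp)
        np.testing.assert_allclose(scaled.x.mean(axis=(0, 1)), 0.0, atol=1e-5)
        np.testing.assert_allclose(scaled.x.std(axis=(0, 1)), 1.0, atol=1e-5)
        assert scaled.y_w.min() == 0.0 and scaled.y_w.max() == 1.0
        assert scaled.subject_features.min() == 0.0
        assert scaled.subject_features.max() == 1.0

    def test_y_round_trip(self, train_set):
        ws = WindowSet(x=train_set.x, y_w=train_set.y_w + np.arange(len(train_set)),
                       subject_features=train_set.subject_features, meta=train_set.meta)
        sp = fit_scalers(ws)
        back = sp.invert_y(sp.scale_y(ws.y_w))
        np.testing.assert_allclose(back, ws.y_w, atol=1e-9)

    def test_out_of_range_targets_not_clipped(self, train_set):
        ws = WindowSet(x=train_set.x, y_w=train_set.y_w + np.arange(len(train_set)),
                       subject_features=train_set.subject_features, meta=train_set.meta)
        sp = fit_scalers(ws)
        assert sp.scale_y(np.array([ws.y_w.max() + 100.0]))[0] > 1.0

    def test_constant_target_rejected(self, train_set):
        with pytest.raises(ValueError):
            fit_scalers(train_set)  # single-trial set: constant y

    def test_zero_variance_channel_rejected(self, train_set):
        x = train_set.x.copy()
        x[:, :, 3] = 0.0
        ws = WindowSet(x=x, y_w=train_set.y_w + np.arange(len(train_set)),
                       subject_features=train_set.subject_features, meta=train_set.meta)
        with pytest.raises(ValueError):
            fit_scalers(ws)


class TestPersistence:
    def test_save_load_round_trip(self, walk_trial, tmp_path):
        ws = extract_windows(walk_trial, BodyLocation.SHANK, 2.0, 100.0, 4.0)
        path = tmp_path / "windows.npz"
        ws.save(path)
        back = WindowSet.load(path)
        np.testing.assert_array_equal(back.x, ws.x)
        np.testing.assert_array_equal(back.y_w, ws.y_w)
        assert list(back.meta["subject"]) == list(ws.meta["subject"])
        assert back.scaled == ws.scaled
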