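"""IMU preprocessing: low-pass filtering, resampling, windowing, scaling.

Pipeline order is fixed: filter at the native rate, resample to the model
rate, then cut fixed-length windows from the trial's steady-state interval.
Windows never touch standing or transition segments, because the only
defined regression target is the steady-state energy expenditure.

Scaling follows the training convention of the model family: IMU channels
are standardized (zero mean, unit sd per channel over the training set),
while the EE target and the two subject features (weight, height) are
min-max normalized to [0, 1].  Scalers are fitted on training data only and
travel with the trained model.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import signal as sps

from . import metabolic
from .simulator import BodyLocation, IMURecording, Trial

__all__ = [
    "WindowSet",
    "ScalerParams",
    "lowpass_filter",
    "resample",
    "extract_windows",
    "fit_scalers",
    "apply_scalers",
    "concat_window_sets",
]

FILTER_ORDER = 4
CUTOFF_HZ = 6.0


@dataclass
class WindowSet:
    """Model-ready window tensor with targets, subject features and metadata.

    ``x`` is N x L x 6 (accel then gyro channels), ``y_w`` the steady-state
    EE target in watts repeated per window, ``subject_features`` N x 2
    (weight kg, height m).  ``meta`` has one row per window with subject,
    trial and location identifiers.  ``scaled`` marks whether scalers have
    been applied.
    """

    x: np.ndarray
    y_w: np.ndarray
    subject_features: np.ndarray
    meta: pd.DataFrame
    scaled: bool = False

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=np.float32)
        self.y_w = np.asarray(self.y_w, dtype=np.float64)
        self.subject_features = np.asarray(self.subject_features, dtype=np.float64)
        n = self.x.shape[0]
        if self.x.ndim != 3:
            raise ValueError("x must be N x L x C")
        if len(self.y_w) != n or self.subject_features.shape != (n, 2) or len(self.meta) != n:
            raise ValueError("inconsistent window-set component lengths")

    def __len__(self) -> int:
        return self.x.shape[0]

    def save(self, path) -> None:
        """Persist as a single .npz plus a JSON metadata sidecar."""
        path = Path(path)
        np.savez_compressed(path, x=self.x, y=self.y_w, features=self.subject_features)
        sidecar = path.with_suffix(path.suffix + ".meta.json")
        sidecar.write_text(json.dumps({
            "scaled": self.scaled,
            "meta": self.meta.to_dict(orient="list"),
        }))

    @classmethod
    def load(cls, path) -> "WindowSet":
        path = Path(path)
        with np.load(path) as z:
            x, y, feats = z["x"], z["y"], z["features"]
        side = json.loads(path.with_suffix(path.suffix + ".meta.json").read_text())
        return cls(x=x, y_w=y, subject_features=feats,
                   meta=pd.DataFrame(side["meta"]), scaled=side["scaled"])


@dataclass(frozen=True)
class ScalerParams:
    """Training-set scaling state: channel standardization + target min-max."""

    channel_mean: np.ndarray
    channel_sd: np.ndarray
    y_min: float
    y_max: float
    feat_min: np.ndarray
    feat_max: np.ndarray

    def __post_init__(self) -> None:
        if np.any(np.asarray(self.channel_sd) <= 0):
            raise ValueError("channel_sd must be > 0")
        if self.y_max <= self.y_min:
            raise ValueError("y_max must exceed y_min")

    def scale_x(self, x: np.ndarray) -> np.ndarray:
        return ((x - self.channel_mean) / self.channel_sd).astype(np.float32)

    def scale_y(self, y: np.ndarray) -> np.ndarray:
        return (np.asarray(y, dtype=float) - self.y_min) / (self.y_max - self.y_min)

    def invert_y(self, y_scaled: np.ndarray):
        return np.asarray(y_scaled, dtype=float) * (self.y_max - self.y_min) + self.y_min

    def scale_features(self, feats: np.ndarray) -> np.ndarray:
        rng = np.maximum(self.feat_max - self.feat_min, 1e-12)
        return (np.asarray(feats, dtype=float) - self.feat_min) / rng

    def to_dict(self) -> dict:
        return {
            "channel_mean": np.asarray(self.channel_mean).tolist(),
            "channel_sd": np.asarray(self.channel_sd).tolist(),
            "y_min": self.y_min,
            "y_max": self.y_max,
            "feat_min": np.asarray(self.feat_min).tolist(),
            "feat_max": np.asarray(self.feat_max).tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ScalerParams":
        return cls(
            channel_mean=np.asarray(d["channel_mean"], dtype=float),
            channel_sd=np.asarray(d["channel_sd"], dtype=float),
            y_min=float(d["y_min"]),
            y_max=float(d["y_max"]),
            feat_min=np.asarray(d["feat_min"], dtype=float),
            feat_max=np.asarray(d["feat_max"], dtype=float),
        )


def lowpass_filter(x: np.ndarray, fs: float) -> np.ndarray:
    """Zero-phase 4th-order Butterworth low-pass at 6 Hz, per channel.

    Forward-backward application (filtfilt), so the effective magnitude
    response is |H(f)|^2 = 1 / (1 + (f/6)^8) with no phase distortion.
    Output length equals input length.
    """
    x = np.asarray(x, dtype=float)
    if fs <= 2 * CUTOFF_HZ:
        raise ValueError(f"sample rate {fs} Hz too low for a {CUTOFF_HZ} Hz cutoff")
    squeeze = x.ndim == 1
    if squeeze:
        x = x[:, None]
    if x.shape[0] < 3 * (2 * FILTER_ORDER + 1):
        raise ValueError("signal too short for zero-phase filtering")
    sos = sps.butter(FILTER_ORDER, CUTOFF_HZ, btype="low", fs=fs, output="sos")
    y = sps.sosfiltfilt(sos, x, axis=0)
    return y[:, 0] if squeeze else y


def resample(recording: IMURecording, target_hz: float) -> IMURecording:
    """Linear-interpolation downsampling onto a uniform grid of the same span.

    Valid only after low-pass filtering: with the signal band at or below
    6 Hz and the lowest target Nyquist at 30 Hz, linear interpolation error
    is negligible.  Upsampling is refused.
    """
    if target_hz > recording.sample_rate_hz:
        raise ValueError("resample only downsamples (target above source rate)")
    if target_hz == recording.sample_rate_hz:
        return IMURecording(
            location=recording.location,
            sample_rate_hz=recording.sample_rate_hz,
            accel=recording.accel.copy(),
            gyro=recording.gyro.copy(),
        )
    t_src = np.arange(recording.n_samples) / recording.sample_rate_hz
    n_out = int(round(recording.duration_s * target_hz))
    t_out = np.arange(n_out) / target_hz
    def interp(block: np.ndarray) -> np.ndarray:
        return np.stack([np.interp(t_out, t_src, block[:, c]) for c in range(block.shape[1])], axis=1)
    return IMURecording(
        location=recording.location,
        sample_rate_hz=target_hz,
        accel=interp(recording.accel),
        gyro=interp(recording.gyro),
    )


def window_starts(interval_len_s: float, seq_time_s: float, hop_s: float) -> np.ndarray:
    """Window start offsets within an interval: floor((S-L)/hop)+1 of them."""
    if seq_time_s > interval_len_s:
        raise ValueError("window longer than the interval")
    n = int(np.floor((interval_len_s - seq_time_s) / hop_s)) + 1
    return np.arange(n) * hop_s


def extract_windows(
    trial: Trial,
    location: BodyLocation,
    seq_time_s: float = 2.0,
    fs: float = 100.0,
    hop_s: float = 1.0,
) -> WindowSet:
    """Cut fixed-size windows from one trial's steady-state interval.

    The recording is low-pass filtered at its native rate, resampled to
    ``fs``, then windows of L = seq_time_s x fs samples are taken every
    ``hop_s`` seconds inside the steady-state interval.  Every window's
    target is the trial's ground-truth EE.
    """
    location = BodyLocation(location)
    rec = trial.recordings[location]
    start, end = metabolic.steady_state_window(trial.condition)
    if end - start < seq_time_s:
        raise ValueError("sequence time exceeds the steady-state interval")

    filtered = lowpass_filter(rec.six_axis(), rec.sample_rate_hz)
    rec_f = IMURecording(location=location, sample_rate_hz=rec.sample_rate_hz,
                         accel=filtered[:, :3], gyro=filtered[:, 3:])
    rec_r = resample(rec_f, fs)
    sig = rec_r.six_axis()

    L = int(round(seq_time_s * fs))
    truth = metabolic.trial_ground_truth(trial.breaths, trial.condition).ee_w

    xs = []
    for s in start + window_starts(end - start, seq_time_s, hop_s):
        i0 = int(round(s * fs))
        xs.append(sig[i0:i0 + L])
    x = np.stack(xs)
    n = x.shape[0]
    meta = pd.DataFrame({
        "subject": [trial.subject.id] * n,
        "trial": [trial.id] * n,
        "location": [location.value] * n,
    })
    feats = np.tile([trial.subject.weight_kg, trial.subject.height_m], (n, 1))
    return WindowSet(x=x, y_w=np.full(n, truth), subject_features=feats, meta=meta)


def concat_window_sets(sets: Sequence[WindowSet]) -> WindowSet:
    """Stack window (or stride) sets from several trials into one."""
    sets = [s for s in sets if len(s) > 0]
    if not sets:
        raise ValueError("nothing to concatenate")
    if len({s.scaled for s in sets}) != 1:
        raise ValueError("cannot mix scaled and unscaled sets")
    return WindowSet(
        x=np.concatenate([s.x for s in sets]),
        y_w=np.concatenate([s.y_w for s in sets]),
        subject_features=np.concatenate([s.subject_features for s in sets]),
        meta=pd.concat([s.meta for s in sets], ignore_index=True),
        scaled=sets[0].scaled,
    )


def fit_scalers(train: WindowSet) -> ScalerParams:
    """Fit channel standardization and target/feature min-max on training data."""
    if len(train) < 2:
        raise ValueError("need at least 2 windows to fit scalers")
    mean = train.x.mean(axis=(0, 1), dtype=np.float64)
    sd = train.x.std(axis=(0, 1), dtype=np.float64)
    if np.any(sd <= 0):
        raise ValueError("zero variance in at least one channel")
    y_min, y_max = float(train.y_w.min()), float(train.y_w.max())
    if y_max <= y_min:
        raise ValueError("constant target: cannot min-max normalize")
    return ScalerParams(
        channel_mean=mean,
        channel_sd=sd,
        y_min=y_min,
        y_max=y_max,
        feat_min=train.subject_features.min(axis=0),
        feat_max=train.subject_features.max(axis=0),
    )


def apply_scalers(ws: WindowSet, sp: ScalerParams) -> WindowSet:
    """Return a scaled copy; values outside the training range are not clipped."""
    return WindowSet(
        x=sp.scale_x(ws.x),
        y_w=sp.scale_y(ws.y_w),
        subject_features=sp.scale_features(ws.subject_features),
        meta=ws.meta.copy(),
        scaled=True,
    )
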