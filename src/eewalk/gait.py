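"""Gait event detection and stride-normalized inputs for the MLP baseline.

Heel strikes are detected from the shank gyroscope's sagittal channel with a
peak-and-minimum rule: mid-swing candidates are local maxima above an
adaptive threshold (0.6 x the 95th percentile of the signal) separated by at
least 0.5 s; the heel strike is the first local minimum after each mid-swing
peak within half the median peak spacing (falling back to the minimum sample
in that window when noise leaves no interior local minimum).  Strides whose
duration falls outside the physiologic 0.5-2.0 s band are discarded.

Strides are always delimited by SHANK-derived events, whichever location's
recording is being segmented, and each stride is resampled per channel onto
30 equally spaced phase points (endpoints included) to form the fixed-size
input of the stride-MLP baseline.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import List, Tuple

import numpy as np
import pandas as pd
from scipy import signal as sps

from . import metabolic
from .preprocess import WindowSet, lowpass_filter, resample
from .simulator import BodyLocation, IMURecording, Trial

__all__ = [
    "HeelStrikes",
    "StrideSet",
    "STRIDE_LEN",
    "STRIDE_DURATION_BOUNDS_S",
    "detect_heel_strikes",
    "segment_strides",
    "resample_stride",
    "build_stride_set",
    "sagittal_gyro_channel",
]

#: Samples per normalized stride fed to the MLP.
STRIDE_LEN = 30

#: Valid stride durations, seconds.
STRIDE_DURATION_BOUNDS_S = (0.5, 2.0)

# StrideSet is structurally a WindowSet whose second dimension is STRIDE_LEN.
StrideSet = WindowSet


@dataclass(frozen=True)
class HeelStrikes:
    """Strictly increasing heel-strike times, seconds."""

    times_s: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times_s, dtype=float)
        object.__setattr__(self, "times_s", t)
        if len(t) > 1 and not np.all(np.diff(t) > 0):
            raise ValueError("heel-strike times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.times_s)


def detect_heel_strikes(
    shank_gyro_sagittal: np.ndarray,
    fs: float,
    min_peak_height: float = 1.0,
) -> HeelStrikes:
    """Detect heel strikes from the (filtered) sagittal shank gyro channel.

    The adaptive mid-swing threshold (0.6 x 95th percentile) is combined
    with an absolute floor of ``min_peak_height`` rad/s: mid-swing shank
    angular velocity during gait is several rad/s, so the floor rejects
    quiet-standing noise that a purely relative threshold would fire on.

    Returns an empty result rather than raising when fewer than two valid
    events are found (e.g. quiet standing).
    """
    sig = np.asarray(shank_gyro_sagittal, dtype=float)
    if sig.ndim != 1:
        raise ValueError("expected a single channel")
    if len(sig) < int(fs):
        return HeelStrikes(times_s=np.array([]))

    height = max(0.6 * np.percentile(sig, 95), min_peak_height)
    if height <= 0:
        return HeelStrikes(times_s=np.array([]))
    peaks, _ = sps.find_peaks(sig, height=height, distance=max(1, int(round(0.5 * fs))))
    if len(peaks) < 2:
        return HeelStrikes(times_s=np.array([]))

    half_spacing = int(round(0.5 * float(np.median(np.diff(peaks)))))
    events: List[int] = []
    for p in peaks:
        seg = sig[p:p + half_spacing + 1]
        if len(seg) < 3:
            continue
        interior = np.nonzero((seg[1:-1] < seg[:-2]) & (seg[1:-1] <= seg[2:]))[0]
        off = int(interior[0]) + 1 if len(interior) else int(np.argmin(seg))
        idx = p + off
        if not events or idx > events[-1]:
            events.append(idx)
    if len(events) < 2:
        return HeelStrikes(times_s=np.array([]))
    return HeelStrikes(times_s=np.asarray(events, dtype=float) / fs)


def segment_strides(
    recording: IMURecording, hs: HeelStrikes
) -> List[np.ndarray]:
    """Cut one recording into [hs[k], hs[k+1]) six-channel segments.

    Events always come from the shank gyro; the recording may belong to any
    body location sampled at the same rate.
    """
    sig = recording.six_axis()
    fs = recording.sample_rate_hz
    out = []
    for t0, t1 in zip(hs.times_s[:-1], hs.times_s[1:]):
        i0, i1 = int(round(t0 * fs)), int(round(t1 * fs))
        out.append(sig[i0:i1])
    return out


def resample_stride(segment: np.ndarray, target_len: int = STRIDE_LEN) -> np.ndarray:
    """Per-channel linear interpolation onto an endpoints-inclusive phase grid.

    Exact on affine signals; requires at least two input samples.
    """
    seg = np.asarray(segment, dtype=float)
    if seg.ndim != 2:
        raise ValueError("segment must be M x C")
    m = seg.shape[0]
    if m < 2:
        raise ValueError("stride segment needs at least 2 samples")
    src = np.arange(m, dtype=float)
    dst = np.linspace(0.0, m - 1.0, target_len)
    return np.stack([np.interp(dst, src, seg[:, c]) for c in range(seg.shape[1])], axis=1)


def sagittal_gyro_channel(shank: IMURecording, active: Tuple[float, float]) -> int:
    """Pick the sagittal axis as the gyro channel with maximal active variance."""
    i0 = int(round(active[0] * shank.sample_rate_hz))
    i1 = int(round(active[1] * shank.sample_rate_hz))
    return int(np.argmax(shank.gyro[i0:i1].var(axis=0)))


def build_stride_set(
    trial: Trial,
    location: BodyLocation,
    fs: float = 100.0,
) -> StrideSet:
    """Stride-segmented, length-30 inputs for one trial and location.

    Both the shank (event source) and the target location's recording are
    low-pass filtered and resampled to ``fs``.  Only strides lying wholly
    inside the steady-state interval and passing the duration-validity rule
    are kept; each carries the trial's ground-truth EE as target.
    """
    location = BodyLocation(location)
    start, end = metabolic.steady_state_window(trial.condition)

    def prep(rec: IMURecording) -> IMURecording:
        filt = lowpass_filter(rec.six_axis(), rec.sample_rate_hz)
        return resample(
            IMURecording(location=rec.location, sample_rate_hz=rec.sample_rate_hz,
                         accel=filt[:, :3], gyro=filt[:, 3:]),
            fs,
        )

    shank = prep(trial.recordings[BodyLocation.SHANK])
    target = shank if location is BodyLocation.SHANK else prep(trial.recordings[location])

    ch = sagittal_gyro_channel(shank, (start, end))
    i0, i1 = int(round(start * fs)), int(round(end * fs))
    hs_local = detect_heel_strikes(shank.gyro[i0:i1, ch], fs)
    hs = HeelStrikes(times_s=hs_local.times_s + start)

    lo, hi = STRIDE_DURATION_BOUNDS_S
    strides, durations = [], []
    for k, seg in enumerate(segment_strides(target, hs)):
        t0, t1 = hs.times_s[k], hs.times_s[k + 1]
        if t0 < start or t1 > end:
            continue
        if not lo <= t1 - t0 <= hi:
            continue
        strides.append(resample_stride(seg, STRIDE_LEN))
        durations.append(t1 - t0)

    n = len(strides)
    if n == 0:
        warnings.warn(f"no valid strides in trial {trial.id}", stacklevel=2)
        return StrideSet(
            x=np.zeros((0, STRIDE_LEN, 6), dtype=np.float32),
            y_w=np.zeros(0),
            subject_features=np.zeros((0, 2)),
            meta=pd.DataFrame({"subject": [], "trial": [], "location": []}),
        )

    truth = metabolic.trial_ground_truth(trial.breaths, trial.condition).ee_w
    meta = pd.DataFrame({
        "subject": [trial.subject.id] * n,
        "trial": [trial.id] * n,
        "location": [location.value] * n,
    })
    feats = np.tile([trial.subject.weight_kg, trial.subject.height_m], (n, 1))
    return StrideSet(
        x=np.stack(strides),
        y_w=np.full(n, truth),
        subject_features=feats,
        meta=meta,
    )
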