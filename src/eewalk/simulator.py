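"""Synthetic treadmill gait and gas-exchange data generator.

Emulates a treadmill protocol in which each subject completes eight
conditions — level walking at 4 and 6 KPH, level running at 7.5 and 9 KPH,
and inclined walking at 4 and 6 KPH on 3 % and 6 % grades — while wearing
six-axis IMUs on the chest, right wrist, thigh, shank and foot (100 Hz) and
a breath-by-breath metabolic analyzer.  Walking trials last 10 min, running
trials 8 min, with one minute of quiet standing at both ends.

Every generator is a pure function of its inputs and a seed, so the full
downstream pipeline (filtering, windowing, gait segmentation, training,
leave-one-subject-out evaluation) is testable without any recorded data.

The metabolic ground truth follows ACSM-style walking/running VO2 equations
converted to watts with the Brockway equation at a fixed respiratory
exchange ratio of 0.85.  The IMU signal model is a per-location Fourier
template (three harmonics of the stride frequency) whose amplitude grows
with speed and, for lower-body locations, with incline; it is a stand-in
with the statistical structure the pipeline needs (periodicity, a dominant
shank-gyro mid-swing peak, gravity offset, noise), not a biomechanical
claim.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from enum import Enum
from typing import Dict, List, Sequence, Tuple

import numpy as np

__all__ = [
    "Activity",
    "BodyLocation",
    "Subject",
    "TrialCondition",
    "IMURecording",
    "BreathSeries",
    "Trial",
    "generate_subject",
    "latent_metabolic_rate",
    "generate_breaths",
    "generate_imu",
    "simulate_trial",
    "standing_metabolic_rate",
    "stride_frequency_hz",
    "standard_protocol",
    "standard_conditions",
    "GRAVITY_M_S2",
]

GRAVITY_M_S2 = 9.81

#: Cohort anthropometrics the subject generator draws from (mean, sd).
WEIGHT_MEAN_KG, WEIGHT_SD_KG = 72.8, 6.3
HEIGHT_MEAN_M, HEIGHT_SD_M = 1.73, 0.06

#: Resting oxygen uptake, mL O2 per kg per minute.
VO2_REST_ML_KG_MIN = 3.5

#: Fixed respiratory exchange ratio used by the simulator (VCO2/VO2).
RER = 0.85

#: First-order VO2 on/off-kinetics time constant, seconds.
VO2_TAU_S = 30.0

IMU_SAMPLE_RATE_HZ = 100.0


class Activity(str, Enum):
    LEVEL_WALK = "level_walk"
    INCLINE_WALK = "incline_walk"
    LEVEL_RUN = "level_run"


class BodyLocation(str, Enum):
    CHEST = "chest"
    WRIST = "wrist"
    THIGH = "thigh"
    SHANK = "shank"
    FOOT = "foot"


LOWER_BODY = frozenset({BodyLocation.THIGH, BodyLocation.SHANK, BodyLocation.FOOT})


@dataclass(frozen=True)
class Subject:
    """One participant: identifier plus the two anthropometric model inputs."""

    id: str
    weight_kg: float
    height_m: float

    def __post_init__(self) -> None:
        if not 30.0 < self.weight_kg < 150.0:
            raise ValueError(f"weight_kg={self.weight_kg} outside (30, 150)")
        if not 1.2 < self.height_m < 2.2:
            raise ValueError(f"height_m={self.height_m} outside (1.2, 2.2)")


@dataclass(frozen=True)
class TrialCondition:
    """One treadmill condition: activity, speed, grade and timing."""

    activity: Activity
    speed_kph: float
    incline_pct: float = 0.0
    duration_s: float = 600.0
    standing_margin_s: float = 60.0

    def __post_init__(self) -> None:
        if self.speed_kph < 0:
            raise ValueError("speed_kph must be >= 0")
        if self.incline_pct < 0:
            raise ValueError("incline_pct must be >= 0")
        if self.activity is not Activity.INCLINE_WALK and self.incline_pct != 0.0:
            raise ValueError("incline_pct must be 0 unless activity is incline_walk")
        if self.duration_s <= 0:
            raise ValueError("duration_s must be > 0")
        if self.standing_margin_s < 0:
            raise ValueError("standing_margin_s must be >= 0")

    @property
    def label(self) -> str:
        if self.activity is Activity.INCLINE_WALK:
            return f"incline_walk_{self.speed_kph:g}kph_{self.incline_pct:g}pct"
        return f"{self.activity.value}_{self.speed_kph:g}kph"


@dataclass
class IMURecording:
    """Uniformly sampled six-axis inertial signal from one body location.

    ``accel`` is T x 3 in m/s^2, ``gyro`` T x 3 in rad/s.
    """

    location: BodyLocation
    sample_rate_hz: float
    accel: np.ndarray
    gyro: np.ndarray

    def __post_init__(self) -> None:
        self.accel = np.asarray(self.accel, dtype=np.float32)
        self.gyro = np.asarray(self.gyro, dtype=np.float32)
        if self.sample_rate_hz <= 0:
            raise ValueError("sample_rate_hz must be > 0")
        if self.accel.shape != self.gyro.shape or self.accel.ndim != 2 or self.accel.shape[1] != 3:
            raise ValueError("accel and gyro must both be T x 3 with identical T")
        if not (np.isfinite(self.accel).all() and np.isfinite(self.gyro).all()):
            raise ValueError("IMU samples must be finite")

    @property
    def n_samples(self) -> int:
        return self.accel.shape[0]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sample_rate_hz

    def six_axis(self) -> np.ndarray:
        """T x 6 array: accelerometer channels then gyroscope channels."""
        return np.concatenate([self.accel, self.gyro], axis=1)


@dataclass
class BreathSeries:
    """Breath-by-breath gas exchange: times plus VO2/VCO2 in mL/min."""

    times_s: np.ndarray
    vo2_ml_min: np.ndarray
    vco2_ml_min: np.ndarray

    def __post_init__(self) -> None:
        self.times_s = np.asarray(self.times_s, dtype=float)
        self.vo2_ml_min = np.asarray(self.vo2_ml_min, dtype=float)
        self.vco2_ml_min = np.asarray(self.vco2_ml_min, dtype=float)
        n = len(self.times_s)
        if len(self.vo2_ml_min) != n or len(self.vco2_ml_min) != n:
            raise ValueError("times, VO2 and VCO2 must have equal length")
        if n > 1 and not np.all(np.diff(self.times_s) > 0):
            raise ValueError("times_s must be strictly increasing")
        if np.any(self.vo2_ml_min < 0) or np.any(self.vco2_ml_min < 0):
            raise ValueError("gas-exchange rates must be >= 0")


@dataclass
class Trial:
    """One subject x condition session: IMU recordings, breaths, latent truth.

    ``latent_ee_w`` is simulator-only knowledge — the exact activity plateau
    the breath data converges to — used to validate ground-truth extraction.
    """

    subject: Subject
    condition: TrialCondition
    recordings: Dict[BodyLocation, IMURecording]
    breaths: BreathSeries
    latent_ee_w: float
    id: str = field(default="")

    def __post_init__(self) -> None:
        if self.latent_ee_w <= 0:
            raise ValueError("latent_ee_w must be > 0")
        if not self.id:
            self.id = f"{self.subject.id}_{self.condition.label}"


# ---------------------------------------------------------------------------
# subjects


def generate_subject(seed: int, id: str = "S0") -> Subject:
    """Draw one subject from the cohort anthropometric distribution.

    Weight ~ N(72.8, 6.3) kg clipped to (50, 100); height ~ N(1.73, 0.06) m
    clipped to (1.5, 2.0).  Deterministic per seed.
    """
    rng = np.random.default_rng(seed)
    weight = float(np.clip(rng.normal(WEIGHT_MEAN_KG, WEIGHT_SD_KG),
                           np.nextafter(50.0, 100.0), np.nextafter(100.0, 50.0)))
    height = float(np.clip(rng.normal(HEIGHT_MEAN_M, HEIGHT_SD_M),
                           np.nextafter(1.5, 2.0), np.nextafter(2.0, 1.5)))
    return Subject(id=id, weight_kg=weight, height_m=height)


# ---------------------------------------------------------------------------
# metabolic truth


def _vo2_ml_kg_min(activity: Activity, speed_kph: float, incline_pct: float) -> float:
    """ACSM-style gross VO2 in mL/kg/min. v in m/min, grade fractional."""
    if speed_kph < 0:
        raise ValueError("speed must be >= 0")
    v = speed_kph * 1000.0 / 60.0
    g = incline_pct / 100.0
    if v == 0:
        return VO2_REST_ML_KG_MIN
    if activity is Activity.LEVEL_RUN:
        return VO2_REST_ML_KG_MIN + 0.2 * v + 0.9 * v * g
    return VO2_REST_ML_KG_MIN + 0.1 * v + 1.8 * v * g


def _vo2_to_watts(vo2_ml_min: float) -> float:
    """Brockway conversion at the simulator's fixed RER of 0.85."""
    from .metabolic import brockway_ee

    return brockway_ee(vo2_ml_min, RER * vo2_ml_min)


def latent_metabolic_rate(condition: TrialCondition, subject: Subject) -> float:
    """Steady-state metabolic power (watts) a subject settles to in a condition."""
    vo2 = _vo2_ml_kg_min(condition.activity, condition.speed_kph, condition.incline_pct)
    return _vo2_to_watts(vo2 * subject.weight_kg)


def standing_metabolic_rate(subject: Subject) -> float:
    """Quiet-standing metabolic power (watts): resting VO2 of 3.5 mL/kg/min."""
    return _vo2_to_watts(VO2_REST_ML_KG_MIN * subject.weight_kg)


# ---------------------------------------------------------------------------
# breath-by-breath gas exchange


def _segments(condition: TrialCondition) -> List[Tuple[float, float, bool]]:
    """(start, end, is_active) partition of the trial timeline."""
    m = condition.standing_margin_s
    d = condition.duration_s
    if m == 0:
        return [(0.0, d, True)]
    return [(0.0, m, False), (m, d - m, True), (d - m, d, False)]


def generate_breaths(
    condition: TrialCondition,
    subject: Subject,
    seed: int,
    noise_sd: float = 0.05,
) -> BreathSeries:
    """Simulate breath-by-breath VO2/VCO2 for one trial.

    Breath intervals are N(3.0, 0.5) s truncated above 1 s.  VO2 follows
    first-order exponential kinetics (tau = 30 s) toward the current
    segment's plateau — the standing rate during the margins, the activity
    rate in between — with multiplicative Gaussian noise of relative sd
    ``noise_sd`` applied per breath.  VCO2 = 0.85 x VO2.
    """
    rng = np.random.default_rng(seed)

    # breath times: truncated-normal intervals accumulated over the trial
    times = []
    t = float(rng.normal(3.0, 0.5))
    while t < condition.duration_s:
        times.append(t)
        dt = rng.normal(3.0, 0.5)
        while dt <= 1.0:
            dt = rng.normal(3.0, 0.5)
        t += float(dt)
    times = np.asarray(times)

    vo2_stand = VO2_REST_ML_KG_MIN * subject.weight_kg
    vo2_active = (
        _vo2_ml_kg_min(condition.activity, condition.speed_kph, condition.incline_pct)
        * subject.weight_kg
    )

    # exact exponential solution segment by segment
    segs = _segments(condition)
    boundary_vals = [vo2_stand]  # VO2 state entering each segment
    for (s0, s1, active) in segs:
        target = vo2_active if active else vo2_stand
        v_in = boundary_vals[-1]
        boundary_vals.append(target + (v_in - target) * np.exp(-(s1 - s0) / VO2_TAU_S))

    vo2 = np.empty_like(times)
    for i, tb in enumerate(times):
        for k, (s0, s1, active) in enumerate(segs):
            if s0 <= tb < s1 or (k == len(segs) - 1 and tb == s1):
                target = vo2_active if active else vo2_stand
                vo2[i] = target + (boundary_vals[k] - target) * np.exp(-(tb - s0) / VO2_TAU_S)
                break

    if noise_sd > 0:
        vo2 = vo2 * (1.0 + rng.normal(0.0, noise_sd, size=vo2.shape))
        vo2 = np.maximum(vo2, 0.0)
    return BreathSeries(times_s=times, vo2_ml_min=vo2, vco2_ml_min=RER * vo2)


# ---------------------------------------------------------------------------
# IMU signal model

# per-location waveform scale: (accel amplitude m/s^2, gyro amplitude rad/s)
_LOC_AMP = {
    BodyLocation.CHEST: (0.8, 0.3),
    BodyLocation.WRIST: (1.5, 0.8),
    BodyLocation.THIGH: (2.0, 1.5),
    BodyLocation.SHANK: (3.0, 3.0),
    BodyLocation.FOOT: (5.0, 4.0),
}

#: Relative harmonic amplitudes of the gait template.
_HARMONICS = (1.0, 0.5, 0.25)

#: Relative amplitude of each of the six channels (ax ay az gx gy gz);
#: gy is the sagittal gyro channel and dominates so variance-based axis
#: selection and mid-swing peak detection are well posed.
_CHANNEL_REL = np.array([0.8, 0.6, 1.0, 0.5, 1.0, 0.4])
_SAGITTAL_GYRO = 1  # gy


def stride_frequency_hz(condition: TrialCondition) -> float:
    """Programmed stride (full gait cycle) rate for a condition.

    Step rate grows affinely with speed — 1.4 + 0.25 v steps/s walking,
    2.4 + 0.1 v running — and one stride is two steps, which keeps stride
    durations inside the physiologic 0.5–2.0 s band for every protocol
    condition.
    """
    v = condition.speed_kph
    if condition.activity is Activity.LEVEL_RUN:
        return (2.4 + 0.1 * v) / 2.0
    return (1.4 + 0.25 * v) / 2.0


def _subject_gain(subject: Subject) -> float:
    """Per-subject multiplicative signal gain, uniform in [0.9, 1.1]."""
    h = zlib.crc32(subject.id.encode("utf-8"))
    u = np.random.default_rng(h).uniform()
    return 0.9 + 0.2 * u


def _channel_phase(ch: int, harmonic: int) -> float:
    # fixed deterministic phase table; sagittal gyro keeps zero phase so its
    # harmonics add coherently into one dominant positive peak per stride
    if ch == 3 + _SAGITTAL_GYRO:
        return 0.0
    return 2.0 * np.pi * (((ch + 1) * 0.37 + harmonic * 0.21) % 1.0)


def generate_imu(
    condition: TrialCondition,
    subject: Subject,
    location: BodyLocation,
    seed: int,
    sample_rate_hz: float = IMU_SAMPLE_RATE_HZ,
) -> IMURecording:
    """Simulate one six-axis recording for a trial and body location.

    Active portion: three-harmonic Fourier template in gait-cycle phase with
    speed- (and for lower-body locations incline-) scaled amplitude and a
    per-subject gain; accelerometer channels carry a gravity offset pitched
    by the treadmill grade; additive white noise at 5 % of the signal
    amplitude everywhere.  Standing margins contain gravity plus noise only.
    """
    location = BodyLocation(location)
    rng = np.random.default_rng(seed)

    T = int(round(condition.duration_s * sample_rate_hz))
    t = np.arange(T) / sample_rate_hz
    f = stride_frequency_hz(condition)
    accel_amp, gyro_amp = _LOC_AMP[location]

    speed_scale = 0.5 + 0.12 * condition.speed_kph
    if location in LOWER_BODY:
        speed_scale *= 1.0 + 0.05 * condition.incline_pct
    gain = _subject_gain(subject)

    sig = np.zeros((T, 6))
    active = np.zeros(T, dtype=bool)
    for (s0, s1, is_active) in _segments(condition):
        if is_active:
            active |= (t >= s0) & (t < s1)

    phase = 2.0 * np.pi * f * t
    for ch in range(6):
        base = accel_amp if ch < 3 else gyro_amp
        amp = base * _CHANNEL_REL[ch] * speed_scale * gain
        wave = np.zeros(T)
        for h, rel in enumerate(_HARMONICS, start=1):
            wave += rel * np.cos(h * phase + _channel_phase(ch, h))
        sig[:, ch] = np.where(active, amp * wave, 0.0)
        sig[:, ch] += rng.normal(0.0, 0.05 * amp, size=T)

    # gravity offset in the sensor frame, pitched by the treadmill grade
    pitch = np.arctan(condition.incline_pct / 100.0)
    sig[:, 0] += GRAVITY_M_S2 * np.sin(pitch)
    sig[:, 2] += GRAVITY_M_S2 * np.cos(pitch)

    return IMURecording(
        location=location,
        sample_rate_hz=sample_rate_hz,
        accel=sig[:, :3],
        gyro=sig[:, 3:],
    )


# ---------------------------------------------------------------------------
# protocol


def standard_conditions() -> List[TrialCondition]:
    """The eight treadmill conditions of the standard protocol."""
    walk = dict(duration_s=600.0, standing_margin_s=60.0)
    run = dict(duration_s=480.0, standing_margin_s=60.0)
    conds = [
        TrialCondition(Activity.LEVEL_WALK, 4.0, 0.0, **walk),
        TrialCondition(Activity.LEVEL_WALK, 6.0, 0.0, **walk),
        TrialCondition(Activity.LEVEL_RUN, 7.5, 0.0, **run),
        TrialCondition(Activity.LEVEL_RUN, 9.0, 0.0, **run),
    ]
    for speed in (4.0, 6.0):
        for grade in (3.0, 6.0):
            conds.append(TrialCondition(Activity.INCLINE_WALK, speed, grade, **walk))
    return conds


def _child_seed(rng: np.random.Generator) -> int:
    return int(rng.integers(0, 2**31 - 1))


def simulate_trial(
    subject: Subject,
    condition: TrialCondition,
    seed: int,
    locations: Sequence[BodyLocation] = tuple(BodyLocation),
    breath_noise_sd: float = 0.05,
) -> Trial:
    """Simulate one full trial: IMU recordings per location plus breaths."""
    rng = np.random.default_rng(seed)
    recordings = {
        BodyLocation(loc): generate_imu(condition, subject, BodyLocation(loc), _child_seed(rng))
        for loc in locations
    }
    breaths = generate_breaths(condition, subject, _child_seed(rng), noise_sd=breath_noise_sd)
    return Trial(
        subject=subject,
        condition=condition,
        recordings=recordings,
        breaths=breaths,
        latent_ee_w=latent_metabolic_rate(condition, subject),
    )


def standard_protocol(
    n_subjects: int,
    seed: int,
    locations: Sequence[BodyLocation] = tuple(BodyLocation),
    breath_noise_sd: float = 0.05,
) -> List[Trial]:
    """Simulate the full protocol: eight conditions for each subject.

    Condition order is shuffled per subject (the session order was random);
    every trial receives an independent child seed, so the whole dataset is
    a pure function of ``(n_subjects, seed, locations)``.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    rng = np.random.default_rng(seed)
    trials: List[Trial] = []
    for i in range(n_subjects):
        subject = generate_subject(_child_seed(rng), id=f"S{i + 1:02d}")
        conds = standard_conditions()
        order = rng.permutation(len(conds))
        for j in order:
            trials.append(
                simulate_trial(
                    subject, conds[j], _child_seed(rng),
                    locations=locations, breath_noise_sd=breath_noise_sd,
                )
            )
    return trials
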