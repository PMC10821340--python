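"""The two model input formats: fixed windows and normalized strides.

Cuts one simulated walking trial into (i) 2 s sliding windows at 100 Hz
and (ii) stride-segmented, length-30 inputs delimited by shank-gyro heel
strikes, and prints the resulting tensor shapes plus the detected cadence.
"""

from eewalk.gait import build_stride_set
from eewalk.preprocess import extract_windows
from eewalk.simulator import (
    Activity, BodyLocation, TrialCondition, generate_subject, simulate_trial,
    stride_frequency_hz,
)

subject = generate_subject(5, "S1")
cond = TrialCondition(Activity.LEVEL_WALK, 4.0, 0.0,
                      duration_s=600.0, standing_margin_s=60.0)
trial = simulate_trial(subject, cond, seed=8, locations=[BodyLocation.SHANK])

windows = extract_windows(trial, BodyLocation.SHANK, seq_time_s=2.0, fs=100.0, hop_s=1.0)
print(f"windows: x{windows.x.shape}, target {windows.y_w[0]:.1f} W per window")
print("  (240 s steady interval, 2 s windows every 1 s -> 239 windows of 200 samples)")

strides = build_stride_set(trial, BodyLocation.SHANK, fs=100.0)
detected = len(strides) / 240.0
programmed = stride_frequency_hz(cond)
print(f"strides: x{strides.x.shape}")
print(f"  detected cadence {detected:.3f} strides/s vs programmed {programmed:.3f} "
      f"({100*abs(detected-programmed)/programmed:.1f} % off)")
print("Both formats carry the same steady-state EE target and subject features.")
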