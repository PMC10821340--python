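# Methods

## Problem

`eewalk` estimates steady-state metabolic energy expenditure (EE, watts)
during treadmill walking and running from six-axis IMU signals.  The
task: subjects wear IMUs on the chest, right wrist, thigh, shank
and foot (100 Hz) while breath-by-breath VO₂/VCO₂ is recorded by indirect
calorimetry; a regression model maps a short window of inertial data plus
the subject's weight and height to the steady-state EE, and generalization
is measured by leave-one-subject-out (LOSO) cross-validation with NRMSE
(W/kg, RMSE normalized by body weight) and MAPE (%).

Because datasets of this kind are typically private, the package ships a
synthetic generator that emulates the study conditions end to end, so every
pipeline stage is exercised and tested without any download.

## Ground truth: indirect calorimetry

Breath-by-breath gas exchange is converted to watts with the Brockway
equation using the standard energy equivalents of O₂ and CO₂,

    EE_W = (16.58 · VO₂ + 4.51 · VCO₂) / 60,    VO₂, VCO₂ in mL/min,

with the urinary-nitrogen term omitted (its contribution is below the
noise floor of breath-by-breath measurement).  The per-trial ground truth
is the arithmetic mean of breath-wise EE over the **last four minutes of
activity**: each trial ends with one minute of quiet standing, so the
240 s window is anchored at `duration − standing_margin` (minute 5–9 of a
10-min walking trial, minute 3–7 of an 8-min running trial).  The window is
half-open `[start, end)` to avoid double counting at boundaries.  Breaths
are averaged as sampled; no interpolation onto a uniform grid is applied
(the plateau is flat, so the irregular sampling is unbiased).

## Synthetic protocol

`simulator.standard_protocol` reproduces the study conditions: per subject,
eight treadmill trials in shuffled order — level walking at 4 and 6 KPH,
level running at 7.5 and 9 KPH, inclined walking at 4 and 6 KPH on 3 % and
6 % grades; 10-min walking and 8-min running trials with 60 s standing
margins.  Subjects are drawn from the cohort anthropometrics (weight
N(72.8, 6.3) kg clipped to (50, 100), height N(1.73, 0.06) m clipped to
(1.5, 2.0)).

**Metabolic truth.** The latent plateau uses ACSM-style gross VO₂
equations — walking `3.5 + 0.1·v + 1.8·v·g`, running `3.5 + 0.2·v +
0.9·v·g` mL/kg/min (v in m/min, g fractional grade), standing 3.5 —
converted to watts through Brockway at a fixed respiratory exchange ratio
of 0.85.  An experimental study *measures* EE rather than modelling it; any
smooth plateau that is monotone in speed and grade would do for
parameter-recovery testing, and the ACSM forms keep values physiologic
(≈240 W at 4 KPH to ≈800 W at 9 KPH for a 73-kg subject).

**Breath dynamics.** Breath intervals are N(3.0, 0.5) s truncated above
1 s.  VO₂ follows first-order exponential kinetics with a 30 s time
constant toward the current segment's plateau (standing ↔ activity), the
typical scale of VO₂ on-kinetics; 240 s into activity the signal is 8 time
constants deep, so the ground-truth window sees a settled plateau.
Multiplicative Gaussian noise (relative sd 5 %) is applied per breath;
VCO₂ = 0.85 · VO₂.

**IMU signal model.** Per location, each of the six channels is a
three-harmonic Fourier series in gait-cycle phase.  Step rate grows
affinely with speed (1.4 + 0.25·v steps/s walking, 2.4 + 0.1·v running; a
stride is two steps), which keeps every protocol condition's stride
duration inside the physiologic 0.5–2.0 s band.  Amplitudes scale affinely
with speed and, for lower-body locations, with incline; a per-subject gain
in [0.9, 1.1] adds between-subject variation; accelerometer channels carry
a gravity offset pitched by the treadmill grade; additive white noise at
5 % of the signal amplitude covers the whole trial, and the standing
margins contain gravity plus noise only (the pipeline never looks at
static segments, so a postural-sway model would add nothing).  The shank
sagittal gyro channel (gy) keeps zero harmonic phase so its harmonics add
into one dominant positive mid-swing peak per stride — the feature the
gait detector keys on.

What the generator does **not** emulate: soft-tissue artifact, sensor
misalignment, stride-to-stride timing variability, asymmetric gait,
fatigue drift, overground or speed-varying locomotion.  Passing tests
therefore demonstrate that the pipeline's machinery (filtering, windowing,
segmentation, training, LOSO bookkeeping) recovers structure it is
designed for — not that the trained networks would reach the same accuracy
on human data.

## Preprocessing

Order is fixed: **filter → resample → window**.  Filtering is a zero-phase
(forward–backward) 4th-order Butterworth low-pass at 6 Hz per channel, the
offline biomechanics convention; the effective magnitude response is the
square of the single-pass design, |H(f)|² = 1/(1 + (f/6)⁸), i.e. −6 dB at
the cutoff, and tests assert exactly that.  Resampling to 60/80/100 Hz
uses linear interpolation — with the band limited to 6 Hz and the lowest
Nyquist at 30 Hz the interpolation error is negligible (tested < 1 % on a
2 Hz tone).  Windows of 2/4/6 s are cut only inside the steady-state
interval, every `hop_s` (default 1 s; the overlap is a free parameter and
configurable), and every window inherits the trial's ground-truth EE as
target.  IMU channels are standardized per channel; the EE target and the
two subject features are min–max normalized to [0, 1].  Scalers are fitted
on the training fold only and travel with the model; out-of-range test
values are deliberately not clipped.

## Gait segmentation (stride-MLP input)

Heel strikes come from the shank gyro's sagittal channel, chosen as the
gyro axis with maximal variance during the active period (no hard-coded
axis convention).  Mid-swing candidates are local maxima above
0.6 × the 95th percentile of the signal **and** above an absolute floor of
1 rad/s, separated by ≥ 0.5 s; the relative threshold adapts across
speeds, while the absolute floor (mid-swing shank angular velocity during
gait is several rad/s) keeps a purely adaptive rule from firing on
quiet-standing noise.  The heel strike is the first interior local minimum
after each peak within half the median peak spacing; if noise leaves no
interior minimum the minimum sample of that window is used, making the
detector total.  Strides with duration outside 0.5–2.0 s are discarded.
Whatever location is being segmented, boundaries always come from the
shank.  Each stride is resampled per channel onto 30 equally spaced phase
points including both endpoints, which makes the resampler exact on affine
signals (tested to 1e-9).

## Models

All four architectures share one contract: input array plus two subject
features → one scalar EE in normalized target space, with the features
concatenated immediately after the flatten.

- **CNN–LSTM** (primary): 1D conv 6→64, kernel 3, stride 1, valid →
  1D max pool, kernel 3, stride 1 → LSTM(64) → LSTM(64) → flatten the full
  hidden sequence → concat features → linear head.  For a 200-sample
  window: conv 198, pool 196, flatten 196·64 = 12544, head input 12546.
- **CNN baseline**: three conv+pool blocks (64 @ k3), flatten, head.
- **LSTM baseline**: three LSTM(64) layers, flatten, head.
- **Stride-MLP baseline**: flatten(30×6) + 2 features = 182 → three
  400-unit ReLU layers → linear head.

Choices where the contract was open: valid (no-padding) convolutions keep
every length testable in closed form; pooling is channel-wise over the 64
conv channels (pooling has no weights); the flatten consumes the **full**
LSTM output sequence, not only the final hidden state; the head is linear
(regression in [0, 1] target space); no activation is inserted between
conv and pool (the LSTM stack provides the nonlinearity); dropout 0.5 sits
between the two LSTM layers and between the flatten and the head (for the
CNN and LSTM baselines, in the analogous positions), and the MLP trains
without dropout.

The networks are implemented in a small numpy engine (`eewalk._nn`):
float32 forward/backward for conv, pool, LSTM (full backpropagation
through time, input projections batched into single GEMMs, the recurrence
optionally JIT-compiled with numba), dense, ReLU, dropout, and Adam.
Parameter counts are asserted in closed form (e.g. conv: 6·3·64 + 64 =
1216), and LSTM gradients are validated against directional finite
differences.

## Training

Loss = MSE(normalized prediction, normalized target) + `l2_coeff` ·
Σ(kernel weights²); biases are not regularized.  Optimizer is Adam
(0.9/0.999/1e-8) with one-cycle scheduling: cosine warm-up from
`max_lr/div_factor` to the peak over the first `pct_start` of all steps,
then cosine annealing to `max_lr/final_div_factor`.  Fixed by the
model family: peak learning rate 0.001 and the 100-epoch budget.
Remaining knobs are package defaults: batch 64, `l2_coeff` 1e-4,
`pct_start` 0.3, `div_factor` 25, `final_div_factor` 1e4, no early
stopping.  Minibatch order and dropout masks derive from one seeded
Generator, so runs are bit-reproducible per platform (cross-platform,
final losses agree to ~1e-5).

## Evaluation

LOSO: one fold per subject; scalers and parameters of a fold depend only
on its training subjects.  Metrics pool all test windows/strides of the
held-out subject (per-trial means are reported alongside); NRMSE is
normalized by the held-out subject's weight, and cells that aggregate
folds average per-fold values, preserving the per-subject normalization
semantics.  Dataset definitions: D1 = level + inclined walking,
D2 = level walking + running, D3 = everything.
`evaluate.run_experiment_grid` runs any cross-product of datasets ×
locations × architectures × (sequence time, sampling rate) cells,
recording failed cells without aborting the grid.

## Desk-scale problem sizes

The full grid (3 datasets × 5 locations × 4 architectures × 9 input
formats × 7 folds × 100 epochs) is an overnight computation.  The shipped
tests and `scripts/acceptance.py` run a reduced study chosen once as the
package's desk-scale configuration: 7 subjects × 8 conditions, shank only,
2 s @ 100 Hz windows with a 4 s hop (60 windows per trial), the first two
LOSO folds, 12 epochs for the CNN–LSTM and 20 for the stride-MLP.  The
thresholds these runs are held to (held-out MAPE < 15 %, ≥ 2× better than
an untrained network in the identical harness, per-condition rank
correlation ≥ 0.9, MLP MAPE < 20 %) are unchanged by the down-scaling —
fewer epochs and sparser windows make them harder, not easier.  On the
synthetic task the trained CNN–LSTM typically lands near 6 % MAPE /
0.5 W/kg with an untrained ratio above 5, and the stride-MLP near 3 %.

## Known limitations

- The IMU templates are spectrally simple; models may exploit regularities
  (exact periodicity, stationary noise) real signals lack.
- Stride-to-stride variability is absent, so stride segmentation is easier
  than on human data.
- The EE plateau depends deterministically on (condition, weight); with a
  5 % breath noise floor, very low errors are attainable in-silico.
- Only steady-state EE is defined; transitions and time-varying conditions
  are out of scope.
- Standing margins carry no sway signal, so static-state classification is
  not a meaningful task on this generator.
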