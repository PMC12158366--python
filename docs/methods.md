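# Methods

## Problem setting

During walking, each lower-leg muscle's surface EMG activity precedes
its mechanical effect on plantar pressure by an electromechanical delay
(EMD) of roughly 0.1–0.7 s, depending on muscle, task phase and subject.
`emg2press` estimates these delays, aligns the signals, and learns a
sequence-to-sequence mapping from EMG activation features to the four
plantar pressure channels, from which the gait events heel strike (HS),
mid-stance (MST) and toe off (TO) can be read in real time.

## Synthetic gait generator

The generator produces a statistical emulation of a four-muscle /
four-FSR acquisition, not a musculoskeletal simulation. Its purpose is
to provide recordings with *known* ground truth (event times, clean
activation envelopes, planted EMDs) whose second-order structure —
timing, bandwidths, rates, noise — matches the real setup.

**Cycle structure.** Each gait cycle of duration `C` (default 1.1 s, a
typical self-selected cadence; the true cadence of any given cohort is
unknown, so this is exposed in `GaitParams`) is divided into stance
(default 60%) and swing. Event fractions default to HS 0.00, FF 0.10,
MST 0.30, HO 0.45, TO 0.60.

**Pressure.** Each channel is a train of raised-cosine (Hann) bumps,
one per cycle: heel loading just after HS, two midfoot bumps placed
symmetrically about MST (the lateral one 0.025·stance·C earlier —
the lateral column loads first, then weight transfers medially, and the
symmetry makes the summed-midfoot maximum coincide with the MST event),
and a toe bump peaking before TO. Heel and toe bump widths are sized so
that the region where either exceeds 5% of its peak tiles exactly
[HS, TO]: the measured ground-contact fraction therefore equals the
stance fraction (60%) by construction, and the package verifies this
rather than assuming it. Channels 2–4 are emitted at their native
148 Hz; channel 1 (heel) at 1926 Hz. A small constant baseline (0.02)
and sensor noise (σ = 0.003, clipped at zero) are added.

**Muscle activation.** Each muscle's clean envelope is a bump train
anchored to the same per-cycle event anchors as its paired pressure
channel: TA to heel loading (plus a swing-phase dorsiflexion burst for
foot clearance, centred midway between consecutive heel loads), and
FL/SOL/GA to push-off. GA matches the toe-bump shape exactly (the
sharp plantarflexion burst), SOL is broader (half-width 0.45·stance·C),
FL broader still (0.36·stance·C support placed mid-to-late stance,
consistent with published peroneus longus EMG profiles of ~10–50% of
the cycle). Sharing anchors between a muscle and its paired pressure
bump is what makes the planted EMD the exact argmax of their
cross-correlation — a property the test suite relies on.

**EMD planting.** The EMG envelope of channel *c* is the activation
envelope evaluated at `t − emd_c` (delays are negative, so the EMG
content appears *earlier* than the pressure it drives). Defaults span
the physiological range (−0.096 … −0.687 s), and `SUBJECT_EMD_PRESETS`
provides four per-subject delay sets used to give synthetic subjects
distinct neuromechanical timing.

**EMG synthesis.** Envelope × carrier + mains + noise. The carrier is
white Gaussian noise zero-phase band-passed to 20–450 Hz and scaled to
unit mean absolute value, so rectification + 10 Hz smoothing of the
modulated carrier recovers the envelope with unit gain. Mains is a
50 Hz sinusoid with random phase (amplitude 0.1 in envelope units by
default); baseline noise is white with power set by `carrier_snr`
(default 10 dB, "moderate noise").

**Variability.** Per-cycle amplitude jitter is multiplicative
(σ = `envelope_jitter`, default 5%); timing jitter is additive on the
per-cycle anchors with σ = `envelope_jitter`·0.4·C (≈22 ms, a 2%
stride-time CV typical of healthy gait), clipped at ±7% of C to
preserve event ordering. Timing jitter is *shared* between a pressure
bump and the muscle bumps anchored to it, so gait variability never
blurs the planted delay. Aperiodicity matters beyond realism: for a
strictly periodic recording the cross-correlation has alias peaks one
cycle away from the true delay that tie with it exactly; ~2% stride
variability separates them decisively.

**What the generator does not emulate** — and hence what passing tests
do not show about real data: motor-unit structure and EMG
non-stationarity within a burst, crosstalk between electrode sites,
load-dependent FSR nonlinearity, electrode-skin impedance drift,
fatigue, double support asymmetries, and pathological gait. Results on
synthetic data bound the method's behaviour under the stated noise
model only.

## Preprocessing

EMG: 4th-order Butterworth band-pass 20–450 Hz → IIR notch at 50 Hz
(Q = 30, ≈1.7 Hz width) → full-wave rectification → 4th-order 10 Hz
low-pass (linear envelope, clipped at 0) → per-channel min–max to
[0, 1]. FSR: 4th-order 20 Hz low-pass → baseline subtraction (5th
percentile, robust to contact spikes; clipped at 0) → min–max. All
filters run forward–backward (`filtfilt`), hence zero-phase: any group
delay here would bias the EMD estimates, and a property test asserts
the cross-correlation peak of input vs. filtered broadband noise sits
at lag zero.

All channels end on a common 1926 Hz grid (the native EMG rate). The
low-rate FSR channels are upsampled by cubic spline rather than by
linear interpolation: their content is ~10–20 Hz against a 74 Hz
Nyquist, and the spline's reconstruction error is negligible where
linear interpolation leaves grid-phase-dependent distortion large
enough to perturb sub-millisecond lag estimation on broad correlation
peaks. Min–max normalization (rather than MVC normalization) is used
because no maximal-contraction calibration exists in this protocol.

## EMD estimation and alignment

For each calibration pairing the delay is the argmax over lags
τ ∈ [−1 s, +1 s] of the Pearson correlation between the overlapping
segments of the mean-removed pair (all per-lag means/variances from
cumulative sums; FFT cross-correlation for the numerator). Sign
convention: negative lag = EMG leads. Ties within numerical tolerance
break toward the smallest |lag|. Constant (dead) channels raise an
undefined-correlation error rather than returning 0.

Calibration pairings follow the muscles' mechanical roles: FL, SOL, GA
against toe pressure (plantarflexion), TA against heel pressure
(dorsiflexion) and against medial midfoot pressure (inversion). The
predictive dataset applies per-channel shifts from each channel's
*primary* pairing (TA↔heel, FL/SOL/GA↔toe); the inversion pairing is
diagnostic only, and with a ±1 s search on short recordings its broad
secondary-activation correlation can legitimately lock onto a
one-cycle alias, which is why it is reported but never used for
alignment. Pairs with peak correlation below 0.3 are flagged
incompatible.

Accuracy, measured by the test suite: with ≥25-cycle noiseless
fixtures every planted delay in the −0.096 … −0.687 s range is
recovered within ±1 sample at 1926 Hz; at 10 dB carrier SNR with the
full preprocessing chain, within ±10 ms in ≥95% of 100 seeded trials.
Finite recordings do carry an O(1/n_cycles) edge bias (the first
cycle's EMD-advanced activation is truncated at the recording start),
which is why the exactness fixtures use 25 cycles.

## Features and dataset

200-sample windows, 75% overlap (stride 50), RMS per window per
channel, computed on the normalized envelopes (the alternative —
RMS of the raw band-passed signal — is equivalent up to the envelope's
normalization and smoothing and is not separately exposed). Targets
default to the window-center sample of each FSR channel
(`window_mean` is available); the center preserves timing symmetry
with the RMS feature. One recording = one training sequence; window
count follows `floor((N − 200)/50) + 1`, checked against brute-force
enumeration.

## GRU regressor

Reset-after GRU (separate input and recurrent biases — the convention
whose count is 3·(D·H + H² + 2H); the fused-bias alternative would
give 13,248 parameters instead of 13,440), 64 units, full-sequence
output, ReLU on the outputs, inverted dropout 0.4 during training,
shared per-timestep dense head with linear output. Outputs are left
linear and clipped to [0, 1] only in `predict`; evaluation metrics use
the raw outputs. Initialization: Glorot-uniform kernels, orthogonal
recurrent blocks, zero biases. Adam (β₁ 0.9, β₂ 0.999, ε 1e-8),
learning rate 5e-4, fixed 200 epochs in the full protocol with no
early stopping; the demo profile uses 30 epochs. Gradients are exact
BPTT, validated against central finite differences to ~1e-9 relative
error. A non-finite loss aborts with a diagnostic rather than being
silently clipped. Both end-of-training and best-epoch losses are
reported, since either can be the quantity of record.

Training determinism: parameter initialization, dropout masks and data
order are all derived from the config seed, so identical seeds
reproduce runs bit-for-bit.

The sensor-ablation scaffold retrains the model per EMG-channel subset
and reports validation MAE and relative change versus the four-sensor
baseline; single-sensor degradation is reported, not hard-asserted,
because its size depends on the co-activation structure of the data.

## Event inference

On normalized pressure sequences: HS = upward crossing of the heel
channel through 0.2 with a 150 ms refractory period; TO = first
downward crossing of the toe channel through 0.2 after the toe peak of
the cycle; MST = maximum of the summed midfoot channels between them;
cycles that cannot be ordered HS < MST < TO are dropped. Thresholds
are configurable; 0.2 trades noise immunity against a bounded
systematic offset (~±30 ms on clean signals) from detecting partway up
the contact edge. Detected indices are converted to seconds with the
sequence's time origin — for windowed predictions the first window's
*center*, an offset of ~52 ms that would otherwise dominate the error
budget. On the demo benchmark the pooled median |error| versus planted
truth is ~20–40 ms, under two window strides.

## Problem sizes

Defaults were chosen so the full suite and the acceptance script run
comfortably on a single CPU: demo pipeline 4 subjects × 20 cycles ×
30 epochs (~4 s); held-out-MAE protocol 4 subjects × 20 cycles ×
200 epochs, three runs, median (~90 s); EMD exactness fixtures
25 cycles; noise-robustness 100 trials × 10 cycles. Larger sizes only
sharpen the estimates.

## Known limitations

- The EMD is assumed constant within a recording; cycle-by-cycle delay
  variation (and hence dynamic alignment such as DTW) is out of scope.
- Min–max normalization ties the pressure scale to each recording's
  own extremes; absolute pressure is not modelled.
- The event rules are threshold crossings with fixed defaults; on
  signals with baselines near the threshold they will chatter, and the
  refractory period is the only guard.
- The NumPy trainer is single-threaded batch-1 BPTT; it is sized for
  this problem (13.7k parameters, sequences of ~10³ steps), not for
  larger architectures.
- Synthetic validation bounds behaviour only under the generator's
  noise model (see above); no claim transfers to clinical populations.
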