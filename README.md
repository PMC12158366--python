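# emg2press

Estimating plantar pressure from surface EMG during walking.

Lower-leg muscles activate a reproducible fraction of a second *before*
the forces they produce appear under the foot. `emg2press` implements a
complete pipeline that exploits this: it conditions four-channel surface
EMG (tibialis anterior, fibularis longus, soleus, gastrocnemius) and
four-channel force-sensitive-resistor (FSR) pressure recordings (heel,
medial/lateral midfoot, toe), measures each muscle's electromechanical
delay (EMD) by normalized cross-correlation, extracts sliding-window RMS
features, and trains a compact GRU sequence regressor that maps muscle
activation to the four normalized pressure channels. Predicted pressure
waveforms then serve as real-time surrogates for the gait events —
heel strike (HS), mid-stance (MST), toe off (TO) — that an active
ankle–foot orthosis must synchronize with.

Because gait lab recordings of this kind are rarely shared, the package
ships a first-class synthetic gait generator with known ground truth
(event times, clean activation envelopes, planted EMDs), so every stage
is testable end to end.

## The model

Input sequences are RMS values over 200-sample windows with 75% overlap
(stride 50 at 1926 Hz, one 4-vector every ~26 ms), computed from
band-passed (20–450 Hz), notch-filtered (50 Hz), rectified, 10 Hz
low-pass smoothed and min–max normalized EMG envelopes, each envelope
first delayed by its channel's estimated EMD. Targets are the four FSR
channels, 20 Hz low-passed, baseline-corrected and normalized to [0, 1].

The regressor is a single GRU layer (64 units, full sequence output,
reset-after gating with separate input/recurrent biases) followed by
ReLU, dropout 0.4 (training only) and a per-timestep linear dense layer
with 4 outputs:

    GRU:   3 × (4·64 + 64² + 2·64) = 13,440 parameters
    Dense: 64·4 + 4               =    260 parameters
    total                         = 13,700 trainable parameters

Training minimizes MSE with Adam (lr 5·10⁻⁴), batch size 1 (one whole
recording per optimizer step, preserving sequence integrity), MAE as the
evaluation metric. The implementation is pure NumPy with exact
backpropagation through time, verified against finite differences.

EMD estimation: for an EMG envelope `e` and pressure `p` at a common
rate, the delay is `argmax_τ corr(e(t), p(t+τ))` over τ ∈ [−1 s, +1 s],
each lag scored by the Pearson correlation of the overlapping segments.
Negative lags mean the muscle leads the pressure; during gait the
recovered delays fall around −0.1 … −0.7 s depending on muscle and
subject.

## Worked example

```python
import emg2press as ep

result = ep.run_pipeline(ep.PipelineConfig(seed=0))
print(result.summary["validation"])
print(result.summary["median_event_timing_error_s"])
```

The demo profile simulates four synthetic subjects (20 cycles each,
10 dB carrier SNR, 5% gait variability, subject-specific EMDs), trains
on three for 30 epochs and validates on the fourth, printing

```
{'mse': 0.022953548454765344, 'mae': 0.09197721487318075}
0.02106864099300587
```

— a held-out normalized-pressure MAE of 0.092 and a median gait-event
timing error of ~21 ms (under one window stride). Training for the full
200-epoch protocol brings the held-out MAE to ~0.04. The per-subject
compatibility report for the first subject reads

```
FL  <-> toe   lag -0.626 s  corr 0.978
SOL <-> toe   lag -0.112 s  corr 0.947
GA  <-> toe   lag -0.625 s  corr 0.987
TA  <-> heel  lag -0.108 s  corr 0.815
```

recovering the planted delays (−0.626, −0.112, −0.623, −0.108 s) to
within ~2 ms under 10 dB carrier noise, with the gastrocnemius showing
the sharpest, strongest coupling to toe pressure — the signature of
plantarflexion at push-off.

The same stages are scriptable from the shell:

```
emg2press simulate --seed 3 --cycles 20 --out rec/
emg2press align --in rec/ --out emd.json
emg2press featurize --in rec/ --emd emd.json --out feat/
emg2press train --x feat/X.csv --y feat/Y.csv --out run/
emg2press run --seed 0 --out demo/
```

## Layout

- `emg2press.synthetic` — gait generator, ground truth, CSV/JSON persistence
- `emg2press.preprocess` — filter chains, normalization, resampling
- `emg2press.emd` — delay estimation, alignment, compatibility report
- `emg2press.windows` — sliding-window RMS features and datasets
- `emg2press.gru` — the NumPy GRU regressor, training, evaluation, ablation
- `emg2press.pipeline` — orchestration and gait-event detection
- `docs/methods.md` — modelling assumptions, parameter choices, limitations
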