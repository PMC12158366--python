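"""Conditioning of raw sEMG and FSR traces onto a common normalized grid.

EMG chain: 20–450 Hz band-pass → 50 Hz notch → full-wave rectification →
linear-envelope smoothing (10 Hz low-pass) → per-channel min–max
normalization to [0, 1].  FSR chain: 20 Hz low-pass → baseline
correction (5th-percentile subtraction, clipped at 0) → min–max
normalization.  All filters are 4th-order Butterworth (the notch an IIR
biquad) applied forward–backward, so the chain is zero-phase — group
delay here would bias the downstream electromechanical-delay estimates.
Finally every channel is linearly interpolated onto a common grid at
``target_rate`` (default 1926 Hz, the native EMG rate, so the low-rate
FSR channels are upsampled).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.signal import butter, filtfilt, iirnotch, sosfiltfilt

from .signals import SignalTrace
from .synthetic import EMG_CHANNELS, FSR_CHANNELS, GaitRecording

__all__ = [
    "PreprocessConfig",
    "EnvelopeSet",
    "bandpass",
    "lowpass",
    "notch",
    "rectify",
    "envelope",
    "baseline_correct",
    "normalize01",
    "resample",
    "preprocess_recording",
]


@dataclass
class PreprocessConfig:
    emg_band: tuple[float, float] = (20.0, 450.0)
    notch_freq: float = 50.0
    notch_q: float = 30.0            # ~1.7 Hz -3 dB width at 50 Hz
    envelope_lowpass: float = 10.0
    fsr_lowpass: float = 20.0
    filter_order: int = 4
    baseline_percentile: float = 5.0
    target_rate: float = 1926.0

    def validate(self, rate: float | None = None) -> None:
        low, high = self.emg_band
        if not 0 < low < high:
            raise ValueError(f"emg_band cutoffs must satisfy 0 < low < high, got {self.emg_band}")
        for name in ("notch_freq", "envelope_lowpass", "fsr_lowpass", "target_rate"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.filter_order < 1:
            raise ValueError("filter_order must be >= 1")
        if rate is not None and high >= rate / 2:
            raise ValueError(f"emg_band high cutoff {high} Hz >= Nyquist ({rate / 2} Hz)")


@dataclass
class EnvelopeSet:
    """Normalized EMG envelopes and FSR pressures on one common grid."""

    emg_env: dict[str, np.ndarray]
    fsr_norm: dict[str, np.ndarray]
    target_rate: float

    def __post_init__(self) -> None:
        lengths = {len(v) for v in self.emg_env.values()} | \
                  {len(v) for v in self.fsr_norm.values()}
        if len(lengths) != 1:
            raise ValueError(f"traces of unequal length: {sorted(lengths)}")

    @property
    def n_samples(self) -> int:
        return len(next(iter(self.emg_env.values())))

    def emg_trace(self, ch: str) -> SignalTrace:
        return SignalTrace(self.emg_env[ch], self.target_rate, ch)

    def fsr_trace(self, ch: str) -> SignalTrace:
        return SignalTrace(self.fsr_norm[ch], self.target_rate, ch)


def bandpass(trace: SignalTrace, low: float, high: float, order: int = 4) -> SignalTrace:
    """Zero-phase Butterworth band-pass; length and rate preserved."""
    if not 0 < low < high:
        raise ValueError(f"need 0 < low < high, got ({low}, {high})")
    if high >= trace.rate / 2:
        raise ValueError(f"high cutoff {high} Hz >= Nyquist ({trace.rate / 2} Hz)")
    sos = butter(order, [low, high], btype="bandpass", fs=trace.rate, output="sos")
    return trace.with_samples(sosfiltfilt(sos, trace.samples))


def lowpass(trace: SignalTrace, cutoff: float, order: int = 4) -> SignalTrace:
    """Zero-phase Butterworth low-pass."""
    if not 0 < cutoff < trace.rate / 2:
        raise ValueError(f"cutoff {cutoff} Hz outside (0, Nyquist={trace.rate / 2}) Hz")
    sos = butter(order, cutoff, btype="lowpass", fs=trace.rate, output="sos")
    return trace.with_samples(sosfiltfilt(sos, trace.samples))


def notch(trace: SignalTrace, freq: float = 50.0, q: float = 30.0) -> SignalTrace:
    """Zero-phase IIR notch removing a narrow mains line."""
    if not 0 < freq < trace.rate / 2:
        raise ValueError(f"notch frequency {freq} Hz outside (0, Nyquist={trace.rate / 2}) Hz")
    b, a = iirnotch(freq, q, fs=trace.rate)
    return trace.with_samples(filtfilt(b, a, trace.samples))


def rectify(trace: SignalTrace) -> SignalTrace:
    return trace.with_samples(np.abs(trace.samples))


def envelope(trace: SignalTrace, cutoff: float = 10.0, order: int = 4) -> SignalTrace:
    """Linear envelope: low-pass the rectified signal, clip filter ringing at 0."""
    out = lowpass(trace, cutoff, order)
    return out.with_samples(np.maximum(out.samples, 0.0))


def baseline_correct(trace: SignalTrace, percentile: float = 5.0) -> SignalTrace:
    """Subtract a robust baseline (5th percentile) and clip at 0."""
    base = np.percentile(trace.samples, percentile)
    return trace.with_samples(np.maximum(trace.samples - base, 0.0))


def normalize01(trace: SignalTrace) -> SignalTrace:
    """Min–max scale to [0, 1]; a constant trace maps to all zeros."""
    x = trace.samples
    lo, hi = x.min(), x.max()
    if hi == lo:
        return trace.with_samples(np.zeros_like(x))
    return trace.with_samples((x - lo) / (hi - lo))


def resample(trace: SignalTrace, target_rate: float) -> SignalTrace:
    """Interpolation onto a uniform grid spanning the original times.

    Uses a cubic spline (falling back to linear for traces shorter than four
    samples).  The low-rate FSR channels carry only ~10–20 Hz content, well
    inside their 74 Hz Nyquist band, and the spline's reconstruction error is
    orders of magnitude below linear interpolation's — linear upsampling
    leaves grid-phase-dependent waveform distortion large enough to bias
    sub-millisecond delay estimation on broad correlation peaks.
    """
    if target_rate <= 0:
        raise ValueError(f"target_rate must be positive, got {target_rate}")
    if len(trace) < 2:
        raise ValueError("cannot resample a trace with fewer than 2 samples")
    if target_rate == trace.rate:
        return trace
    t_old = trace.times()
    n_new = int(np.floor(t_old[-1] * target_rate)) + 1
    t_new = np.arange(n_new) / target_rate
    if len(trace) < 4:
        out = np.interp(t_new, t_old, trace.samples)
    else:
        out = CubicSpline(t_old, trace.samples)(t_new)
    return trace.with_samples(out, rate=target_rate)


def preprocess_recording(rec: GaitRecording,
                         cfg: PreprocessConfig | None = None) -> EnvelopeSet:
    """Run the full EMG and FSR conditioning chains onto the common grid."""
    cfg = cfg or PreprocessConfig()
    emg_env: dict[str, np.ndarray] = {}
    fsr_norm: dict[str, np.ndarray] = {}

    for ch in EMG_CHANNELS:
        tr = rec.emg[ch]
        try:
            cfg.validate(rate=tr.rate)
            tr = bandpass(tr, *cfg.emg_band, order=cfg.filter_order)
            tr = notch(tr, cfg.notch_freq, cfg.notch_q)
            tr = rectify(tr)
            tr = envelope(tr, cfg.envelope_lowpass, cfg.filter_order)
            tr = normalize01(tr)
            tr = resample(tr, cfg.target_rate)
        except Exception as exc:
            raise type(exc)(f"EMG channel {ch}: {exc}") from exc
        emg_env[ch] = np.clip(tr.samples, 0.0, 1.0)   # spline overshoot guard

    for ch in FSR_CHANNELS:
        tr = rec.fsr[ch]
        try:
            tr = lowpass(tr, cfg.fsr_lowpass, cfg.filter_order)
            tr = baseline_correct(tr, cfg.baseline_percentile)
            tr = normalize01(tr)
            tr = resample(tr, cfg.target_rate)
        except Exception as exc:
            raise type(exc)(f"FSR channel {ch}: {exc}") from exc
        fsr_norm[ch] = np.clip(tr.samples, 0.0, 1.0)  # spline overshoot guard

    n = min(min(len(v) for v in emg_env.values()),
            min(len(v) for v in fsr_norm.values()))
    emg_env = {c: v[:n] for c, v in emg_env.items()}
    fsr_norm = {c: v[:n] for c, v in fsr_norm.items()}
    return EnvelopeSet(emg_env=emg_env, fsr_norm=fsr_norm, target_rate=cfg.target_rate)
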