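"""Sliding-window RMS features and the supervised sequence dataset.

The envelopes are segmented into 200-sample windows with 75% overlap
(stride 50 at the 1926 Hz grid, i.e. ~26 ms between feature vectors).
Each window yields one 4-dimensional RMS feature vector (order TA, FL,
SOL, GA) paired with the 4 normalized FSR pressures (order heel,
midfoot_medial, midfoot_lateral, toe) sampled at the window center.  A
whole recording becomes one training sequence.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .emd import EMDTable, PRIMARY_PAIRING, apply_shift
from .preprocess import EnvelopeSet
from .synthetic import EMG_CHANNELS, FSR_CHANNELS

__all__ = [
    "WindowConfig",
    "WindowedDataset",
    "sliding_windows",
    "rms",
    "build_dataset",
    "channel_subset",
]


@dataclass
class WindowConfig:
    window_len: int = 200
    overlap: float = 0.75
    target_mode: str = "window_center"   # or "window_mean"

    def __post_init__(self) -> None:
        if self.window_len < 1:
            raise ValueError(f"window_len must be >= 1, got {self.window_len}")
        if not 0.0 <= self.overlap < 1.0:
            raise ValueError(f"overlap must lie in [0, 1), got {self.overlap}")
        if self.target_mode not in ("window_center", "window_mean"):
            raise ValueError(f"unknown target_mode {self.target_mode!r}")
        if self.stride < 1:
            raise ValueError("stride rounds to 0; decrease overlap or enlarge window")

    @property
    def stride(self) -> int:
        return int(round(self.window_len * (1.0 - self.overlap)))


@dataclass
class WindowedDataset:
    X: np.ndarray                 # (T, n_features) RMS values
    Y: np.ndarray                 # (T, 4) pressure targets
    window_times: np.ndarray      # (T,) window-center times, seconds
    feature_channels: tuple[str, ...] = EMG_CHANNELS
    target_channels: tuple[str, ...] = FSR_CHANNELS
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (len(self.X) == len(self.Y) == len(self.window_times)):
            raise ValueError("X, Y and window_times must have equal length")
        if not (np.all(np.isfinite(self.X)) and np.all(np.isfinite(self.Y))):
            raise ValueError("dataset contains non-finite values")

    def __len__(self) -> int:
        return len(self.X)


def sliding_windows(n_samples: int, cfg: WindowConfig) -> list[tuple[int, int]]:
    """Half-open [start, start + window_len) ranges at stride spacing.

    The trailing partial window is dropped, so the count is
    ``floor((n_samples - window_len) / stride) + 1``.
    """
    if n_samples < cfg.window_len:
        raise ValueError(f"trace of {n_samples} samples is shorter than one "
                         f"{cfg.window_len}-sample window: empty dataset")
    count = (n_samples - cfg.window_len) // cfg.stride + 1
    return [(i * cfg.stride, i * cfg.stride + cfg.window_len) for i in range(count)]


def rms(window: np.ndarray) -> float:
    """Root mean square, sqrt(mean(x^2))."""
    window = np.asarray(window, dtype=np.float64)
    if window.size == 0:
        raise ValueError("rms of an empty window is undefined")
    return float(np.sqrt(np.mean(window * window)))


def _windowed_rms(x: np.ndarray, spans: list[tuple[int, int]], window_len: int,
                  stride: int) -> np.ndarray:
    # vectorized RMS over all placements via a strided view
    view = np.lib.stride_tricks.sliding_window_view(x, window_len)[::stride]
    view = view[: len(spans)]
    return np.sqrt(np.mean(view * view, axis=1))


def build_dataset(env: EnvelopeSet, emd: EMDTable | None, cfg: WindowConfig,
                  provenance: dict | None = None) -> WindowedDataset:
    """Build the supervised sequence dataset from a preprocessed recording.

    If an EMD table is given, each EMG envelope is first delayed by the lag
    of its primary calibration pairing (TA from heel, FL/SOL/GA from toe) so
    features and pressure targets are synchronized.
    """
    emg = {ch: env.emg_env[ch] for ch in EMG_CHANNELS}
    if emd is not None:
        for ch in EMG_CHANNELS:
            lag = emd.lag_for_emg_channel(ch)
            if lag is not None:
                emg[ch] = apply_shift(env.emg_trace(ch), lag).samples
    n = env.n_samples
    if any(len(v) != n for v in emg.values()):
        raise ValueError("length mismatch between shifted envelopes and targets")
    spans = sliding_windows(n, cfg)
    stride = cfg.stride

    X = np.column_stack([_windowed_rms(emg[ch], spans, cfg.window_len, stride)
                         for ch in EMG_CHANNELS])
    centers = np.array([(s + e - 1) // 2 for s, e in spans])
    if cfg.target_mode == "window_center":
        Y = np.column_stack([env.fsr_norm[ch][centers] for ch in FSR_CHANNELS])
    else:
        Y = np.column_stack([
            np.array([env.fsr_norm[ch][s:e].mean() for s, e in spans])
            for ch in FSR_CHANNELS])
    times = centers / env.target_rate
    prov = dict(provenance or {})
    prov.setdefault("window_len", cfg.window_len)
    prov.setdefault("overlap", cfg.overlap)
    prov.setdefault("target_mode", cfg.target_mode)
    prov.setdefault("emd_applied", emd is not None)
    return WindowedDataset(X=X, Y=Y, window_times=times, provenance=prov)


def channel_subset(ds: WindowedDataset, channels: Sequence[str]) -> WindowedDataset:
    """Restrict the feature columns to ``channels``; targets are unchanged."""
    channels = tuple(channels)
    if not channels:
        raise ValueError("channel subset must not be empty")
    unknown = [c for c in channels if c not in ds.feature_channels]
    if unknown:
        raise ValueError(f"unknown channels {unknown}; have {ds.feature_channels}")
    idx = [ds.feature_channels.index(c) for c in channels]
    return WindowedDataset(X=ds.X[:, idx], Y=ds.Y, window_times=ds.window_times,
                           feature_channels=channels, target_channels=ds.target_channels,
                           provenance=dict(ds.provenance, subset=list(channels)))
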