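"""Basic signal container shared by all stages.

A :class:`SignalTrace` is a uniformly sampled, finite, one-dimensional
time series with a sampling rate in Hz and a channel label.  Raw traces
carry sensor units (volts, raw FSR counts); after normalization the
samples are unitless in [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = ["SignalTrace"]


@dataclass
class SignalTrace:
    samples: np.ndarray
    rate: float
    name: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1:
            raise ValueError(f"trace {self.name!r}: samples must be 1-D")
        if not np.isfinite(self.rate) or self.rate <= 0:
            raise ValueError(f"trace {self.name!r}: rate must be positive, got {self.rate}")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError(f"trace {self.name!r}: samples contain non-finite values")

    def __len__(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        """Duration in seconds (n samples at ``rate`` Hz)."""
        return self.samples.size / self.rate

    def times(self) -> np.ndarray:
        """Sample times in seconds, starting at 0."""
        return np.arange(self.samples.size) / self.rate

    def with_samples(self, samples: np.ndarray, rate: float | None = None) -> "SignalTrace":
        """Copy of this trace with new samples (and optionally a new rate)."""
        return replace(self, samples=np.asarray(samples, dtype=np.float64),
                       rate=self.rate if rate is None else rate)
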