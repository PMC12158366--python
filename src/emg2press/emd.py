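"""Electromechanical delay (EMD) estimation and alignment.

The EMD is the lag between a muscle's electrical activation (EMG
envelope) and the mechanical response it produces (plantar pressure).
It is estimated as the argmax over lags of the normalized
cross-correlation of the mean-removed pair, each lag's correlation
normalized by the energies of the actually overlapping segments so that
the peak value is a Pearson-style coefficient in [-1, 1].

Sign convention (fixed throughout the package): **negative lag means the
EMG leads the pressure**, which is the physiological direction — muscle
activation precedes force by roughly 0.1–0.7 s during gait.
``apply_shift(emg, lag)`` with that negative lag delays the EMG so the
pair is synchronized.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import correlate

from .preprocess import EnvelopeSet
from .signals import SignalTrace

__all__ = [
    "EMDEstimate",
    "EMDTable",
    "Pairing",
    "PairingScheme",
    "DEFAULT_PAIRINGS",
    "PRIMARY_PAIRING",
    "estimate_emd",
    "apply_shift",
    "compatibility_report",
]


@dataclass
class EMDEstimate:
    lag: float        # seconds; negative = EMG precedes pressure
    peak_corr: float  # normalized correlation at the peak, in [-1, 1]


@dataclass(frozen=True)
class Pairing:
    emg_channel: str
    fsr_channel: str
    movement: str


#: Calibration pairings: plantarflexors against the toe sensor, TA against
#: the heel sensor (dorsiflexion) and the medial midfoot sensor (inversion).
DEFAULT_PAIRINGS: tuple[Pairing, ...] = (
    Pairing("FL", "toe", "plantarflexion"),
    Pairing("SOL", "toe", "plantarflexion"),
    Pairing("GA", "toe", "plantarflexion"),
    Pairing("TA", "heel", "dorsiflexion"),
    Pairing("TA", "midfoot_medial", "inversion"),
)

#: One pairing per EMG channel, used to shift inputs for the predictive
#: dataset (TA from its dorsiflexion pairing, plantarflexors from toe).
PRIMARY_PAIRING: dict[str, str] = {"TA": "heel", "FL": "toe", "SOL": "toe", "GA": "toe"}


@dataclass
class PairingScheme:
    pairings: tuple[Pairing, ...] = DEFAULT_PAIRINGS


@dataclass
class EMDTable:
    """Per (EMG, FSR) channel-pair lag estimates; absent pairs stay ``None``."""

    entries: dict[tuple[str, str], EMDEstimate | None] = field(default_factory=dict)
    search_halfwidth: float = 1.0

    def get(self, emg_channel: str, fsr_channel: str) -> EMDEstimate | None:
        return self.entries.get((emg_channel, fsr_channel))

    def lag_for_emg_channel(self, emg_channel: str,
                            primary: dict[str, str] = PRIMARY_PAIRING) -> float | None:
        est = self.get(emg_channel, primary[emg_channel])
        return None if est is None else est.lag

    def to_dict(self) -> dict:
        return {
            "search_halfwidth": self.search_halfwidth,
            "entries": [
                {"emg": e, "fsr": f,
                 "lag": None if est is None else est.lag,
                 "peak_corr": None if est is None else est.peak_corr}
                for (e, f), est in self.entries.items()
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "EMDTable":
        table = cls(search_halfwidth=float(d.get("search_halfwidth", 1.0)))
        for row in d.get("entries", []):
            est = None if row["lag"] is None else EMDEstimate(float(row["lag"]),
                                                              float(row["peak_corr"]))
            table.entries[(row["emg"], row["fsr"])] = est
        return table


def estimate_emd(emg_env: SignalTrace, fsr: SignalTrace,
                 search_halfwidth: float = 1.0) -> EMDEstimate:
    """Cross-correlation EMD estimate over lags in ±``search_halfwidth`` s.

    Both traces must share rate and length.  For every candidate lag the
    score is the exact Pearson correlation of the two overlapping
    segments (overlap means and variances from cumulative sums), so the
    peak value is interpretable across pairs.  The returned lag is
    negative when the EMG envelope leads the pressure; ties (within
    numerical tolerance) break toward the smallest ``|lag|``.
    """
    if emg_env.rate != fsr.rate:
        raise ValueError(f"rates differ: {emg_env.rate} vs {fsr.rate} Hz")
    if len(emg_env) != len(fsr):
        raise ValueError(f"lengths differ: {len(emg_env)} vs {len(fsr)}")
    n = len(emg_env)
    rate = emg_env.rate
    w = int(round(search_halfwidth * rate))
    if w < 1:
        raise ValueError("search_halfwidth must cover at least one sample")
    if w >= n - 1:
        raise ValueError("search_halfwidth exceeds the trace duration")

    a = emg_env.samples
    b = fsr.samples
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        which = "EMG" if np.ptp(a) == 0 else "FSR"
        raise ValueError(f"undefined correlation: {which} trace has zero variance")

    # full cross-correlation index m maps to lag k = m - (n - 1), with
    # c[k] = sum_j a[j] * b[j - k]; a leading b by d samples peaks at k = -d.
    num_full = correlate(a, b, mode="full", method="fft")
    lags = np.arange(-w, w + 1)
    num = num_full[lags + n - 1]

    def seg_sums(cum: np.ndarray, sign_lags: np.ndarray) -> np.ndarray:
        lo = np.maximum(0, sign_lags)
        hi = n + np.minimum(0, sign_lags)
        return cum[hi] - cum[lo]

    ca1 = np.concatenate([[0.0], np.cumsum(a)])
    cb1 = np.concatenate([[0.0], np.cumsum(b)])
    ca2 = np.concatenate([[0.0], np.cumsum(a * a)])
    cb2 = np.concatenate([[0.0], np.cumsum(b * b)])
    length = (n - np.abs(lags)).astype(float)
    sa, ea = seg_sums(ca1, lags), seg_sums(ca2, lags)
    sb, eb = seg_sums(cb1, -lags), seg_sums(cb2, -lags)
    var_a = np.maximum(ea - sa * sa / length, 0.0)
    var_b = np.maximum(eb - sb * sb / length, 0.0)
    denom = np.sqrt(var_a * var_b)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.where(denom > 0, (num - sa * sb / length) / denom, -np.inf)

    cmax = corr.max()
    candidates = np.flatnonzero(corr >= cmax - 1e-9 * max(1.0, abs(cmax)))
    best = candidates[np.argmin(np.abs(lags[candidates]))]
    return EMDEstimate(lag=float(lags[best] / rate),
                       peak_corr=float(np.clip(corr[best], -1.0, 1.0)))


def apply_shift(trace: SignalTrace, lag: float) -> SignalTrace:
    """Shift a trace by ``-lag`` so an (EMG, FSR) pair becomes synchronized.

    With the estimate's convention (negative lag = EMG leads), applying the
    estimated lag to the EMG trace delays it by ``|lag|``; edges are padded
    with the edge sample and length is preserved.
    """
    if abs(lag) >= trace.duration:
        raise ValueError(f"|lag| = {abs(lag)} s >= trace duration {trace.duration} s")
    shift = int(round(lag * trace.rate))
    x = trace.samples
    if shift == 0:
        return trace.with_samples(x.copy())
    if shift > 0:
        out = np.concatenate([x[shift:], np.full(shift, x[-1])])
    else:
        out = np.concatenate([np.full(-shift, x[0]), x[:shift]])
    return trace.with_samples(out)


@dataclass
class PairSummary:
    pairing: Pairing
    lag: float | None
    peak_corr: float | None
    compatible: bool


def compatibility_report(env: EnvelopeSet,
                         scheme: PairingScheme | None = None,
                         search_halfwidth: float = 1.0,
                         min_corr: float = 0.3) -> tuple[EMDTable, list[PairSummary]]:
    """EMD and peak correlation for every calibration pairing.

    Pairs whose peak correlation falls below ``min_corr`` — or whose
    correlation is undefined (for example a dead, constant channel) — are
    flagged incompatible; other pairs are unaffected.
    """
    scheme = scheme or PairingScheme()
    table = EMDTable(search_halfwidth=search_halfwidth)
    summaries: list[PairSummary] = []
    for pairing in scheme.pairings:
        if pairing.emg_channel not in env.emg_env or pairing.fsr_channel not in env.fsr_norm:
            raise KeyError(f"pairing {pairing.emg_channel}<->{pairing.fsr_channel}: "
                           "channel missing from the envelope set")
        try:
            est = estimate_emd(env.emg_trace(pairing.emg_channel),
                               env.fsr_trace(pairing.fsr_channel),
                               search_halfwidth)
        except ValueError:
            table.entries[(pairing.emg_channel, pairing.fsr_channel)] = None
            summaries.append(PairSummary(pairing, None, None, compatible=False))
            continue
        table.entries[(pairing.emg_channel, pairing.fsr_channel)] = est
        summaries.append(PairSummary(pairing, est.lag, est.peak_corr,
                                     compatible=est.peak_corr >= min_corr))
    return table, summaries
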