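"""Synthetic gait recordings with known ground truth.

Emulates a treadmill-free level-walking acquisition with four lower-leg
surface EMG channels (TA, FL, SOL, GA) and four plantar force-sensitive
resistor channels (heel, midfoot medial/lateral, toe).  Each gait cycle
contributes smooth raised-cosine (Hann) pressure bumps — heel loading
just after heel strike, midfoot loading around mid-stance, toe loading
peaking before toe off — and muscle-activation envelopes anchored to the
same per-cycle events.  Each EMG trace is its activation envelope,
advanced in time by the channel's electromechanical delay (EMD, negative
= muscle activity precedes force), amplitude-modulating a 20–450 Hz
band-limited Gaussian carrier, plus a mains sinusoid and broadband
baseline noise.

Cycle-to-cycle variability (multiplicative amplitude jitter and additive
timing jitter on the per-cycle anchors) is part of the default
conditions: real gait is never strictly periodic, and the aperiodicity
is what makes the planted EMD the unique cross-correlation maximum.

The geometry is arranged so that the fraction of each cycle with heel or
toe pressure above a 5% contact threshold equals ``stance_fraction``
(the conventional ~60/40 stance/swing split).
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import butter, sosfiltfilt

from .signals import SignalTrace

__all__ = [
    "EMG_CHANNELS",
    "FSR_CHANNELS",
    "DEFAULT_EMD",
    "SUBJECT_EMD_PRESETS",
    "GaitParams",
    "GaitTruth",
    "GaitRecording",
    "simulate_recording",
    "contact_fraction",
    "write_recording",
    "read_recording",
]

EMG_CHANNELS = ("TA", "FL", "SOL", "GA")
FSR_CHANNELS = ("heel", "midfoot_medial", "midfoot_lateral", "toe")

#: Default per-muscle electromechanical delays in seconds (negative: the
#: muscle activates before the mechanical response), in the range observed
#: for dynamic lower-limb tasks.
DEFAULT_EMD: dict[str, float] = {"TA": -0.108, "FL": -0.626, "SOL": -0.112, "GA": -0.623}

#: Physiologically plausible per-subject EMD sets used by the pipeline to
#: give each synthetic subject its own neuromechanical timing.
SUBJECT_EMD_PRESETS: tuple[dict[str, float], ...] = (
    {"TA": -0.108, "FL": -0.626, "SOL": -0.112, "GA": -0.623},
    {"TA": -0.146, "FL": -0.590, "SOL": -0.110, "GA": -0.636},
    {"TA": -0.124, "FL": -0.607, "SOL": -0.096, "GA": -0.631},
    {"TA": -0.156, "FL": -0.686, "SOL": -0.673, "GA": -0.687},
)

# Hann bump 0.5*(1+cos(pi*u)) crosses 5% of its peak at |u| = _U05; the
# contact-bump half-widths are sized from this so the heel+toe above-threshold
# union spans exactly stance_fraction of the cycle.
_CONTACT_THRESHOLD = 0.05
_U05 = math.acos(2 * _CONTACT_THRESHOLD - 1) / math.pi
# Heel bears the first 8/15 of stance, toe the last 8/15 (1/15 overlap).
_R = 8.0 / 15.0


def default_event_fractions(stance_fraction: float) -> dict[str, float]:
    """Gait-event timings as fractions of the cycle (heel strike at 0)."""
    s = stance_fraction
    return {"HS": 0.0, "FF": s / 6.0, "MST": s / 2.0, "HO": 0.75 * s, "TO": s}


@dataclass
class GaitParams:
    """Generator settings; defaults reflect the study acquisition setup."""

    n_cycles: int = 20
    cycle_duration: float = 1.1          # s; self-selected walking cadence
    stance_fraction: float = 0.60
    event_fractions: dict[str, float] | None = None
    emd: dict[str, float] | None = None  # s per EMG channel, negative = EMG leads
    emg_rate: float = 1926.0
    fsr_rates: tuple[float, float, float, float] = (1926.0, 148.0, 148.0, 148.0)
    mains_freq: float = 50.0
    mains_amplitude: float = 0.1         # in clean-envelope units
    carrier_snr: float = 10.0            # dB; math.inf disables baseline noise
    envelope_jitter: float = 0.05        # cycle-to-cycle amplitude/timing variability
    fsr_baseline: float = 0.02           # constant sensor offset on pressure channels
    fsr_noise_std: float = 0.003
    seed: int = 0

    def validate(self) -> None:
        def bad(name: str, msg: str) -> ValueError:
            return ValueError(f"GaitParams.{name}: {msg}")

        if not (isinstance(self.n_cycles, (int, np.integer)) and self.n_cycles >= 1):
            raise bad("n_cycles", f"must be an integer >= 1, got {self.n_cycles!r}")
        if not (np.isfinite(self.cycle_duration) and self.cycle_duration > 0):
            raise bad("cycle_duration", f"must be positive, got {self.cycle_duration!r}")
        if not (0.0 < self.stance_fraction < 1.0):
            raise bad("stance_fraction", f"must lie in (0, 1), got {self.stance_fraction!r}")
        if not (np.isfinite(self.emg_rate) and self.emg_rate > 0):
            raise bad("emg_rate", f"must be positive, got {self.emg_rate!r}")
        if len(self.fsr_rates) != len(FSR_CHANNELS):
            raise bad("fsr_rates", f"expected {len(FSR_CHANNELS)} rates")
        for r in self.fsr_rates:
            if not (np.isfinite(r) and r > 0):
                raise bad("fsr_rates", f"rates must be positive, got {r!r}")
        if not (np.isfinite(self.mains_amplitude) and self.mains_amplitude >= 0):
            raise bad("mains_amplitude", f"must be >= 0, got {self.mains_amplitude!r}")
        if math.isnan(self.carrier_snr):
            raise bad("carrier_snr", "must not be NaN")
        if not (0.0 <= self.envelope_jitter < 1.0) or not np.isfinite(self.envelope_jitter):
            raise bad("envelope_jitter", f"must lie in [0, 1), got {self.envelope_jitter!r}")
        if not (np.isfinite(self.fsr_noise_std) and self.fsr_noise_std >= 0):
            raise bad("fsr_noise_std", f"must be >= 0, got {self.fsr_noise_std!r}")
        fr = self.resolved_event_fractions()
        order = ["HS", "FF", "MST", "HO", "TO"]
        if set(fr) != set(order):
            raise bad("event_fractions", f"must define exactly {order}")
        vals = [fr[e] for e in order]
        if fr["HS"] != 0.0:
            raise bad("event_fractions", "HS must be 0")
        if any(b <= a for a, b in zip(vals, vals[1:])) or vals[-1] >= 1.0:
            raise bad("event_fractions", "must be strictly increasing within [0, 1)")
        emd = self.resolved_emd()
        for ch in EMG_CHANNELS:
            if ch not in emd or not np.isfinite(emd[ch]):
                raise bad("emd", f"needs a finite value for channel {ch}")

    def resolved_event_fractions(self) -> dict[str, float]:
        if self.event_fractions is None:
            return default_event_fractions(self.stance_fraction)
        return dict(self.event_fractions)

    def resolved_emd(self) -> dict[str, float]:
        return dict(DEFAULT_EMD if self.emd is None else self.emd)


@dataclass
class GaitTruth:
    """Ground truth carried by synthetic recordings only."""

    event_times: dict[str, np.ndarray]     # per event name, one time per cycle (s)
    envelopes: dict[str, np.ndarray]       # clean activation envelopes on the EMG grid
    emd: dict[str, float]                  # planted per-channel delays (s)
    seed: int


@dataclass
class GaitRecording:
    emg: dict[str, SignalTrace]
    fsr: dict[str, SignalTrace]
    truth: GaitTruth | None = None

    def __post_init__(self) -> None:
        missing = [c for c in EMG_CHANNELS if c not in self.emg]
        missing += [c for c in FSR_CHANNELS if c not in self.fsr]
        if missing:
            raise ValueError(f"recording is missing channels {missing}; "
                             f"expected EMG {list(EMG_CHANNELS)} and FSR {list(FSR_CHANNELS)}")

    @property
    def duration(self) -> float:
        return self.emg[EMG_CHANNELS[0]].duration


def _hann_bumps(t: np.ndarray, centers: np.ndarray, widths: np.ndarray,
                amps: np.ndarray) -> np.ndarray:
    """Sum of raised-cosine bumps a*0.5*(1+cos(pi*(t-c)/w)) on |t-c|<=w.

    ``t`` must be sorted ascending.
    """
    out = np.zeros_like(t)
    for c, w, a in zip(centers, widths, amps):
        lo, hi = np.searchsorted(t, (c - w, c + w))
        if hi > lo:
            u = (t[lo:hi] - c) / w
            out[lo:hi] += a * 0.5 * (1.0 + np.cos(np.pi * u))
    return out


def _bandlimited_noise(rng: np.random.Generator, n: int, rate: float,
                       low: float = 20.0, high: float = 450.0) -> np.ndarray:
    """Zero-phase band-passed white Gaussian noise, unit mean absolute value.

    Standard interference-pattern surrogate for surface EMG; the unit
    mean-|x| scaling makes rectification-plus-smoothing of a modulated
    carrier recover the modulating envelope with unit gain.
    """
    x = rng.standard_normal(n)
    sos = butter(4, [low, high], btype="bandpass", fs=rate, output="sos")
    x = sosfiltfilt(sos, x)
    return x / np.mean(np.abs(x))


def _jitter(rng: np.random.Generator, n: int, std: float, limit: float) -> np.ndarray:
    return np.clip(rng.normal(0.0, std, n), -limit, limit) if std > 0 else np.zeros(n)


def _amps(rng: np.random.Generator, n: int, jitter: float) -> np.ndarray:
    return np.clip(1.0 + rng.normal(0.0, jitter, n), 0.1, None) if jitter > 0 else np.ones(n)


def simulate_recording(params: GaitParams) -> GaitRecording:
    """Generate a seeded multi-rate EMG + FSR gait recording with truth."""
    params.validate()
    rng = np.random.default_rng(params.seed)
    n, C, s = params.n_cycles, params.cycle_duration, params.stance_fraction
    fr = params.resolved_event_fractions()
    emd = params.resolved_emd()
    dur = n * C

    # Per-cycle anchors: heel loading, push off, mid-stance.  Timing jitter is
    # shared between a pressure bump and the muscle bumps anchored to it, so
    # planted EMDs stay exact; the 0.4*C scaling gives a ~2% stride-time CV at
    # the default 5% jitter (typical of healthy gait), enough aperiodicity for
    # the one-cycle cross-correlation alias to stay strictly below the true
    # peak.  Clipped to +-7% of the cycle to keep event ordering.
    sig_t = params.envelope_jitter * 0.4 * C
    lim = 0.07 * C
    d_load = _jitter(rng, n + 1, sig_t, lim)
    d_push = _jitter(rng, n, sig_t, lim)
    d_mid = _jitter(rng, n, sig_t, lim)
    k = np.arange(n)
    w_contact = (_R / 2.0) * s * C / _U05
    heel_c_ext = np.arange(n + 1) * C + (_R / 2.0) * s * C + d_load      # incl. one past end
    heel_c = heel_c_ext[:n]
    toe_c = k * C + (1.0 - _R / 2.0) * s * C + d_push
    # lateral midfoot loads slightly before medial (load transfers medially),
    # symmetric about mid-stance so their sum peaks at the MST event
    mst_anchor = k * C + fr["MST"] * C + d_mid
    mid_c = mst_anchor + 0.025 * s * C
    lat_c = mst_anchor - 0.025 * s * C
    swing_c = 0.5 * (heel_c_ext[:-1] + heel_c_ext[1:])                   # between heel loads

    j = params.envelope_jitter
    pressure_bumps = {
        "heel": (heel_c, np.full(n, w_contact), _amps(rng, n, j)),
        "midfoot_medial": (mid_c, np.full(n, 0.25 * s * C), _amps(rng, n, j)),
        "midfoot_lateral": (lat_c, np.full(n, 0.25 * s * C), 0.9 * _amps(rng, n, j)),
        "toe": (toe_c, np.full(n, w_contact), _amps(rng, n, j)),
    }
    # Muscle bumps share centres (and hence jitter) with their paired pressure
    # bump: TA with heel loading, FL/SOL/GA with push off.  GA matches the toe
    # bump shape exactly (sharp plantarflexion burst); SOL and FL are broader.
    # TA gets a second, swing-phase dorsiflexion burst for foot clearance,
    # narrow enough never to overlap the heel bumps at small correlation lags.
    activation_bumps = {
        "TA": (np.concatenate([heel_c, swing_c]),
               np.concatenate([np.full(n, w_contact), np.full(n + 1, 0.15 * C)]),
               np.concatenate([0.9 * _amps(rng, n, j), np.full(n + 1, 0.6)])),
        "FL": (toe_c, np.full(n, 0.36 * s * C), 0.7 * _amps(rng, n, j)),
        "SOL": (toe_c, np.full(n, 0.45 * s * C), 0.85 * _amps(rng, n, j)),
        "GA": (toe_c, np.full(n, w_contact), _amps(rng, n, j)),
    }

    # EMG traces: envelope advanced by |EMD|, modulating a band-limited carrier.
    n_emg = int(round(dur * params.emg_rate))
    t_emg = np.arange(n_emg) / params.emg_rate
    emg: dict[str, SignalTrace] = {}
    envelopes: dict[str, np.ndarray] = {}
    for ch in EMG_CHANNELS:
        c, w, a = activation_bumps[ch]
        env = _hann_bumps(t_emg - emd[ch], c, w, a)   # emd < 0 -> evaluated later in cycle time
        envelopes[ch] = env
        carrier = _bandlimited_noise(rng, n_emg, params.emg_rate)
        x = env * carrier
        if params.mains_amplitude > 0:
            x = x + params.mains_amplitude * np.sin(
                2 * np.pi * params.mains_freq * t_emg + rng.uniform(0, 2 * np.pi))
        if np.isfinite(params.carrier_snr):
            p_sig = float(np.mean((env * carrier) ** 2))
            sigma = math.sqrt(p_sig / 10.0 ** (params.carrier_snr / 10.0)) if p_sig > 0 else 0.0
            if sigma > 0:
                x = x + rng.normal(0.0, sigma, n_emg)
        emg[ch] = SignalTrace(x, params.emg_rate, ch)

    fsr: dict[str, SignalTrace] = {}
    for ch, rate in zip(FSR_CHANNELS, params.fsr_rates):
        n_f = int(round(dur * rate))
        t_f = np.arange(n_f) / rate
        c, w, a = pressure_bumps[ch]
        p = _hann_bumps(t_f, c, w, a) + params.fsr_baseline
        if params.fsr_noise_std > 0:
            p = p + rng.normal(0.0, params.fsr_noise_std, n_f)
        fsr[ch] = SignalTrace(np.maximum(p, 0.0), rate, ch)

    event_times = {
        "HS": k * C + d_load[:n],
        "FF": k * C + fr["FF"] * C + d_load[:n],
        "MST": mst_anchor.copy(),
        "HO": k * C + fr["HO"] * C + d_push,
        "TO": k * C + s * C + d_push,
    }
    truth = GaitTruth(event_times=event_times, envelopes=envelopes,
                      emd=dict(emd), seed=params.seed)
    return GaitRecording(emg=emg, fsr=fsr, truth=truth)


def contact_fraction(rec: GaitRecording, threshold: float = _CONTACT_THRESHOLD) -> float:
    """Fraction of time with heel-or-toe normalized pressure above threshold.

    Toe pressure is linearly interpolated onto the heel grid; each channel is
    min-max normalized over the recording before thresholding.  Because the
    cycles tile the recording exactly, this equals the per-cycle contact
    fraction averaged over cycles.
    """
    heel, toe = rec.fsr["heel"], rec.fsr["toe"]
    t = heel.times()
    toe_up = np.interp(t, toe.times(), toe.samples)

    def norm(x: np.ndarray) -> np.ndarray:
        lo, hi = x.min(), x.max()
        return np.zeros_like(x) if hi == lo else (x - lo) / (hi - lo)

    contact = np.maximum(norm(heel.samples), norm(toe_up)) > threshold
    return float(np.mean(contact))


# ---------------------------------------------------------------------------
# Plain-text persistence: one CSV per sampling-rate group plus a JSON sidecar.

_META_NAME = "meta.json"
_TRUTH_ENV_NAME = "truth_envelopes.csv"


def _rate_key(rate: float) -> str:
    return f"{rate:g}"


def write_recording(rec: GaitRecording, path: str | os.PathLike) -> None:
    """Write a recording as CSV groups (full float precision) + JSON sidecar."""
    os.makedirs(path, exist_ok=True)
    groups: dict[str, dict[str, SignalTrace]] = {}
    for ch in EMG_CHANNELS:
        groups.setdefault(_rate_key(rec.emg[ch].rate), {})[ch] = rec.emg[ch]
    for ch in FSR_CHANNELS:
        groups.setdefault(_rate_key(rec.fsr[ch].rate), {})[ch] = rec.fsr[ch]

    meta: dict = {"channels": {}, "files": {}, "truth": None}
    for key, traces in groups.items():
        fname = f"signals_{key}hz.csv"
        first = next(iter(traces.values()))
        frame = pd.DataFrame({"time_s": first.times()})
        for ch, tr in traces.items():
            if len(tr) != len(first):
                raise ValueError(f"rate group {key}: traces of unequal length")
            frame[ch] = tr.samples
            meta["channels"][ch] = {"rate": tr.rate, "file": fname,
                                    "kind": "emg" if ch in EMG_CHANNELS else "fsr"}
        frame.to_csv(os.path.join(path, fname), index=False, float_format="%.17g")
        meta["files"][fname] = {"rate": float(key), "channels": list(traces)}

    if rec.truth is not None:
        meta["truth"] = {
            "event_times": {e: list(map(float, v)) for e, v in rec.truth.event_times.items()},
            "emd": {c: float(v) for c, v in rec.truth.emd.items()},
            "seed": int(rec.truth.seed),
            "envelope_rate": rec.emg[EMG_CHANNELS[0]].rate,
        }
        env_frame = pd.DataFrame(
            {"time_s": rec.emg[EMG_CHANNELS[0]].times(),
             **{ch: rec.truth.envelopes[ch] for ch in EMG_CHANNELS}})
        env_frame.to_csv(os.path.join(path, _TRUTH_ENV_NAME), index=False,
                         float_format="%.17g")

    with open(os.path.join(path, _META_NAME), "w") as fh:
        json.dump(meta, fh, indent=1)


def read_recording(path: str | os.PathLike) -> GaitRecording:
    """Read a recording written by :func:`write_recording`."""
    meta_path = os.path.join(path, _META_NAME)
    if not os.path.exists(meta_path):
        raise FileNotFoundError(f"no {_META_NAME} in {path}")
    with open(meta_path) as fh:
        meta = json.load(fh)

    expected = set(EMG_CHANNELS) | set(FSR_CHANNELS)
    unknown = sorted(set(meta.get("channels", {})) - expected)
    if unknown:
        raise ValueError(f"unknown channel name(s) {unknown}; "
                         f"expected EMG {list(EMG_CHANNELS)} and FSR {list(FSR_CHANNELS)}")
    missing = sorted(expected - set(meta.get("channels", {})))
    if missing:
        raise ValueError(f"metadata lists no entry for channel(s) {missing}")

    tables: dict[str, pd.DataFrame] = {}
    emg: dict[str, SignalTrace] = {}
    fsr: dict[str, SignalTrace] = {}
    for ch, info in meta["channels"].items():
        if "rate" not in info:
            raise ValueError(f"channel {ch}: missing rate metadata")
        fname = info["file"]
        if fname not in tables:
            fpath = os.path.join(path, fname)
            try:
                tables[fname] = pd.read_csv(fpath, float_precision="round_trip")
            except Exception as exc:  # pragma: no cover - pandas reports the line
                raise ValueError(f"failed to parse {fpath}: {exc}") from exc
        table = tables[fname]
        if ch not in table.columns:
            raise ValueError(f"file {fname}: expected a column {ch!r}")
        trace = SignalTrace(table[ch].to_numpy(), float(info["rate"]), ch)
        (emg if info.get("kind") == "emg" else fsr)[ch] = trace

    truth = None
    if meta.get("truth"):
        t = meta["truth"]
        env_frame = pd.read_csv(os.path.join(path, _TRUTH_ENV_NAME),
                                float_precision="round_trip")
        truth = GaitTruth(
            event_times={e: np.asarray(v, dtype=float) for e, v in t["event_times"].items()},
            envelopes={ch: env_frame[ch].to_numpy() for ch in EMG_CHANNELS},
            emd={c: float(v) for c, v in t["emd"].items()},
            seed=int(t["seed"]),
        )
    return GaitRecording(emg=emg, fsr=fsr, truth=truth)
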