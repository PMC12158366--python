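import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import emg2press as ep

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")

#: Subject-specific per-muscle delay sets spanning the physiological range
#: (seconds, negative = EMG precedes pressure); one entry is unmeasurable on
#: some subjects, hence the shorter second row.
EMD_ROWS = [
    {"TA": -0.108, "FL": -0.626, "SOL": -0.112, "GA": -0.623},
    {"TA": -0.146, "FL": -0.590, "GA": -0.636},
    {"TA": -0.124, "FL": -0.607, "SOL": -0.096, "GA": -0.631},
    {"TA": -0.156, "FL": -0.686, "SOL": -0.673, "GA": -0.687},
]


def noiseless_params(**kw) -> ep.GaitParams:
    """Zero sensor/carrier/mains noise; gait variability stays on."""
    defaults = dict(n_cycles=12, seed=7, carrier_snr=float("inf"),
                    mains_amplitude=0.0, fsr_noise_std=0.0)
    defaults.update(kw)
    return ep.GaitParams(**defaults)


@pytest.fixture(scope="session")
def noiseless_recording() -> ep.GaitRecording:
    return ep.simulate_recording(noiseless_params())


@pytest.fixture(scope="session")
def default_recording() -> ep.GaitRecording:
    return ep.simulate_recording(ep.GaitParams(n_cycles=20, seed=1))


@pytest.fixture(scope="session")
def default_envelopes(default_recording) -> ep.EnvelopeSet:
    return ep.preprocess_recording(default_recording)


@pytest.fixture(scope="session")
def noiseless_envelopes(noiseless_recording) -> ep.EnvelopeSet:
    return ep.preprocess_recording(noiseless_recording)


@pytest.fixture(scope="session")
def tiny_dataset(noiseless_envelopes) -> ep.WindowedDataset:
    table, _ = ep.compatibility_report(noiseless_envelopes)
    return ep.build_dataset(noiseless_envelopes, table, ep.WindowConfig())
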