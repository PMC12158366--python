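"""Signal conditioning chain: filter responses, envelope extraction,
normalization, resampling, and the end-to-end recording chain."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import emg2press as ep
from emg2press.signals import SignalTrace


def steady_amplitude(x: np.ndarray) -> float:
    """Peak amplitude of the central half (transients excluded)."""
    n = len(x)
    return float(np.max(np.abs(x[n // 4: 3 * n // 4])))


def sine(freq: float, rate: float = 1926.0, dur: float = 4.0) -> SignalTrace:
    t = np.arange(int(dur * rate)) / rate
    return SignalTrace(np.sin(2 * np.pi * freq * t), rate, f"sine{freq}")


class TestFilters:
    def test_bandpass_passband_within_1db(self):
        out = ep.bandpass(sine(100.0), 20.0, 450.0)
        assert 10 ** (-1 / 20) < steady_amplitude(out.samples) < 10 ** (1 / 20)

    def test_bandpass_stopband_at_least_20db(self):
        out = ep.bandpass(sine(5.0), 20.0, 450.0)
        assert steady_amplitude(out.samples) < 0.1

    def test_bandpass_zero_in_zero_out(self):
        tr = SignalTrace(np.zeros(2000), 1926.0, "z")
        assert np.all(ep.bandpass(tr, 20.0, 450.0).samples == 0)

    def test_bandpass_rejects_cutoff_above_nyquist(self):
        with pytest.raises(ValueError, match="Nyquist"):
            ep.bandpass(sine(10.0, rate=800.0), 20.0, 450.0)

    def test_notch_kills_50hz_keeps_100hz(self):
        assert steady_amplitude(ep.notch(sine(50.0)).samples) <= 0.1
        amp = steady_amplitude(ep.notch(sine(100.0)).samples)
        assert 10 ** (-1 / 20) < amp < 10 ** (1 / 20)

    def test_zero_phase_no_lag_on_broadband_noise(self):
        rng = np.random.default_rng(11)
        x = rng.standard_normal(20000)
        y = ep.bandpass(SignalTrace(x, 1926.0, "n"), 20.0, 450.0).samples
        full = np.correlate(x - x.mean(), y - y.mean(), mode="full")
        assert abs(int(np.argmax(full)) - (len(x) - 1)) == 0


class TestPointwiseOps:
    def test_rectify_definition_and_idempotence(self):
        tr = SignalTrace(np.array([-1.0, 2.0, -3.0]), 10.0, "r")
        out = ep.rectify(tr)
        np.testing.assert_array_equal(out.samples, [1.0, 2.0, 3.0])
        np.testing.assert_array_equal(ep.rectify(out).samples, out.samples)

    def test_rectified_sine_mean_is_2_over_pi(self):
        out = ep.rectify(sine(50.0, dur=2.0))
        assert abs(out.samples.mean() - 2 / np.pi) < 0.01

    def test_envelope_dc_gain_unity(self):
        tr = SignalTrace(np.ones(8000), 1926.0, "c")
        mid = ep.envelope(tr, 10.0).samples[2000:6000]
        np.testing.assert_allclose(mid, 1.0, atol=1e-6)

    def test_envelope_tracks_slow_modulator(self):
        rate, dur = 1926.0, 6.0
        t = np.arange(int(dur * rate)) / rate
        mod = 0.5 * (1 + np.cos(2 * np.pi * 2.0 * (t - dur / 2) / dur)) ** 2
        x = np.abs(mod * np.sin(2 * np.pi * 200.0 * t))
        env = ep.envelope(SignalTrace(x, rate, "m"), 10.0).samples
        assert np.corrcoef(env, mod)[0, 1] > 0.95
        assert env.min() >= 0.0

    def test_baseline_correct_removes_offset(self):
        rng = np.random.default_rng(1)
        base = np.maximum(rng.random(5000) - 0.3, 0.0)
        shifted = SignalTrace(base + 0.3, 100.0, "b")
        out = ep.baseline_correct(shifted)
        corrected = ep.baseline_correct(SignalTrace(base, 100.0, "b0"))
        np.testing.assert_allclose(out.samples, corrected.samples, atol=1e-9)

    def test_baseline_correct_constant_goes_to_zero(self):
        out = ep.baseline_correct(SignalTrace(np.full(100, 0.7), 10.0, "c"))
        assert np.all(out.samples == 0.0)

    def test_normalize01_examples(self):
        out = ep.normalize01(SignalTrace(np.array([2.0, 4.0, 6.0]), 1.0, "x"))
        np.testing.assert_allclose(out.samples, [0.0, 0.5, 1.0])
        const = ep.normalize01(SignalTrace(np.full(5, 3.3), 1.0, "c"))
        np.testing.assert_array_equal(const.samples, np.zeros(5))

    def test_normalize01_idempotent(self):
        rng = np.random.default_rng(2)
        tr = SignalTrace(rng.random(1000) * 7 - 3, 10.0, "x")
        once = ep.normalize01(tr)
        twice = ep.normalize01(once)
        np.testing.assert_allclose(twice.samples, once.samples, atol=1e-12)

    @given(st.lists(st.floats(-1e6, 1e6), min_size=1, max_size=200))
    def test_normalize01_range_property(self, values):
        out = ep.normalize01(SignalTrace(np.asarray(values), 10.0, "h"))
        assert out.samples.min() >= 0.0 and out.samples.max() <= 1.0


class TestResample:
    def test_linear_ramp_exact(self):
        n = 300
        tr = SignalTrace(np.arange(n) / 148.0, 148.0, "ramp")  # x(t) = t
        out = ep.resample(tr, 1926.0)
        expected = out.times()
        interior = slice(10, len(out) - 10)
        assert np.max(np.abs(out.samples[interior] - expected[interior])) < 1e-9

    def test_identity_when_rates_match(self):
        tr = sine(5.0, rate=148.0, dur=2.0)
        out = ep.resample(tr, 148.0)
        np.testing.assert_array_equal(out.samples, tr.samples)

    def test_sine_upsample_error_below_1_percent(self):
        tr = sine(5.0, rate=148.0, dur=3.0)
        out = ep.resample(tr, 1926.0)
        truth = np.sin(2 * np.pi * 5.0 * out.times())
        rms = np.sqrt(np.mean((out.samples - truth) ** 2))
        assert rms < 0.01

    def test_single_sample_is_an_error(self):
        with pytest.raises(ValueError):
            ep.resample(SignalTrace(np.array([1.0]), 10.0, "s"), 100.0)


class TestChain:
    def test_outputs_in_unit_range_and_equal_length(self, default_envelopes):
        env = default_envelopes
        n = env.n_samples
        for d in (env.emg_env, env.fsr_norm):
            for x in d.values():
                assert len(x) == n
                assert x.min() >= 0.0 and x.max() <= 1.0

    def test_envelopes_match_truth_on_noiseless_recording(
            self, noiseless_recording, noiseless_envelopes):
        truth = noiseless_recording.truth.envelopes
        for ch in ep.EMG_CHANNELS:
            est = noiseless_envelopes.emg_env[ch]
            r = np.corrcoef(est[:len(truth[ch])], truth[ch][:len(est)])[0, 1]
            assert r > 0.95, ch

    def test_pressure_peak_times_preserved(self, noiseless_recording):
        env = ep.preprocess_recording(noiseless_recording)
        one_cycle = int(1.1 * 1926)
        for ch in ("heel", "toe"):
            raw = ep.resample(noiseless_recording.fsr[ch], 1926.0) \
                if noiseless_recording.fsr[ch].rate != 1926.0 \
                else noiseless_recording.fsr[ch]
            raw_peak = int(np.argmax(raw.samples[:one_cycle]))
            proc_peak = int(np.argmax(env.fsr_norm[ch][:one_cycle]))
            assert abs(proc_peak - raw_peak) <= 1

    def test_chain_applied_twice_stays_in_range(self, noiseless_recording):
        env = ep.preprocess_recording(noiseless_recording)
        again = ep.preprocess_recording(noiseless_recording)
        for ch in ep.EMG_CHANNELS:
            assert again.emg_env[ch].max() <= 1.0

    def test_stage_errors_carry_channel_name(self, noiseless_recording):
        cfg = ep.PreprocessConfig(emg_band=(20.0, 2000.0))
        with pytest.raises(ValueError, match="EMG channel TA"):
            ep.preprocess_recording(noiseless_recording, cfg)
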