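"""Signal chain: filtering, enveloping, segmentation, normalization."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import synergykit as sk
from synergykit.preprocess import segment_and_time_normalize
from synergykit.session import TrialEvent

FS = 600.0


def _amplitude(x):
    """Peak amplitude of a steady oscillation, central half only."""
    n = len(x)
    return np.abs(x[n // 4: 3 * n // 4]).max()


class TestBandpass:
    def test_dc_is_rejected(self):
        x = np.ones(6000)
        y = sk.bandpass_filter(x, FS, 10, 300)
        assert np.abs(y).max() < 0.01

    def test_passband_tone_is_preserved(self):
        t = np.arange(12000) / FS
        y = sk.bandpass_filter(np.sin(2 * np.pi * 50 * t), FS, 10, 300)
        assert _amplitude(y) == pytest.approx(1.0, abs=0.02)

    def test_low_frequency_is_attenuated(self):
        t = np.arange(12000) / FS
        y = sk.bandpass_filter(np.sin(2 * np.pi * 2 * t), FS, 10, 300)
        assert _amplitude(y) < 0.10

    def test_linearity(self):
        rng = np.random.default_rng(0)
        x, y = rng.standard_normal(3000), rng.standard_normal(3000)
        lhs = sk.bandpass_filter(2.0 * x + 3.0 * y, FS, 10, 300)
        rhs = (2.0 * sk.bandpass_filter(x, FS, 10, 300)
               + 3.0 * sk.bandpass_filter(y, FS, 10, 300))
        assert np.allclose(lhs, rhs, atol=1e-10)

    def test_high_edge_capped_below_nyquist(self):
        # band to 300 Hz at fs=600 would be degenerate; the cap keeps it valid
        y = sk.bandpass_filter(np.random.default_rng(1).standard_normal(2000),
                               FS, 10, 300)
        assert np.all(np.isfinite(y))

    @pytest.mark.parametrize("kwargs", [
        dict(fs=0.0, low=10, high=300),
        dict(fs=600.0, low=-1, high=300),
        dict(fs=600.0, low=300, high=10),
        dict(fs=15.0, low=10, high=300),
    ])
    def test_parameter_errors(self, kwargs):
        with pytest.raises(sk.ParameterError):
            sk.bandpass_filter(np.ones(100), **kwargs)


class TestMedianFilter:
    def test_isolated_spike_is_removed(self):
        x = np.array([1.0, 1.0, 9.0, 1.0, 1.0])
        assert np.array_equal(sk.median_filter_artifact(x, 5), np.ones(5))

    def test_constant_signal_unchanged(self):
        x = np.full(50, 3.3)
        assert np.array_equal(sk.median_filter_artifact(x, 5), x)

    def test_even_kernel_rejected(self):
        with pytest.raises(sk.ParameterError):
            sk.median_filter_artifact(np.ones(10), 4)

    def test_periodic_pulses_on_sinusoid_halve_envelope_error(self):
        t = np.arange(6000) / FS
        clean = np.sin(2 * np.pi * 30 * t)
        dirty = clean.copy()
        dirty[::20] += 8.0                     # 1-sample periodic pulses
        env_clean = sk.rms_envelope(clean, FS, 100)
        err_raw = np.linalg.norm(sk.rms_envelope(dirty, FS, 100) - env_clean)
        filt = sk.median_filter_artifact(dirty, 5)
        err_fil = np.linalg.norm(sk.rms_envelope(filt, FS, 100) - env_clean)
        assert err_fil <= 0.5 * err_raw


class TestRmsEnvelope:
    def test_output_count_is_floor_of_windows(self):
        env = sk.rms_envelope(np.ones(600), FS, 100)   # 1 s -> 10 windows
        assert env.shape == (10,)

    def test_constant_signal_gives_its_amplitude(self):
        env = sk.rms_envelope(np.full(1200, 2.0), FS, 100)
        assert np.allclose(env, 2.0)

    def test_sinusoid_gives_inverse_sqrt2(self):
        t = np.arange(1200) / FS
        env = sk.rms_envelope(np.sin(2 * np.pi * 30 * t), FS, 100)
        assert np.allclose(env, 1 / np.sqrt(2), rtol=0.01)

    def test_short_signal_rejected(self):
        with pytest.raises(sk.ParameterError):
            sk.rms_envelope(np.ones(30), FS, 100)

    @given(st.floats(0.1, 5.0))
    def test_scale_equivariance(self, c):
        x = np.linspace(0, 1, 600)
        assert np.allclose(sk.rms_envelope(c * x, FS, 100),
                           c * sk.rms_envelope(x, FS, 100))


class TestSegmentation:
    def _events(self):
        return [TrialEvent("BL-Hip", 0, "control", 0, 3000),
                TrialEvent("R-Hip", 0, "control", 3000, 7200)]

    def test_every_trial_has_n_points_columns(self):
        env = np.random.default_rng(0).random((10, 120))
        out = segment_and_time_normalize(env, self._events(), 60, 7000)
        for mat in out.values():
            assert mat.shape == (10, 7000)

    def test_constant_envelope_stays_constant(self):
        env = np.full((1, 120), 4.2)
        out = segment_and_time_normalize(env, self._events(), 60, 500)
        for mat in out.values():
            assert np.allclose(mat, 4.2)

    def test_linear_ramp_stays_linear(self):
        env = np.arange(120.0)[None, :]
        out = segment_and_time_normalize(
            env, [TrialEvent("BL-Hip", 0, "control", 0, 7200)], 60, 1000)
        mat = out[("BL-Hip", "control", 0)][0]
        # affine signals are preserved exactly by linear interpolation
        fitted = np.polyval(np.polyfit(np.arange(1000), mat, 1),
                            np.arange(1000))
        assert np.allclose(mat, fitted, atol=1e-9)

    def test_event_outside_envelope_names_the_trial(self):
        env = np.zeros((2, 50))
        with pytest.raises(sk.SegmentationError, match="L-Hip.*trial2"):
            segment_and_time_normalize(
                env, [TrialEvent("L-Hip", 2, "control", 0, 10**6)], 60)


class TestAmplitudeNormalize:
    def test_per_trial_minmax(self):
        trials = {("BL-Hip", "control", 0): np.array([[0.0, 2.0, 4.0]])}
        out, _, _ = sk.amplitude_normalize(trials, scope="per_trial")
        assert np.allclose(out[("BL-Hip", "control", 0)], [[0.0, 0.5, 1.0]])

    @pytest.mark.parametrize("scope", ["per_trial", "per_muscle_session"])
    def test_scale_invariance(self, scope):
        rng = np.random.default_rng(4)
        trials = {("BL-Hip", "control", t): rng.random((3, 50))
                  for t in range(3)}
        scaled = {k: 10.0 * v for k, v in trials.items()}
        out1, _, _ = sk.amplitude_normalize(trials, scope)
        out2, _, _ = sk.amplitude_normalize(scaled, scope)
        for k in trials:
            assert np.allclose(out1[k], out2[k])

    def test_per_muscle_session_max_is_one_across_movements(self):
        rng = np.random.default_rng(5)
        trials = {(m, "control", 0): rng.random((4, 40)) + (0.1 if m == "BL-Hip" else 0)
                  for m in sk.MOVEMENTS}
        out, _, _ = sk.amplitude_normalize(trials, "per_muscle_session")
        stacked = np.concatenate(list(out.values()), axis=1)
        assert np.allclose(stacked.max(axis=1), 1.0)
        for mat in out.values():
            assert mat.max() <= 1.0 + 1e-12

    def test_all_zero_muscle_is_reported(self):
        trials = {("BL-Hip", "control", 0): np.zeros((2, 10))}
        with pytest.raises(sk.NormalizationError):
            sk.amplitude_normalize(trials, "per_muscle_session")


class TestEnsembleAverage:
    def test_identical_trials_average_to_themselves(self):
        t = np.random.default_rng(6).random((10, 20))
        assert np.allclose(sk.ensemble_average([t, t, t]), t)

    def test_scalar_example(self):
        out = sk.ensemble_average([np.array([[0.0]]), np.array([[3.0]]),
                                   np.array([[6.0]])])
        assert np.allclose(out, [[3.0]])

    def test_matches_elementwise_loop_oracle(self):
        rng = np.random.default_rng(7)
        trials = [rng.random((4, 6)) for _ in range(3)]
        out = sk.ensemble_average(trials)
        for i in range(4):
            for j in range(6):
                assert out[i, j] == pytest.approx(
                    sum(t[i, j] for t in trials) / 3, abs=1e-15)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(sk.ParameterError):
            sk.ensemble_average([np.zeros((2, 3)), np.zeros((2, 4))])


def test_full_chain_shape_contract(prep_control):
    """A control session yields 18 time-normalized trials of 10 x 7000 and
    6 ensemble envelopes, all non-negative with normalized values in [0, 1]."""
    assert len(prep_control.trials_raw) == 18
    for mat in prep_control.trials_raw.values():
        assert mat.shape == (10, 7000)
        assert np.all(mat >= 0)
    assert len(prep_control.ensembles) == 6
    for env in prep_control.ensembles:
        assert env.values.shape == (10, 7000)
        assert env.values.min() >= 0
        assert env.values.max() <= 1 + 1e-12
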