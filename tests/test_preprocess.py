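"""Filtering, segmentation and staircase contracts."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import signal as sps

from oxygait.core import ConfigurationError, GaitTrace, HemodynamicRecording, InputError
from oxygait.preprocess import (
    DEFAULT_BANDS,
    bandpass_decompose,
    design_bandpass,
    lowpass_gait,
    moving_average,
    process_gait,
    rectify_smooth,
    remove_baseline,
    segment_cycles,
    staircase,
)
from oxygait.synthetic import SimulationConfig, generate_latent_profile, synthesize_gait


def _rec(data, fs=10.0):
    return HemodynamicRecording(sampling_rate=fs, species="HbO", data=np.atleast_2d(data))


class TestBaseline:
    @pytest.mark.parametrize(
        "data,expected",
        [([5.0, 5.0, 5.0], [0.0, 0.0, 0.0]), ([1.0, 2.0, 3.0], [0.0, 1.0, 2.0])],
    )
    def test_examples(self, data, expected):
        np.testing.assert_array_equal(remove_baseline(_rec(data)).data[0], expected)

    @settings(derandomize=True, max_examples=25)
    @given(st.lists(st.floats(-100, 100), min_size=1, max_size=30))
    def test_first_sample_zero_and_idempotent(self, data):
        out = remove_baseline(_rec(data))
        assert out.data[0, 0] == 0.0
        np.testing.assert_array_equal(remove_baseline(out).data, out.data)


class TestBandpass:
    def test_default_band_table(self):
        expected = {
            "cardiac": (0.6, 2.0),
            "respiratory": (0.145, 0.6),
            "myogenic": (0.052, 0.145),
            "neurogenic": (0.021, 0.052),
            "endothelial": (0.0095, 0.021),
        }
        assert {b.name: (b.low_edge, b.high_edge) for b in DEFAULT_BANDS} == expected

    def test_zero_input_gives_zero_output(self):
        decomp = bandpass_decompose(_rec(np.zeros(200)))
        assert all(np.allclose(rec.data, 0) for rec in decomp.values())

    def test_sinusoid_passband_and_stopband(self):
        """1 Hz sinusoid: kept by the cardiac band, crushed by the neurogenic
        band; empirical amplitudes agree with the designed transfer function."""
        fs = 10.0
        t = np.arange(0, 300, 1 / fs)
        x = np.sin(2 * np.pi * 1.0 * t)
        decomp = bandpass_decompose(_rec(x, fs))
        mid = slice(len(t) // 3, 2 * len(t) // 3)  # past the filter transients

        def amplitude(y):  # phase-insensitive estimate
            return float(np.sqrt(2.0 * np.mean(y[mid] ** 2)))

        amp_card = amplitude(decomp[("cardiac", "HbO")].data[0])
        amp_neuro = amplitude(decomp[("neurogenic", "HbO")].data[0])
        assert amp_card >= 0.8
        assert amp_neuro < 0.05
        # transfer-function oracle: forward-backward gain is |H(f)|^2
        bands = {b.name: b for b in DEFAULT_BANDS}
        _, h_card = sps.sosfreqz(design_bandpass(bands["cardiac"], fs), worN=[1.0], fs=fs)
        assert amp_card == pytest.approx(np.abs(h_card[0]) ** 2, abs=0.01)
        _, h_neuro = sps.sosfreqz(design_bandpass(bands["neurogenic"], fs), worN=[1.0], fs=fs)
        assert np.abs(h_neuro[0]) ** 2 < 0.01

    def test_linearity(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=300)
        d1 = bandpass_decompose(_rec(x))
        d3 = bandpass_decompose(_rec(3.0 * x))
        for key in d1:
            np.testing.assert_allclose(3.0 * d1[key].data, d3[key].data, rtol=1e-9, atol=1e-9)

    def test_band_above_nyquist_rejected(self):
        with pytest.raises(ConfigurationError, match="cardiac"):
            bandpass_decompose(_rec(np.zeros(100), fs=3.0))

    def test_zero_phase_pulse_alignment(self):
        """Forward-backward filtering: a band-centered pulse keeps its peak."""
        fs = 10.0
        t = np.arange(0, 120, 1 / fs)
        carrier = np.sin(2 * np.pi * 1.1 * t)
        envelope = np.exp(-((t - 60) ** 2) / (2 * 4.0**2))
        x = carrier * envelope
        out = bandpass_decompose(_rec(x, fs))[("cardiac", "HbO")].data[0]
        out_env = np.abs(sps.hilbert(out))
        assert abs(int(np.argmax(out_env)) - int(np.argmax(envelope))) <= 2


class TestGaitChain:
    def _trace(self, v, fs=100.0):
        return GaitTrace(sampling_rate=fs, angular_velocity=np.asarray(v, float),
                         angle=np.asarray(v, float))

    def test_lowpass_dc_gain_unity(self):
        out = lowpass_gait(self._trace(np.full(500, 3.0)))
        np.testing.assert_allclose(out.angular_velocity, 3.0, rtol=1e-9)

    @pytest.mark.parametrize("freq,low,high", [(1.0, 0.95, 1.05), (30.0, 0.0, 0.10)])
    def test_lowpass_butterworth_magnitude(self, freq, low, high):
        fs = 100.0
        t = np.arange(0, 20, 1 / fs)
        out = lowpass_gait(self._trace(np.sin(2 * np.pi * freq * t)))
        mid = slice(len(t) // 4, 3 * len(t) // 4)
        amp = np.abs(out.angular_velocity[mid]).max()
        assert low <= amp <= high

    def test_lowpass_cutoff_above_nyquist_rejected(self):
        with pytest.raises(ConfigurationError):
            lowpass_gait(self._trace(np.zeros(100), fs=10.0), cutoff=6.0)

    def test_rectify_window_one(self):
        out = rectify_smooth(self._trace([-1.0, 1.0, -1.0]), window_s=0.01)
        np.testing.assert_array_equal(out.angular_velocity, [1.0, 1.0, 1.0])

    def test_moving_average_matches_direct_convolution_oracle(self):
        x = np.array([0.0, 3.0, 0.0, 3.0, 0.0])
        # independent oracle: mean of the samples available in each centered window
        expected = []
        for i in range(len(x)):
            lo, hi = max(0, i - 1), min(len(x), i + 2)
            expected.append(x[lo:hi].mean())
        np.testing.assert_allclose(moving_average(x, 3), expected)

    @settings(derandomize=True, max_examples=25)
    @given(st.lists(st.floats(-50, 50), min_size=4, max_size=60))
    def test_rectify_smooth_nonnegative(self, values):
        out = rectify_smooth(self._trace(values, fs=10.0), window_s=0.3)
        assert np.all(out.angular_velocity >= 0)

    def test_window_longer_than_trace_rejected(self):
        with pytest.raises(InputError):
            moving_average(np.zeros(3), 5)


class TestSegmentation:
    def test_rectified_sinusoid_minima_match_bruteforce_scan(self):
        fs = 100.0
        t = np.arange(0, 5, 1 / fs)
        env = np.abs(np.sin(2 * np.pi * 1.0 * t))  # minima every 0.5 s
        trace = GaitTrace(sampling_rate=fs, angular_velocity=env, angle=env)
        boundaries, partial = segment_cycles(trace, min_cycle_s=0.4)
        # independent strict local-minima scan
        interior = [
            i for i in range(1, len(env) - 1) if env[i] < env[i - 1] and env[i] <= env[i + 1]
        ]
        assert abs(len(boundaries) - 2 - len(interior)) <= 1
        assert partial[0] and partial[-1]

    def test_monotone_trace_is_single_cycle(self):
        x = np.linspace(0, 1, 200)
        trace = GaitTrace(sampling_rate=100.0, angular_velocity=x, angle=x)
        boundaries, partial = segment_cycles(trace)
        assert len(boundaries) == 2
        assert partial.tolist() == [True]

    def test_simulator_cycle_count_recovered_at_default_noise(self):
        config = SimulationConfig(trial_duration=30.0, seed=13)
        lat = generate_latent_profile(config, 0, "speed")
        trace, truth = synthesize_gait(config, lat)
        processed = process_gait(trace)
        assert processed.n_cycles == len(truth["cycle_boundaries"]) - 1


class TestStaircase:
    def test_single_cycle_max(self):
        np.testing.assert_array_equal(
            staircase(np.array([1.0, 3.0, 2.0]), np.array([0, 3])), [3, 3, 3]
        )

    def test_two_cycle_oracle(self):
        np.testing.assert_array_equal(
            staircase(np.array([1.0, 2.0, 5.0, 4.0]), np.array([0, 2, 4])), [2, 2, 5, 5]
        )

    @settings(derandomize=True, max_examples=25)
    @given(st.lists(st.floats(0, 100), min_size=6, max_size=40), st.randoms())
    def test_invariant_to_within_cycle_permutation(self, values, rnd):
        x = np.asarray(values)
        b = np.array([0, len(x) // 2, len(x)])
        shuffled = x.copy()
        idx = list(range(0, len(x) // 2))
        rnd.shuffle(idx)
        shuffled[: len(x) // 2] = x[idx]
        np.testing.assert_array_equal(staircase(x, b), staircase(shuffled, b))

    def test_constant_within_each_cycle(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=50)
        b = np.array([0, 17, 30, 50])
        out = staircase(x, b)
        for b0, b1 in zip(b[:-1], b[1:]):
            assert np.ptp(out[b0:b1]) == 0.0
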