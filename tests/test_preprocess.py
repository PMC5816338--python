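import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vvorkit import (
    DesaccadeParams,
    SignConvention,
    apply_sign_convention,
    auc_gain,
    desaccade,
    identity_desaccade,
    select_window,
    simulate_vvor,
)
from vvorkit.errors import ParameterError, TooShortError
from vvorkit.synth import SynthParams, preset

from conftest import make_sine_trace


def brute_force_median(x, n, edge_mode):
    """Independent windowed-median oracle: explicit window, sort, middle."""
    left, right = n // 2, n - 1 - n // 2
    out = np.empty_like(x)
    for i in range(len(x)):
        window = []
        for j in range(i - left, i + right + 1):
            if 0 <= j < len(x):
                window.append(x[j])
            elif edge_mode == "zero":
                window.append(0.0)
            else:  # reflect (no repeated edge sample)
                k = -j if j < 0 else 2 * (len(x) - 1) - j
                window.append(x[k])
        window = sorted(window)
        m = len(window)
        out[i] = (window[m // 2] if m % 2 else
                  0.5 * (window[m // 2 - 1] + window[m // 2]))
    return out


class TestSelectWindow:
    def test_selects_ten_seconds_after_one_second_discard(self):
        trace = make_sine_trace(duration=20.0)
        win = select_window(trace, 10.0)
        # original seconds [1, 11), re-based to start at 0
        assert win.t[0] == 0.0
        assert win.duration == pytest.approx(10.0, abs=2 / trace.sample_rate)
        np.testing.assert_allclose(
            win.head_vel[0], trace.head_vel[np.searchsorted(trace.t, 1.0)])

    def test_short_recording_falls_back_with_warning(self):
        trace = make_sine_trace(duration=8.0)
        with pytest.warns(UserWarning, match="shorter"):
            win = select_window(trace, 10.0)
        assert win.duration == pytest.approx(7.0, abs=2 / trace.sample_rate)

    def test_under_two_seconds_rejected(self):
        trace = make_sine_trace(duration=1.5)
        with pytest.raises(TooShortError):
            select_window(trace, 10.0)

    def test_window_gains_match_full_trace_for_noiseless_input(self):
        trace, _ = simulate_vvor(
            SynthParams(duration=20.0, g_pos=0.8, g_neg=0.7, noise_sd=0.0))
        g_full = auc_gain(identity_desaccade(trace))
        g_win = auc_gain(identity_desaccade(select_window(trace, 10.0)))
        assert g_win.g_pos == pytest.approx(g_full.g_pos, abs=0.01)
        assert g_win.g_neg == pytest.approx(g_full.g_neg, abs=0.01)


class TestSignConvention:
    def test_no_flags_is_identity(self, sine_trace):
        out = apply_sign_convention(sine_trace, SignConvention())
        np.testing.assert_array_equal(out.head_vel, sine_trace.head_vel)
        np.testing.assert_array_equal(out.eye_vel, sine_trace.eye_vel)

    def test_invert_head_is_involution(self, sine_trace):
        conv = SignConvention(invert_head=True)
        twice = apply_sign_convention(apply_sign_convention(sine_trace, conv), conv)
        np.testing.assert_array_equal(twice.head_vel, sine_trace.head_vel)

    def test_inverting_both_channels_swaps_directional_gains(self):
        trace, _ = simulate_vvor(preset("unilateral", seed=4, noise_sd=0.0,
                                        saccades_per_cycle=0.0))
        g = auc_gain(identity_desaccade(trace))
        flipped = apply_sign_convention(
            trace, SignConvention(invert_head=True, invert_eye=True))
        g_f = auc_gain(identity_desaccade(flipped))
        assert g_f.g_pos == g.g_neg
        assert g_f.g_neg == g.g_pos

    def test_inverting_head_alone_negates_and_swaps(self):
        # eye becomes anti-compensatory to the inverted head channel
        trace, _ = simulate_vvor(preset("unilateral", seed=4, noise_sd=0.0,
                                        saccades_per_cycle=0.0))
        g = auc_gain(identity_desaccade(trace))
        g_f = auc_gain(identity_desaccade(
            apply_sign_convention(trace, SignConvention(invert_head=True))))
        assert g_f.g_pos == pytest.approx(-g.g_neg, abs=1e-12)
        assert g_f.g_neg == pytest.approx(-g.g_pos, abs=1e-12)


class TestDesaccade:
    def test_constant_signal_passes_through(self):
        trace = make_sine_trace(eye=np.full(2200, 50.0))
        d = desaccade(trace, DesaccadeParams(n=30, edge_mode="reflect"))
        np.testing.assert_array_equal(d.eye_filtered, 50.0)
        np.testing.assert_array_equal(d.residual, 0.0)

    def test_lone_spike_removed_and_kept_in_residual(self):
        eye = np.zeros(2200)
        eye[1000] = 300.0
        trace = make_sine_trace(eye=eye)
        d = desaccade(trace, DesaccadeParams(n=30))
        assert np.all(d.eye_filtered[900:1100] == 0.0)
        assert d.residual[1000] == 300.0

    @pytest.mark.parametrize("n", [29, 30])
    @pytest.mark.parametrize("edge_mode", ["zero", "reflect"])
    def test_matches_brute_force_windowed_median(self, n, edge_mode):
        rng = np.random.default_rng(12)
        x = rng.normal(0, 50, 200)
        trace = make_sine_trace(duration=200 / 220, eye=x)
        d = desaccade(trace, DesaccadeParams(n=n, edge_mode=edge_mode))
        np.testing.assert_array_equal(
            d.eye_filtered, brute_force_median(x, n, edge_mode))

    def test_window_larger_than_trace_rejected(self):
        trace = make_sine_trace(duration=0.1)
        with pytest.raises(ParameterError):
            desaccade(trace, DesaccadeParams(n=30))

    def test_tiny_window_rejected(self):
        with pytest.raises(ParameterError):
            DesaccadeParams(n=2)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1), st.floats(-100, 100))
    def test_shift_invariance(self, seed, c):
        # median filter commutes with adding a constant (reflect mode: no
        # foreign padding values enter the window)
        x = np.random.default_rng(seed).normal(0, 30, 120)
        trace_a = make_sine_trace(duration=120 / 220, eye=x)
        trace_b = make_sine_trace(duration=120 / 220, eye=x + c)
        params = DesaccadeParams(n=30, edge_mode="reflect")
        np.testing.assert_allclose(
            desaccade(trace_b, params).eye_filtered,
            desaccade(trace_a, params).eye_filtered + c,
            atol=1e-10,
        )

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_monotonicity(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(0, 30, 120)
        y = x + np.abs(rng.normal(0, 10, 120))  # y >= x elementwise
        params = DesaccadeParams(n=30)
        fx = desaccade(make_sine_trace(duration=120 / 220, eye=x), params).eye_filtered
        fy = desaccade(make_sine_trace(duration=120 / 220, eye=y), params).eye_filtered
        assert np.all(fy >= fx - 1e-12)

    @pytest.mark.parametrize("fs,freq", [(220.0, 1.0), (220.0, 1.52), (220.0, 2.0)])
    def test_peak_flattening_matches_analytic_bound(self, fs, freq):
        # the running median flattens a sinusoid's peak by about
        # A * (1 - cos(a/2)) where a = pi * f * n / fs is the phase
        # half-span of the window; interior residual must not exceed it
        n = 30
        amp = 100.0
        trace = make_sine_trace(fs=fs, freq=freq, head_amp=150.0,
                                eye=amp * np.sin(2 * np.pi * freq *
                                                 np.arange(int(10 * fs)) / fs))
        d = desaccade(trace, DesaccadeParams(n=n))
        interior = slice(n, len(trace) - n)
        bound = amp * (1 - np.cos(np.pi * freq * n / fs / 2))
        assert np.max(np.abs(d.residual[interior])) <= 1.1 * bound + 1e-9
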