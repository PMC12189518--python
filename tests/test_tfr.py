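"""Morlet CWT: wavelet values, scale-frequency mapping, oracle equivalence,
frequency localization, and image rendering."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cdml_eeg import (MorletParams, Scalogram, compute_scale_grid, cwt, morlet,
                      render_tfr, ridge_frequency)

FS = 250.0
P = MorletParams()


def direct_cwt(x: np.ndarray, grid, params: MorletParams) -> np.ndarray:
    """Independent oracle: trapezoidal quadrature of the transform integral,
    W(s, tau) = (1/sqrt(s)) * sum_t x(t) conj(phi((t - tau)/s)), evaluated
    without any convolution machinery."""
    t = np.arange(x.size, dtype=float)
    out = np.empty((grid.n_scales, x.size))
    for i, s in enumerate(grid.scales):
        for tau in range(x.size):
            kernel = np.conj(morlet(t, s, float(tau), params))
            out[i, tau] = np.abs(np.trapezoid(x * kernel, dx=1.0))
    return out


class TestMorletWavelet:
    @pytest.mark.parametrize("s", [0.5, 2.0, 17.3])
    def test_center_value_is_pi_quarter_over_sqrt_s(self, s):
        val = morlet(3.0, s, 3.0)
        assert val == pytest.approx(math.pi ** -0.25 / math.sqrt(s))
        assert val.imag == 0 and val.real > 0

    def test_one_scale_off_center_modulus(self):
        s, tau = 4.0, 1.0
        expected = math.pi ** -0.25 * math.exp(-0.5) / math.sqrt(s)
        assert abs(morlet(tau + s, s, tau)) == pytest.approx(expected)

    @given(st.floats(-40, 40), st.floats(0.3, 30))
    @settings(deadline=None, max_examples=50)
    def test_modulus_symmetric_about_shift(self, dt, s):
        tau = 5.0
        assert abs(morlet(tau + dt, s, tau)) == pytest.approx(
            abs(morlet(tau - dt, s, tau)), rel=1e-12, abs=1e-300)

    def test_nonpositive_scale_rejected(self):
        with pytest.raises(ValueError):
            morlet(0.0, 0.0)


class TestScaleGrid:
    def test_endpoint_scales_with_unit_center_frequency(self):
        # fc = 1 corresponds to omega0 = 2*pi
        grid = compute_scale_grid(MorletParams(omega0=2 * math.pi), fs=250.0)
        assert grid.scales[0] == pytest.approx(250.0 / 30.0)  # ~8.3333
        assert grid.scales[-1] == pytest.approx(31.25)

    def test_default_grid_spans_band_geometrically(self):
        grid = compute_scale_grid(P, FS)
        assert grid.n_scales == 250
        assert grid.freqs[0] == pytest.approx(30.0)
        assert grid.freqs[-1] == pytest.approx(8.0)
        ratios = grid.scales[1:] / grid.scales[:-1]
        np.testing.assert_allclose(ratios, ratios[0], rtol=1e-9)
        assert np.all((grid.freqs >= 8.0 - 1e-9) & (grid.freqs <= 30.0 + 1e-9))

    def test_nominal_row_resolution(self):
        lo, hi = compute_scale_grid(P, FS).band
        assert (hi - lo) / 250 == pytest.approx(0.088)

    def test_invalid_band_rejected(self):
        with pytest.raises(ValueError):
            compute_scale_grid(P, FS, fmin=30.0, fmax=8.0)


class TestCwtOracle:
    def test_fft_path_equals_direct_integration(self):
        rng = np.random.default_rng(42)
        x = rng.normal(size=256)
        grid = compute_scale_grid(P, FS, n_scales=25)
        fast = cwt(x, grid, P, edge="none").values
        ref = direct_cwt(x, grid, P)
        assert np.abs(fast - ref).max() <= 1e-6 * np.abs(ref).max()

    def test_fft_path_equals_direct_on_tone(self):
        t = np.arange(200) / FS
        x = np.sin(2 * np.pi * 15.0 * t)
        grid = compute_scale_grid(P, FS, n_scales=12)
        fast = cwt(x, grid, P, edge="none").values
        ref = direct_cwt(x, grid, P)
        assert np.abs(fast - ref).max() <= 1e-6 * np.abs(ref).max()

    def test_zero_signal_gives_zero_scalogram(self):
        grid = compute_scale_grid(P, FS, n_scales=10)
        assert np.all(cwt(np.zeros(100), grid, P).values == 0)

    def test_magnitude_homogeneity(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=300)
        grid = compute_scale_grid(P, FS, n_scales=10)
        np.testing.assert_allclose(cwt(7.5 * x, grid, P).values,
                                   7.5 * cwt(x, grid, P).values, rtol=1e-10)

    def test_too_short_signal_rejected(self):
        grid = compute_scale_grid(P, FS, n_scales=10)
        with pytest.raises(ValueError):
            cwt(np.array([1.0]), grid, P)


class TestLocalization:
    @pytest.mark.parametrize("f", [9.0, 12.0, 15.0, 20.0, 25.0, 29.0])
    def test_tone_ridge_within_one_grid_step(self, f):
        grid = compute_scale_grid(P, FS)
        t = np.arange(int(5 * FS)) / FS
        scal = cwt(np.sin(2 * np.pi * f * t), grid, P)
        est = ridge_frequency(scal, grid)
        step = (30.0 / 8.0) ** (1.0 / (grid.n_scales - 1))
        assert abs(math.log(est / f)) <= math.log(step) * 1.0001

    def test_two_tones_give_two_ridges(self):
        grid = compute_scale_grid(P, FS)
        t = np.arange(int(5 * FS)) / FS
        x = np.sin(2 * np.pi * 10.0 * t) + np.sin(2 * np.pi * 25.0 * t)
        scal = cwt(x, grid, P)
        profile = (scal.values / np.sqrt(grid.scales)[:, None]).mean(axis=1)
        # local maxima of the amplitude-flat profile
        peaks = [i for i in range(1, len(profile) - 1)
                 if profile[i] >= profile[i - 1] and profile[i] >= profile[i + 1]
                 and profile[i] > 0.5 * profile.max()]
        peak_freqs = sorted(grid.freqs[i] for i in peaks)
        assert len(peak_freqs) == 2
        step = (30.0 / 8.0) ** (1.0 / (grid.n_scales - 1))
        # spectral interference between simultaneous components can push a
        # ridge slightly beyond the single-tone one-step bound
        for est, true in zip(peak_freqs, [10.0, 25.0]):
            assert abs(math.log(est / true)) <= 2 * math.log(step)

    def test_independent_wavelet_library_agrees_on_ridge(self):
        """Cross-check localization against PyWavelets' complex Morlet CWT."""
        pywt = pytest.importorskip("pywt")
        t = np.arange(int(5 * FS)) / FS
        x = np.sin(2 * np.pi * 15.0 * t)
        grid = compute_scale_grid(P, FS)
        ours = ridge_frequency(cwt(x, grid, P), grid)
        # cmorB-C with B=2, C=fc is exp(2*pi*i*C*u) exp(-u^2/2): same atom,
        # different normalisation; ridge location is comparable
        coef, freqs = pywt.cwt(x, grid.scales, f"cmor2.0-{P.fc:.6f}",
                               sampling_period=1.0 / FS)
        theirs = freqs[np.abs(coef).mean(axis=1).argmax()]
        assert abs(ours - theirs) / 15.0 < 0.03


class TestRenderTfr:
    def test_trial_length_scalogram_renders_250x250(self):
        rng = np.random.default_rng(0)
        grid = compute_scale_grid(P, FS)
        scal = cwt(rng.normal(size=1250), grid, P)
        img = render_tfr(scal)
        assert img.pixels.shape == (250, 250)
        assert img.pixels.min() == 0.0 and img.pixels.max() == 1.0

    def test_constant_scalogram_renders_uniform_half(self):
        grid = compute_scale_grid(P, FS, n_scales=250)
        scal = Scalogram(values=np.full((250, 1250), 3.3),
                         time_axis=np.arange(1250) / FS,
                         freq_axis=grid.freqs)
        assert np.all(render_tfr(scal).pixels == 0.5)

    def test_rendering_invariant_to_signal_gain(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=1250)
        grid = compute_scale_grid(P, FS)
        a = render_tfr(cwt(x, grid, P)).pixels
        b = render_tfr(cwt(100.0 * x, grid, P)).pixels
        np.testing.assert_allclose(a, b, atol=1e-6)

    def test_block_average_reduces_time_axis(self):
        # 4 columns -> 2: block means, then min-max to [0, 1]
        vals = np.array([[0.0, 2.0, 4.0, 6.0]] * 3)
        scal = Scalogram(values=vals, time_axis=np.arange(4) / FS,
                         freq_axis=np.array([30.0, 15.0, 8.0]))
        img = render_tfr(scal, out_size=(3, 2))
        np.testing.assert_allclose(img.pixels, [[0.0, 1.0]] * 3)

    @given(st.integers(0, 2 ** 31 - 1))
    @settings(deadline=None, max_examples=15)
    def test_output_always_in_unit_interval(self, seed):
        rng = np.random.default_rng(seed)
        vals = np.abs(rng.normal(size=(6, 30))) * rng.uniform(0, 1e6)
        scal = Scalogram(values=vals, time_axis=np.arange(30.0),
                         freq_axis=np.linspace(30, 8, 6))
        img = render_tfr(scal, out_size=(6, 10))
        assert img.pixels.min() >= 0.0 and img.pixels.max() <= 1.0

    def test_wrong_row_count_rejected(self):
        scal = Scalogram(values=np.ones((10, 100)), time_axis=np.arange(100.0),
                         freq_axis=np.linspace(30, 8, 10))
        with pytest.raises(ValueError):
            render_tfr(scal, out_size=(250, 250))
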