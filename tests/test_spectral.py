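"""Spectral-stage tests: notch filter, padding, windowing, FFT power
spectrum, moving-trend-filter smoothing, normalization, regridding."""

import numpy as np
import pytest

from emgspecvar import SpectralConfig, Spectrum
from emgspecvar.spectral import (apply_window, common_grid, mtf_smooth,
                                 mtf_values, normalize, notch_filter,
                                 pad_to_reference, power_spectrum, regrid)

FS = 2000.0


def naive_mtf(s, span_bins, order):
    """Literal double-loop implementation: for every window position
    covering a bin, least-squares polynomial fit on u in [-1, 1], evaluate
    at the bin, average."""
    s = np.asarray(s, dtype=float)
    m = 2 * (span_bins // 2) + 1
    L = s.size
    u = np.linspace(-1.0, 1.0, m)
    out = np.zeros(L)
    for n in range(L):
        vals = []
        for s0 in range(max(0, n - m + 1), min(n, L - m) + 1):
            coef = np.polynomial.polynomial.polyfit(u, s[s0:s0 + m], order)
            vals.append(np.polynomial.polynomial.polyval(u[n - s0], coef))
        out[n] = np.mean(vals)
    return out


class TestNotch:
    def test_attenuates_50hz(self):
        # contraction-length tone; edges trimmed past the filter transient
        t = np.arange(int(5 * FS)) / FS
        x = np.sin(2 * np.pi * 50.0 * t)
        y = notch_filter(x, FS, 50.0, 35.0)
        core = slice(int(0.5 * FS), -int(0.5 * FS))
        assert np.sqrt(np.mean(y[core] ** 2)) < 0.01 * np.sqrt(np.mean(x[core] ** 2))

    def test_passes_200hz(self):
        t = np.arange(int(5 * FS)) / FS
        x = np.sin(2 * np.pi * 200.0 * t)
        y = notch_filter(x, FS, 50.0, 35.0)
        core = slice(int(0.5 * FS), -int(0.5 * FS))
        assert abs(np.sqrt(np.mean(y[core] ** 2))
                   / np.sqrt(np.mean(x[core] ** 2)) - 1.0) < 0.02

    def test_zero_in_zero_out(self):
        assert np.allclose(notch_filter(np.zeros(500), FS), 0.0)

    def test_invalid_frequency_raises(self):
        with pytest.raises(ValueError):
            notch_filter(np.zeros(100), FS, 1500.0, 35.0)


class TestPadding:
    def test_equal_lengths_unchanged(self, rng):
        segs = [rng.normal(size=50) for _ in range(3)]
        padded, n = pad_to_reference(segs)
        assert n == 50
        for a, b in zip(padded, segs):
            np.testing.assert_array_equal(a, b)

    def test_trailing_zeros(self, rng):
        a, b = rng.normal(size=100), rng.normal(size=80)
        padded, n = pad_to_reference([a, b])
        assert n == 100
        np.testing.assert_array_equal(padded[1][:80], b)
        assert np.all(padded[1][80:] == 0.0)

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            pad_to_reference([])

    def test_padding_preserves_original_resolution_bins(self):
        # when N is a multiple of the original length, the padded DFT at
        # every k-th bin equals the original DFT
        n0, k = 128, 4
        t = np.arange(n0)
        x = np.sin(2 * np.pi * 10 * t / n0)
        padded, _ = pad_to_reference([x, np.zeros(n0 * k)])
        full = np.fft.rfft(padded[0])
        orig = np.fft.rfft(x)
        np.testing.assert_allclose(full[::k], orig, atol=1e-9)


class TestWindow:
    def test_ones_give_the_taper(self):
        from scipy.signal.windows import hann
        n = 201
        np.testing.assert_array_equal(apply_window(np.ones(n)),
                                      hann(n, sym=True))

    def test_zero_endpoints(self, rng):
        y = apply_window(rng.normal(size=64))
        assert y[0] == 0.0 and y[-1] == 0.0

    def test_sum_of_squares_near_3n_over_8(self):
        for n in (64, 501, 1024):
            w = apply_window(np.ones(n))
            assert abs(np.sum(w**2) - 3 * n / 8) <= 1.0


class TestPowerSpectrum:
    def test_zero_input(self):
        spec = power_spectrum(np.zeros(256), FS)
        assert np.all(spec.p == 0.0)

    def test_pure_tone_bin_power(self):
        n, m0, amp = 2000, 100, 3.0
        t = np.arange(n)
        x = amp * np.sin(2 * np.pi * m0 * t / n)
        spec = power_spectrum(x, FS, (0.0, FS / 2))
        k = np.argmin(np.abs(spec.f - m0 * FS / n))
        np.testing.assert_allclose(spec.p[k], (n * amp / 2) ** 2, rtol=1e-9)

    def test_parseval(self, rng):
        x = rng.normal(size=512)
        spec = power_spectrum(x, FS, (0.0, FS / 2))
        # reconstruct the two-sided energy from the one-sided spectrum
        two_sided = spec.p[0] + 2 * spec.p[1:-1].sum() + spec.p[-1]
        np.testing.assert_allclose(two_sided, 512 * np.sum(x**2), rtol=1e-9)

    def test_band_truncation(self, rng):
        spec = power_spectrum(rng.normal(size=1000), FS, (0.0, 500.0))
        assert spec.f[-1] <= 500.0
        assert spec.f[0] >= 0.0


class TestMtf:
    CFG = SpectralConfig()

    def test_reproduces_cubic(self, rng):
        f = np.arange(500.0)
        coefs = rng.normal(size=4)
        s = np.polynomial.polynomial.polyval(f / 500.0, coefs)
        out = mtf_values(s, self.CFG.mtf_span_bins, 3)
        assert np.max(np.abs(out - s)) <= 1e-8 * np.max(np.abs(s))

    def test_constant_preserved(self):
        s = np.full(400, 3.7)
        np.testing.assert_allclose(
            mtf_values(s, self.CFG.mtf_span_bins, 3), 3.7, rtol=1e-10)

    def test_matches_naive_double_loop(self, rng):
        s = rng.normal(size=120)
        fast = mtf_values(s, 20, 3)
        slow = naive_mtf(s, 20, 3)
        assert np.max(np.abs(fast - slow)) < 1e-9

    def test_linearity(self, rng):
        x, y = rng.normal(size=300), rng.normal(size=300)
        a, b = 2.3, -1.7
        lhs = mtf_values(a * x + b * y, 40, 3)
        rhs = a * mtf_values(x, 40, 3) + b * mtf_values(y, 40, 3)
        np.testing.assert_allclose(lhs, rhs, atol=1e-9)

    def test_lowpass_variance_reduction(self, rng):
        s = rng.normal(size=2000)
        out = mtf_values(s, self.CFG.mtf_span_bins, 3)
        assert np.var(out) / np.var(s) < 0.2

    def test_span_longer_than_spectrum_raises(self):
        spec = Spectrum(f=np.arange(50.0), p=np.ones(50), n_fft=100)
        with pytest.raises(ValueError):
            mtf_smooth(spec, self.CFG)

    def test_clipping_nonnegative(self, rng):
        f = np.arange(400.0)
        spec = Spectrum(f=f, p=rng.normal(size=400), n_fft=800)
        out = mtf_smooth(spec, self.CFG, clip=True)
        assert np.all(out.p >= 0.0)
        assert out.smoothing == "mtf"


class TestNormalize:
    def test_max_mode(self):
        spec = Spectrum(f=np.arange(3.0), p=np.array([1.0, 4.0, 2.0]), n_fft=6)
        np.testing.assert_allclose(normalize(spec, "max").p, [0.25, 1.0, 0.5])

    def test_energy_mode(self):
        spec = Spectrum(f=np.arange(3.0), p=np.array([1.0, 4.0, 2.0]), n_fft=6)
        out = normalize(spec, "energy")
        np.testing.assert_allclose(out.p, np.array([1, 4, 2]) / 7.0)
        np.testing.assert_allclose(out.p.sum(), 1.0, atol=1e-12)

    def test_all_zero_raises(self):
        spec = Spectrum(f=np.arange(3.0), p=np.zeros(3), n_fft=6)
        with pytest.raises(ValueError):
            normalize(spec, "max")

    def test_unknown_mode_raises(self):
        spec = Spectrum(f=np.arange(3.0), p=np.ones(3), n_fft=6)
        with pytest.raises(ValueError):
            normalize(spec, "l2")


class TestRegrid:
    def test_identity_on_same_grid(self, rng):
        f = np.linspace(0.0, 100.0, 201)
        spec = Spectrum(f=f, p=rng.uniform(size=201), n_fft=402)
        np.testing.assert_allclose(regrid(spec, f).p, spec.p, atol=1e-12)

    def test_linear_ramp_exact(self):
        f = np.linspace(0.0, 100.0, 101)
        spec = Spectrum(f=f, p=2.0 * f + 5.0, n_fft=202)
        target = np.linspace(0.0, 100.0, 41)
        np.testing.assert_allclose(regrid(spec, target).p, 2.0 * target + 5.0,
                                   atol=1e-12)

    def test_matches_pointwise_interpolation(self, rng):
        f = np.linspace(0.0, 100.0, 201)
        p = rng.uniform(size=201)
        spec = Spectrum(f=f, p=p, n_fft=402)
        target = np.linspace(0.0, 100.0, 101)
        out = regrid(spec, target)
        for k in (0, 10, 57, 100):
            ft = target[k]
            i = np.searchsorted(f, ft)
            if f[i] == ft:
                expected = p[i]
            else:
                w = (ft - f[i - 1]) / (f[i] - f[i - 1])
                expected = (1 - w) * p[i - 1] + w * p[i]
            assert abs(out.p[k] - expected) < 1e-12

    def test_out_of_range_raises(self):
        spec = Spectrum(f=np.linspace(0, 100, 101), p=np.ones(101), n_fft=202)
        with pytest.raises(ValueError):
            regrid(spec, np.linspace(0, 150, 10))

    def test_renormalization_preserved(self, rng):
        f = np.linspace(0.0, 100.0, 201)
        spec = normalize(Spectrum(f=f, p=rng.uniform(size=201) + 0.1,
                                  n_fft=402), "energy")
        out = regrid(spec, np.linspace(0.0, 100.0, 73))
        np.testing.assert_allclose(out.p.sum(), 1.0, atol=1e-12)


class TestEndToEnd:
    def test_synth_segment_spectrum_is_low_frequency_dominated(
            self, small_cohort):
        # normalized contraction spectra concentrate their energy well
        # below 250 Hz
        from emgspecvar import segment_recording
        cfg = SpectralConfig()
        rec = small_cohort.recordings[0]
        segs = segment_recording(rec)
        series = [s.data[:, 0] for s in segs]
        padded, _ = pad_to_reference([notch_filter(v, rec.fs) for v in series])
        for v in padded:
            spec = power_spectrum(apply_window(v), rec.fs,
                                  cfg.analysis_band_hz)
            spec = normalize(mtf_smooth(spec, cfg), "energy")
            centroid = np.sum(spec.f * spec.p)
            assert centroid < 250.0

    def test_common_grid_respects_sources(self):
        cfg = SpectralConfig()
        grid = common_grid([499.86, 499.93], cfg)
        assert grid[0] == 0.0
        assert grid[-1] <= 499.86
        np.testing.assert_allclose(np.diff(grid), cfg.common_grid_df_hz)
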