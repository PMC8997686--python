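"""Tests for the Morse wavelet, CWT filter bank and image rendering.

The FFT-based transform is checked against a brute-force oracle that uses
explicit DFT summation and an explicit circular convolution (no np.fft).
"""

import numpy as np
import pytest

from bcgnet.preprocess import Epoch
from bcgnet.scalogram import (
    MorseParams,
    ScalogramImage,
    build_filterbank,
    cwt_signal,
    epoch_to_image,
    morse_psi,
    render_scalogram,
    resize_image,
)


def make_epoch(x, fs=100.0):
    return Epoch("s", "HC", 0, fs, np.asarray(x, dtype=float))


class TestMorsePsi:
    def test_peak_angular_frequency_closed_form(self):
        p = MorseParams(gamma=3.0, p2=60.0)
        assert p.beta == pytest.approx(20.0)
        assert p.peak_omega == pytest.approx((20.0 / 3.0) ** (1.0 / 3.0), rel=1e-12)
        assert p.peak_omega == pytest.approx(1.88207, abs=1e-5)

    def test_zero_for_nonpositive_frequencies(self):
        psi = morse_psi(np.array([-2.0, -0.5, 0.0]))
        assert np.all(psi == 0)

    def test_peak_value_is_two(self):
        p = MorseParams()
        assert morse_psi(np.array([p.peak_omega]), p)[0] == pytest.approx(2.0, rel=1e-12)
        w = np.linspace(0.01, 10.0, 5000)
        assert morse_psi(w, p).max() <= 2.0 + 1e-9

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            morse_psi(np.array([1.0]), MorseParams(gamma=-1.0))
        with pytest.raises(ValueError):
            morse_psi(np.array([1.0]), MorseParams(gamma=3.0, p2=2.0))


class TestFilterBank:
    def test_adjacent_ratio_is_one_voice(self):
        bank = build_filterbank(100.0, 3000)
        ratios = bank.center_freqs[:-1] / bank.center_freqs[1:]
        np.testing.assert_allclose(ratios, 2.0 ** (1.0 / 12.0), rtol=1e-12)

    def test_scale_count_for_default_band(self):
        bank = build_filterbank(100.0, 3000, fmin=0.5, fmax=50.0)
        assert len(bank.center_freqs) == 80
        assert bank.center_freqs[0] == pytest.approx(50.0)
        assert bank.center_freqs[-1] >= 0.5

    def test_filters_analytic(self):
        bank = build_filterbank(100.0, 256)
        omega = 2 * np.pi * np.fft.fftfreq(256, d=0.01)
        assert np.all(bank.filters[:, omega <= 0] == 0)

    def test_above_nyquist_rejected(self):
        with pytest.raises(ValueError):
            build_filterbank(100.0, 3000, fmin=60.0, fmax=70.0)
        with pytest.raises(ValueError):
            build_filterbank(100.0, 3000, fmin=5.0, fmax=1.0)


class TestCWT:
    def test_zero_signal_gives_zero_magnitude(self):
        bank = build_filterbank(100.0, 512)
        scal = cwt_signal(np.zeros(512), bank)
        assert np.all(scal.magnitude == 0)

    def test_linearity(self):
        bank = build_filterbank(100.0, 512)
        x = np.random.default_rng(0).normal(size=512)
        a = cwt_signal(x, bank).magnitude
        b = cwt_signal(2.0 * x, bank).magnitude
        np.testing.assert_allclose(b, 2.0 * a, atol=1e-9)

    def test_length_mismatch_rejected(self):
        bank = build_filterbank(100.0, 512)
        with pytest.raises(ValueError):
            cwt_signal(np.zeros(100), bank)

    def test_sinusoid_ridge_within_one_voice_of_5hz(self):
        fs, n = 100.0, 3000
        bank = build_filterbank(fs, n)
        t = np.arange(n) / fs
        scal = cwt_signal(np.sin(2 * np.pi * 5.0 * t), bank)
        central = slice(n // 4, 3 * n // 4)
        ridge = bank.center_freqs[np.argmax(scal.magnitude[:, central].mean(axis=1))]
        assert 5.0 * 2.0 ** (-1 / 12) <= ridge <= 5.0 * 2.0 ** (1 / 12)

    def test_chirp_ridge_monotone_in_time(self):
        fs, n = 100.0, 2048
        t = np.arange(n) / fs
        f0, f1 = 2.0, 20.0
        x = np.sin(2 * np.pi * (f0 * t + (f1 - f0) * t**2 / (2 * t[-1])))
        bank = build_filterbank(fs, n)
        scal = cwt_signal(x, bank)
        cols = np.linspace(n // 5, 4 * n // 5, 8, dtype=int)
        ridge = [bank.center_freqs[np.argmax(scal.magnitude[:, c])] for c in cols]
        assert all(b >= a for a, b in zip(ridge, ridge[1:]))

    def test_fft_path_matches_brute_force_oracle(self):
        """O(N^2) oracle: explicit DFT sums + explicit circular convolution."""
        fs, n = 100.0, 256
        rng = np.random.default_rng(7)
        x = rng.normal(size=n) + np.sin(2 * np.pi * 6.0 * np.arange(n) / fs)
        bank = build_filterbank(fs, n, fmin=2.0, fmax=20.0)
        scal = cwt_signal(x, bank)

        k = np.arange(n)
        idft = np.exp(2j * np.pi * np.outer(k, k) / n) / n  # explicit inverse DFT matrix
        margin = n // 10
        core = slice(margin, n - margin)
        for si in range(0, len(bank.center_freqs), 7):
            wavelet_time = idft @ bank.filters[si]  # time-domain wavelet samples
            direct = np.array(
                [np.sum(x * np.roll(wavelet_time[::-1], m + 1)) for m in range(n)]
            )
            ref = np.abs(direct)
            err = np.abs(scal.magnitude[si] - ref)[core]
            assert err.max() / ref[core].max() < 1e-6


class TestRendering:
    def test_default_render_is_224(self):
        bank = build_filterbank(100.0, 512)
        scal = cwt_signal(np.random.default_rng(1).normal(size=512), bank)
        img = render_scalogram(scal)
        assert img.pixels.shape == (224, 224)
        assert img.pixels.dtype == np.uint8

    def test_constant_magnitude_maps_to_zero_image(self):
        bank = build_filterbank(100.0, 64)
        scal = cwt_signal(np.zeros(64), bank)
        scal.magnitude[:] = 3.7
        img = render_scalogram(scal, side=32)
        assert np.all(img.pixels == 0)

    def test_global_maximum_maps_to_255(self):
        bank = build_filterbank(100.0, 512)
        scal = cwt_signal(np.sin(2 * np.pi * 5 * np.arange(512) / 100.0), bank)
        img = render_scalogram(scal, side=224)
        assert img.pixels.max() == 255 and img.pixels.min() == 0

    def test_resize_224_to_32(self):
        img = ScalogramImage(pixels=np.random.default_rng(2).integers(0, 256, (224, 224)).astype(np.uint8))
        out = resize_image(img, 32)
        assert out.pixels.shape == (32, 32)

    def test_resize_identity_and_uniform(self):
        uni = ScalogramImage(pixels=np.full((32, 32), 200, dtype=np.uint8))
        assert np.all(resize_image(uni, 32).pixels == uni.pixels)
        big = ScalogramImage(pixels=np.full((224, 224), 123, dtype=np.uint8))
        assert np.all(resize_image(big, 32).pixels == 123)

    def test_invalid_side_rejected(self):
        img = ScalogramImage(pixels=np.zeros((32, 32), dtype=np.uint8))
        with pytest.raises(ValueError):
            resize_image(img, 0)

    def test_png_bytes_deterministic(self):
        bank = build_filterbank(100.0, 3000)
        x = np.random.default_rng(3).normal(size=3000)
        a = epoch_to_image(make_epoch(x), bank).to_png_bytes()
        b = epoch_to_image(make_epoch(x), bank).to_png_bytes()
        assert a == b
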