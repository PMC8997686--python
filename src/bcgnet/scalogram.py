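"""Generalized Morse wavelet CWT and scalogram image rendering.

The continuous wavelet transform is computed with an analytic generalized
Morse wavelet defined in the frequency domain,

    Psi(omega) = 2 H(omega) (omega/omega_p)^beta
                 exp(beta/gamma * (1 - (omega/omega_p)^gamma)),

where ``beta = P^2/gamma`` and the peak angular frequency is
``omega_p = (beta/gamma)^(1/gamma)``.  The wavelet is exactly analytic
(zero for omega <= 0) and peak-normalized to 2.  With the defaults
gamma=3, P^2=60 this is the Morse (3,60) wavelet; scales are laid out on a
geometric grid with 12 voices per octave.

The CWT is evaluated by FFT circular convolution: for each scale the
coefficients are ``ifft(fft(x) * Psi(s*omega))``.  Magnitudes are rendered
to square 8-bit grayscale images (log compression, min-max scaling,
bilinear resampling), by default 224x224 and then 32x32 for the CNN.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from PIL import Image

from .preprocess import Epoch

__all__ = [
    "MorseParams",
    "FilterBank",
    "Scalogram",
    "ScalogramImage",
    "morse_psi",
    "build_filterbank",
    "cwt_epoch",
    "cwt_signal",
    "render_scalogram",
    "resize_image",
    "epoch_to_image",
]


@dataclass(frozen=True)
class MorseParams:
    """Generalized Morse wavelet parameters (gamma, P^2) and voice count."""

    gamma: float = 3.0
    p2: float = 60.0  # time-bandwidth product P^2
    voices: int = 12  # voices per octave

    @property
    def beta(self) -> float:
        return self.p2 / self.gamma

    @property
    def peak_omega(self) -> float:
        """Angular frequency of the spectral peak, (beta/gamma)^(1/gamma)."""
        return (self.beta / self.gamma) ** (1.0 / self.gamma)

    def validate(self) -> None:
        if self.gamma <= 0:
            raise ValueError("gamma must be > 0")
        if self.p2 <= self.gamma:
            raise ValueError("P^2 must exceed gamma (beta > 1) for admissibility")
        if self.voices < 1 or int(self.voices) != self.voices:
            raise ValueError("voices per octave must be a positive integer")


def morse_psi(omega: np.ndarray, params: MorseParams = MorseParams()) -> np.ndarray:
    """Evaluate the Morse wavelet spectrum Psi(omega); zero for omega <= 0."""
    params.validate()
    omega = np.asarray(omega, dtype=float)
    beta, gamma = params.beta, params.gamma
    wp = params.peak_omega
    out = np.zeros_like(omega)
    pos = omega > 0
    r = omega[pos] / wp
    with np.errstate(over="ignore"):
        out[pos] = 2.0 * np.exp(beta * np.log(r) + (beta / gamma) * (1.0 - r**gamma))
    return out


@dataclass
class FilterBank:
    """Frequency-domain Morse filters for one epoch length and sample rate."""

    fs: float
    n_samples: int
    center_freqs: np.ndarray  # Hz, descending geometric grid
    filters: np.ndarray  # (n_scales, n_samples) spectra on the FFT grid
    params: MorseParams


def build_filterbank(
    fs: float,
    n_samples: int,
    params: MorseParams = MorseParams(),
    fmin: float = 0.5,
    fmax: float = 50.0,
) -> FilterBank:
    """Lay out center frequencies from ``fmax`` downward at ratio 2^(-1/V).

    The grid stops at the last frequency >= ``fmin``; each scale's filter
    is Psi evaluated at ``scale * omega`` over the length-``n_samples`` FFT
    angular frequency grid, where the scale maps the wavelet peak onto the
    center frequency.
    """
    params.validate()
    if not 0 < fmin < fmax:
        raise ValueError("need 0 < fmin < fmax")
    if fmax > fs / 2:
        raise ValueError(f"fmax {fmax:g} Hz exceeds Nyquist {fs / 2:g} Hz")
    n_scales = int(np.floor(params.voices * np.log2(fmax / fmin))) + 1
    center = fmax * 2.0 ** (-np.arange(n_scales) / params.voices)
    omega = 2.0 * np.pi * np.fft.fftfreq(n_samples, d=1.0 / fs)
    scales = params.peak_omega / (2.0 * np.pi * center)
    filters = np.stack([morse_psi(s * omega, params) for s in scales])
    return FilterBank(fs=fs, n_samples=n_samples, center_freqs=center,
                      filters=filters, params=params)


@dataclass
class Scalogram:
    """|CWT| magnitude over (scale/frequency) x time."""

    magnitude: np.ndarray  # (n_scales, n_times), non-negative
    center_freqs: np.ndarray  # Hz, descending; row 0 = highest frequency
    times: np.ndarray  # seconds


def cwt_signal(x: np.ndarray, bank: FilterBank) -> Scalogram:
    """CWT magnitude of a 1-D signal via FFT circular convolution."""
    x = np.asarray(x, dtype=float)
    if x.shape != (bank.n_samples,):
        raise ValueError(
            f"signal length {x.shape} does not match filter bank ({bank.n_samples},)"
        )
    spectrum = np.fft.fft(x)
    coeffs = np.fft.ifft(spectrum[None, :] * np.conj(bank.filters), axis=1)
    mag = np.abs(coeffs)
    times = np.arange(bank.n_samples) / bank.fs
    return Scalogram(magnitude=mag, center_freqs=bank.center_freqs.copy(), times=times)


def cwt_epoch(epoch: Epoch, bank: FilterBank) -> Scalogram:
    """CWT magnitude of one epoch (length must match the bank)."""
    return cwt_signal(epoch.samples, bank)


@dataclass
class ScalogramImage:
    """Square 8-bit grayscale rendering of a scalogram."""

    pixels: np.ndarray  # (side, side) uint8

    @property
    def side(self) -> int:
        return self.pixels.shape[0]

    def to_png_bytes(self) -> bytes:
        buf = io.BytesIO()
        Image.fromarray(self.pixels, mode="L").save(buf, format="PNG")
        return buf.getvalue()

    def save(self, path: str | Path) -> None:
        Path(path).write_bytes(self.to_png_bytes())


def _resample_bilinear(arr: np.ndarray, side: int) -> np.ndarray:
    img = Image.fromarray(arr.astype(np.float32), mode="F")
    out = img.resize((side, side), resample=Image.BILINEAR)
    return np.asarray(out, dtype=np.float64)


def render_scalogram(scal: Scalogram, side: int = 224) -> ScalogramImage:
    """Log-compress, min-max scale to [0, 255], and resample to side x side.

    Row 0 of the output corresponds to the highest frequency.  A constant
    magnitude matrix (min == max) renders as an all-zero image.
    """
    if scal.magnitude.size == 0:
        raise ValueError("empty scalogram")
    if side <= 0:
        raise ValueError("side must be > 0")
    m = np.log1p(scal.magnitude)
    # Bilinear resampling commutes with affine rescaling, so normalizing
    # after the resample yields the same image while guaranteeing the
    # rendered output spans the full 8-bit range.
    pix = _resample_bilinear(m, side)
    lo, hi = float(pix.min()), float(pix.max())
    if hi > lo:
        pix = (pix - lo) / (hi - lo) * 255.0
    else:
        pix = np.zeros_like(pix)
    pix = np.clip(np.rint(pix), 0, 255).astype(np.uint8)
    return ScalogramImage(pixels=pix)


def resize_image(img: ScalogramImage, side: int = 32) -> ScalogramImage:
    """Bilinear resize of a square grayscale image, clipped to [0, 255]."""
    if side <= 0:
        raise ValueError("side must be > 0")
    if img.pixels.shape[0] != img.pixels.shape[1]:
        raise ValueError("image must be square")
    if img.pixels.shape[0] == side:
        return ScalogramImage(pixels=img.pixels.copy())
    out = _resample_bilinear(img.pixels.astype(np.float64), side)
    return ScalogramImage(pixels=np.clip(np.rint(out), 0, 255).astype(np.uint8))


def epoch_to_image(
    epoch: Epoch,
    bank: FilterBank,
    render_side: int = 224,
    final_side: int = 32,
) -> ScalogramImage:
    """Full per-epoch path: CWT -> 224x224 render -> 32x32 resize."""
    scal = cwt_epoch(epoch, bank)
    img = render_scalogram(scal, side=render_side)
    return resize_image(img, side=final_side)


def epochs_to_array(
    epochs: Sequence[Epoch],
    bank: FilterBank,
    render_side: int = 224,
    final_side: int = 32,
) -> np.ndarray:
    """Stack rendered epoch images into a (n, side, side) uint8 array."""
    return np.stack(
        [epoch_to_image(e, bank, render_side, final_side).pixels for e in epochs]
    )
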