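"""Spectral-domain reconstruction and B-scan artifact removal.

Raw swept-source fringes sampled uniformly in wavelength are resampled to
a uniform wavenumber (k = 2*pi/lambda) grid, windowed and inverse-FFT'd to
depth-resolved complex amplitudes.  Horizontal stripe artifacts (ghost
reflections in the optics) are suppressed with the combined wavelet-FFT
destriping scheme: decompose, damp the zero-lateral-frequency Fourier
content of each horizontal-detail band with a Gaussian notch, reconstruct.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pywt

from .io import ComplexVolume, IntensityVolume

__all__ = ["SpectralFrame", "resample_to_wavenumber", "reconstruct_complex",
           "remove_stripes", "compute_intensity"]


@dataclass
class SpectralFrame:
    """Real-valued interferometric fringes for one frame.

    ``fringes_H``/``fringes_V`` are (n_samples, n_ascans); ``wavelength``
    maps sample index to wavelength in meters and must be strictly
    monotone.  ``uniform_k`` records whether the frame has been resampled
    to an evenly spaced wavenumber grid.
    """

    fringes_H: np.ndarray
    fringes_V: np.ndarray
    wavelength: np.ndarray
    uniform_k: bool = False

    def __post_init__(self) -> None:
        self.fringes_H = np.asarray(self.fringes_H, dtype=np.float64)
        self.fringes_V = np.asarray(self.fringes_V, dtype=np.float64)
        self.wavelength = np.asarray(self.wavelength, dtype=np.float64)
        if self.fringes_H.shape != self.fringes_V.shape:
            raise ValueError("fringe channels must share one shape")
        if self.wavelength.shape[0] != self.fringes_H.shape[0]:
            raise ValueError("calibration length must match the sample axis")
        d = np.diff(self.wavelength)
        if not ((d > 0).all() or (d < 0).all()):
            raise ValueError("wavelength calibration must be strictly monotone")


def resample_to_wavenumber(frame: SpectralFrame) -> SpectralFrame:
    """Linearly interpolate both channels onto a uniform k = 2*pi/lambda grid.

    The grid spans the calibrated wavenumber range with the same sample
    count, ascending in k.
    """
    k = 2.0 * np.pi / frame.wavelength
    n = k.shape[0]
    k_uniform = np.linspace(k.min(), k.max(), n)
    order = np.argsort(k)
    k_sorted = k[order]
    out_H = np.empty_like(frame.fringes_H)
    out_V = np.empty_like(frame.fringes_V)
    for src, dst in ((frame.fringes_H, out_H), (frame.fringes_V, out_V)):
        for j in range(src.shape[1]):
            dst[:, j] = np.interp(k_uniform, k_sorted, src[order, j])
    return SpectralFrame(fringes_H=out_H, fringes_V=out_V,
                         wavelength=2.0 * np.pi / k_uniform, uniform_k=True)


def reconstruct_complex(frame: SpectralFrame):
    """Inverse-FFT a uniform-k frame to complex A-scans.

    Per A-scan and channel: subtract the DC (mean over samples), apply a
    Hann window for sidelobe control, inverse FFT, and keep the
    positive-depth half (n/2 pixels).  Returns ``(AH, AV)`` arrays of
    shape (n/2, n_ascans).
    """
    k = 2.0 * np.pi / frame.wavelength
    dk = np.diff(k)
    if not frame.uniform_k and not np.allclose(dk, dk[0], rtol=1e-6, atol=0):
        raise ValueError("frame must be uniform in wavenumber; run resample_to_wavenumber first")
    n = frame.fringes_H.shape[0]
    win = np.hanning(n)[:, None]
    out = []
    for fr in (frame.fringes_H, frame.fringes_V):
        x = fr - fr.mean(axis=0, keepdims=True)
        a = np.fft.ifft(x * win, axis=0)
        out.append(a[: n // 2])
    return out[0], out[1]


def remove_stripes(image: np.ndarray, levels: int = 5, sigma: float = 2.0,
                   wavelet: str = "db4") -> np.ndarray:
    """Suppress horizontal stripes with the combined wavelet-FFT filter.

    The image is decomposed with a multi-level 2-D DWT; within each
    horizontal-detail band the Fourier transform along the lateral axis is
    damped by the Gaussian notch ``g(f) = 1 - exp(-f^2 / (2 sigma^2))``
    (``sigma`` in frequency-index cycles), which removes content constant
    along the lateral direction — i.e. stripes — while leaving other
    structure intact.  Output has the input's shape; with an orthogonal
    wavelet the damping cannot increase total energy.
    """
    image = np.asarray(image, dtype=np.float64)
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    if image.ndim != 2:
        raise ValueError("expected a 2-D B-scan image")
    if image.shape[0] < 2 ** levels:
        raise ValueError(
            f"image with {image.shape[0]} rows is too small for {levels} levels")
    coeffs = pywt.wavedec2(image, wavelet, level=levels, mode="periodization")
    new_coeffs = [coeffs[0]]
    for cH, cV, cD in coeffs[1:]:
        f = np.fft.fftfreq(cH.shape[1]) * cH.shape[1]  # frequency index
        notch = 1.0 - np.exp(-(f ** 2) / (2.0 * sigma ** 2))
        cH_f = np.fft.fft(cH, axis=1)
        cH = np.real(np.fft.ifft(cH_f * notch[None, :], axis=1))
        new_coeffs.append((cH, cV, cD))
    out = pywt.waverec2(new_coeffs, wavelet, mode="periodization")
    return out[: image.shape[0], : image.shape[1]]


def compute_intensity(vol: ComplexVolume) -> IntensityVolume:
    """Backscattered intensity ``I = |AH|^2 + |AV|^2`` per voxel."""
    return vol.intensity()
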