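"""Complex steerable pyramid, constructed in the frequency domain.

The pyramid splits an image into a high-pass residual, ``n_scales`` levels of
``n_orientations`` oriented complex band-pass responses (each level downsampled
by two), and a low-pass residual. Radial selectivity uses raised-cosine
transitions on a log-frequency axis; angular selectivity uses
``cos(theta)^(K-1)`` lobes restricted to a half-plane, which makes the band
coefficients complex (analytic) so that magnitude and phase are available for
texture statistics.

This is the standard multi-scale front end for texture-statistic models; only
the analysis direction is implemented (no synthesis).
"""

from __future__ import annotations

from dataclasses import dataclass
from math import factorial

import numpy as np

__all__ = ["SteerablePyramid", "build_pyramid"]


@dataclass
class SteerablePyramid:
    """Analysis result: residuals plus oriented complex bands per scale."""

    highpass: np.ndarray                 # real, full resolution
    bands: list[list[np.ndarray]]        # bands[scale][orientation], complex, dyadic sizes
    lowpass: np.ndarray                  # real, coarsest resolution
    lowpass_chain: list[np.ndarray]      # low-pass image at each level, fine -> coarse
    n_orientations: int

    @property
    def n_scales(self) -> int:
        return len(self.bands)


def _raised_cosine(log_rad: np.ndarray) -> np.ndarray:
    """Smooth 0->1 transition over one octave of log2 frequency, ending at 0."""
    x = np.clip(log_rad, -1.0, 0.0)
    return np.cos(np.pi / 2.0 * (-x)) ** 2  # 1 at log_rad=0, 0 at log_rad=-1


def _polar_grids(shape: tuple[int, int]) -> tuple[np.ndarray, np.ndarray]:
    h, w = shape
    fy = np.fft.fftshift(np.fft.fftfreq(h))[:, None] * 2.0  # in units of Nyquist
    fx = np.fft.fftshift(np.fft.fftfreq(w))[None, :] * 2.0
    rad = np.hypot(fy, fx)
    rad[h // 2, w // 2] = rad[h // 2, w // 2 + 1] if w > 1 else 1e-12
    angle = np.arctan2(fy, fx)
    return rad, angle


def _angular_masks(angle: np.ndarray, n_orientations: int) -> list[np.ndarray]:
    k = n_orientations
    order = k - 1
    const = (2.0 ** (2 * order)) * (factorial(order) ** 2) / (k * factorial(2 * order))
    masks = []
    for b in range(k):
        theta = np.mod(angle - np.pi * b / k + np.pi, 2.0 * np.pi) - np.pi
        lobe = 2.0 * np.sqrt(const) * (np.cos(theta) ** order) * (np.abs(theta) < np.pi / 2.0)
        masks.append(lobe)
    return masks


def build_pyramid(image: np.ndarray, n_scales: int = 3, n_orientations: int = 3) -> SteerablePyramid:
    """Decompose a 2-D real image into a complex steerable pyramid."""
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ValueError("pyramid input must be a 2-D single-channel image")
    if min(image.shape) // (2 ** n_scales) < 8:
        raise ValueError(
            f"image {image.shape} too small for {n_scales} scales")

    rad, angle = _polar_grids(image.shape)
    log_rad = np.log2(rad)

    hi_mask = np.sqrt(_raised_cosine(log_rad))
    lo_mask = np.sqrt(1.0 - hi_mask**2)

    ft = np.fft.fftshift(np.fft.fft2(image))
    highpass = np.real(np.fft.ifft2(np.fft.ifftshift(ft * hi_mask)))
    lo_ft = ft * lo_mask

    bands: list[list[np.ndarray]] = []
    lowpass_chain: list[np.ndarray] = []
    for _ in range(n_scales):
        shape = lo_ft.shape
        rad, angle = _polar_grids(shape)
        log_rad = np.log2(rad) + 1.0  # band lives one octave below the previous cutoff
        band_rad = np.sqrt(_raised_cosine(log_rad))
        ang_masks = _angular_masks(angle, n_orientations)
        level = []
        for mask in ang_masks:
            band_ft = lo_ft * band_rad * mask * ((1j) ** (n_orientations - 1))
            level.append(np.fft.ifft2(np.fft.ifftshift(band_ft)))
        bands.append(level)

        lo_next_mask = np.sqrt(1.0 - _raised_cosine(log_rad))
        lo_ft = lo_ft * lo_next_mask
        # crop the central half of the spectrum == downsample by 2
        h, w = shape
        lo_ft = lo_ft[h // 4: h // 4 + h // 2, w // 4: w // 4 + w // 2] / 4.0
        lowpass_chain.append(np.real(np.fft.ifft2(np.fft.ifftshift(lo_ft))))

    lowpass = lowpass_chain[-1]
    return SteerablePyramid(
        highpass=highpass,
        bands=bands,
        lowpass=lowpass,
        lowpass_chain=lowpass_chain,
        n_orientations=n_orientations,
    )
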