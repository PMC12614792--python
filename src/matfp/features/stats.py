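"""Compact statistical image features (the 28-dim "S" representation).

Fourteen deterministic features per frame, concatenated non-specular first:

==  =========================================================================
 1  luminance mean
 2  luminance standard deviation
 3  luminance skewness (0 for a zero-variance frame)
 4  relative spectral energy, radial band 1 (lowest frequencies)
 5  relative spectral energy, radial band 2
 6  relative spectral energy, radial band 3
 7  relative spectral energy, radial band 4 (highest frequencies)
 8  directionality strength: 1 - circular variance of gradient orientations,
    magnitude-weighted (orientations doubled so opposite gradients agree)
 9  bright-outlier fraction: share of pixels whose luminance exceeds the
    frame mean by more than 3 SD (captures sparkle speckle and highlights)
10  effective number of dominant colours: exp of the Shannon entropy of
    cluster shares after 8-cluster colour quantisation of the
    exposure-normalised pixels (2.0 for an ideal two-tone checkerboard)
11  stripe score: spectral-energy excess of the dominant orientation over its
    orthogonal orientation
12  checker score: energy shared by the dominant orientation pair and its
    orthogonal pair (a checkerboard's fundamental peaks span both)
13  mean relative chroma (chroma over lightness, i.e. saturation)
14  dominant-peak scale: log2 radial frequency of the strongest non-DC
    spectral peak (encodes the pattern period)
==  =========================================================================

Covering marginal statistics up to third order, frequency-band energy,
directionality, dominant-colour count and pattern type. All features are pure
functions of the pixel data: no randomness, and the spectral/orientation
features are invariant to translation by whole pattern periods.
"""

from __future__ import annotations

import math
import warnings

import numpy as np
from sklearn.cluster import KMeans

from ..images import MaterialImagePair

__all__ = ["S_DIM", "frame_stat_features", "stat_features", "S_FEATURE_NAMES"]

N_ORIENT_BINS = 16
N_RADIAL_BANDS = 4
N_COLOUR_CLUSTERS = 8
DOMINANT_SHARE = 0.05

S_FEATURE_NAMES = [
    "lum_mean", "lum_sd", "lum_skew",
    "band_energy_1", "band_energy_2", "band_energy_3", "band_energy_4",
    "directionality_strength", "bright_outlier_fraction",
    "n_dominant_colours", "stripe_score", "checker_score",
    "mean_chroma", "peak_log2_frequency",
]
S_DIM = 2 * len(S_FEATURE_NAMES)

REC709 = np.array([0.2126, 0.7152, 0.0722])


def _luminance(frame: np.ndarray) -> np.ndarray:
    return frame @ REC709


def _marginals(lum: np.ndarray) -> tuple[float, float, float]:
    mean = float(lum.mean())
    sd = float(lum.std())
    if sd == 0.0:
        return mean, 0.0, 0.0
    skew = float(((lum - mean) ** 3).mean() / sd**3)
    return mean, sd, skew


def _power_spectrum(lum: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Centred power spectrum with DC removed, plus radial frequency and angle grids."""
    f = np.fft.fftshift(np.fft.fft2(lum - lum.mean()))
    power = np.abs(f) ** 2
    h, w = lum.shape
    fy = np.fft.fftshift(np.fft.fftfreq(h))[:, None]
    fx = np.fft.fftshift(np.fft.fftfreq(w))[None, :]
    radius = np.hypot(fy, fx)
    angle = np.mod(np.arctan2(fy, fx), np.pi)  # orientation of the frequency component
    power[radius == 0] = 0.0
    return power, radius, angle


def _band_energies(power: np.ndarray, radius: np.ndarray) -> np.ndarray:
    total = power.sum()
    if total == 0.0:
        return np.zeros(N_RADIAL_BANDS)
    # log-spaced radial band edges between the lowest resolvable frequency and Nyquist
    r_min = 1.0 / max(power.shape)
    edges = np.geomspace(r_min, 0.5, N_RADIAL_BANDS + 1)
    edges[0] = 0.0
    out = np.empty(N_RADIAL_BANDS)
    for i in range(N_RADIAL_BANDS):
        mask = (radius > edges[i]) & (radius <= edges[i + 1])
        out[i] = power[mask].sum() / total
    return out


def _orientation_energy(power: np.ndarray, angle: np.ndarray) -> np.ndarray:
    """Spectral energy per orientation bin over [0, pi)."""
    bins = np.minimum((angle / np.pi * N_ORIENT_BINS).astype(int), N_ORIENT_BINS - 1)
    return np.bincount(bins.ravel(), weights=power.ravel(), minlength=N_ORIENT_BINS)


def _pattern_scores(power: np.ndarray, angle: np.ndarray) -> tuple[float, float]:
    e = _orientation_energy(power, angle)
    total = e.sum()
    if total == 0.0:
        return 0.0, 0.0
    d = int(np.argmax(e))
    orth = (d + N_ORIENT_BINS // 2) % N_ORIENT_BINS
    stripe = float(max(0.0, (e[d] - e[orth]) / total))
    checker = float(2.0 * min(e[d], e[orth]) / total)
    return stripe, checker


def _directionality(lum: np.ndarray) -> float:
    gy, gx = np.gradient(lum)
    mag = np.hypot(gx, gy)
    w = mag.sum()
    if w == 0.0:
        return 0.0
    theta = 2.0 * np.arctan2(gy, gx)  # double angles: opposite gradients, same orientation
    return float(np.hypot((mag * np.cos(theta)).sum(), (mag * np.sin(theta)).sum()) / w)


def _bright_outlier_fraction(lum: np.ndarray) -> float:
    sd = lum.std()
    if sd == 0.0:
        return 0.0
    return float((lum > lum.mean() + 3.0 * sd).mean())


def _dominant_colours(frame: np.ndarray, max_pixels: int = 4096) -> float:
    """Effective number of dominant colours: exp(entropy) of colour-cluster shares.

    Pixels are normalised by mean luminance first so the count reflects the
    colour composition, not the exposure; the continuous effective count
    equals the plain count for equally-sized colour regions (e.g. 2.0 for an
    ideal two-tone checkerboard) and degrades gracefully for uneven regions.
    """
    pixels = frame.reshape(-1, 3)
    if pixels.shape[0] > max_pixels:
        step = pixels.shape[0] // max_pixels
        pixels = pixels[::step][:max_pixels]
    # normalise out global brightness so colour counts do not depend on exposure
    mean_lum = pixels @ REC709
    scale = mean_lum.mean()
    if scale > 0:
        pixels = np.clip(pixels / (2.0 * scale), 0.0, 1.0)
    # quantise to a coarse lattice first so the number of clusters is well defined
    lattice = np.round(pixels * 24.0) / 24.0
    k = min(N_COLOUR_CLUSTERS, len(np.unique(lattice, axis=0)))
    if k == 1:
        return 1.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        km = KMeans(n_clusters=k, n_init=3, random_state=0)
        labels = km.fit_predict(pixels)
    shares = np.bincount(labels, minlength=k) / len(labels)
    shares = shares[shares > 0]
    return float(np.exp(-(shares * np.log(shares)).sum()))


def _mean_saturation(frame: np.ndarray) -> float:
    mx = frame.max(axis=2)
    mn = frame.min(axis=2)
    # chroma relative to lightness: invariant to exposure, tracks perceived saturation
    with np.errstate(invalid="ignore", divide="ignore"):
        rel = np.where(mx > 0, (mx - mn) / mx, 0.0)
    return float(rel.mean())


def _peak_log_frequency(power: np.ndarray, radius: np.ndarray) -> float:
    """log2 radial frequency of the strongest non-DC spectral component."""
    if power.sum() == 0.0:
        return 0.0
    idx = np.unravel_index(np.argmax(power), power.shape)
    return float(math.log2(max(radius[idx], 1e-3)))


def frame_stat_features(frame: np.ndarray) -> np.ndarray:
    """The 14 statistical features of one frame."""
    lum = _luminance(frame)
    mean, sd, skew = _marginals(lum)
    power, radius, angle = _power_spectrum(lum)
    bands = _band_energies(power, radius)
    stripe, checker = _pattern_scores(power, angle)
    strength = _directionality(lum)
    outliers = _bright_outlier_fraction(lum)
    n_colours = _dominant_colours(frame)
    mean_chroma = _mean_saturation(frame)
    peak = _peak_log_frequency(power, radius)
    out = np.array([mean, sd, skew, *bands, strength, outliers,
                    n_colours, stripe, checker, mean_chroma, peak])
    assert np.all(np.isfinite(out))
    return out


def stat_features(pair: MaterialImagePair) -> np.ndarray:
    """28-dim S feature vector of a frame pair (non-specular features first)."""
    return np.concatenate([
        frame_stat_features(pair.frame_nonspec),
        frame_stat_features(pair.frame_spec),
    ])
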