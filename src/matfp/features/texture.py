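"""Texture-synthesis image statistics (the 1341-dim "T" representation).

Per colour channel, a complex steerable pyramid (3 scales, 3 orientations) is
built for each of the two frames and the classical texture-statistic groups
are computed:

* marginal pixel statistics (mean, variance, skewness, kurtosis, min, max);
* standard deviation, skewness and kurtosis of the low-pass image at every
  pyramid level;
* central 7 x 7 normalised autocorrelation of each low-pass image;
* central 7 x 7 normalised autocorrelation of each oriented band's magnitude;
* mean magnitudes of every band plus the high- and low-pass residuals;
* within-scale cross-orientation correlations of band magnitudes;
* cross-scale (parent) correlations of band magnitudes;
* cross-scale phase statistics: correlation of a band's real part with the
  real and imaginary parts of its phase-doubled, upsampled parent;
* within-scale cross-orientation correlations of band real parts;
* variance, skewness and kurtosis of the high-pass residual.

Statistics of the two frames are averaged per channel. The raw storage layout
holds 786 slots per channel, of which 339 are structurally zero (the redundant
point-symmetric half of each autocorrelation and the empty parent slots of the
coarsest scale). A :class:`ZeroFeatureMask` fitted on a corpus removes every
slot that is zero across all corpus members, leaving the 447 informative
statistics per channel and a 1341-dimensional vector over the three channels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..images import MaterialImagePair
from .pyramid import build_pyramid

__all__ = [
    "T_DIM", "T_RAW_DIM_PER_CHANNEL", "T_MASKED_DIM_PER_CHANNEL",
    "raw_texture_stats", "raw_texture_stats_pair", "ZeroFeatureMask",
    "texture_features", "fit_zero_mask",
]

N_SCALES = 3
N_ORIENTATIONS = 3
NEIGHBOURHOOD = 7

T_MASKED_DIM_PER_CHANNEL = 447
T_DIM = 3 * T_MASKED_DIM_PER_CHANNEL


def _marginals(x: np.ndarray) -> np.ndarray:
    mean = x.mean()
    var = x.var()
    if var == 0.0:
        return np.array([mean, 0.0, 0.0, 0.0, x.min(), x.max()])
    z = (x - mean) / np.sqrt(var)
    return np.array([mean, var, (z**3).mean(), (z**4).mean(), x.min(), x.max()])


def _sd_skew_kurt(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    if sd == 0.0:
        return np.array([0.0, 0.0, 0.0])
    z = (x - x.mean()) / sd
    return np.array([sd, (z**3).mean(), (z**4).mean()])


def _autocorr_halfplane(x: np.ndarray, width: int = NEIGHBOURHOOD) -> np.ndarray:
    """Central normalised autocorrelation, redundant symmetric half zeroed.

    Returns a ``width x width`` matrix of correlations at offsets
    ``(-la..la, -la..la)`` with ``la = (width - 1) // 2``; entries with
    ``di < 0`` or (``di == 0`` and ``dj < 0``) are structural zeros because the
    autocorrelation is point-symmetric.
    """
    la = (width - 1) // 2
    xc = x - x.mean()
    ft = np.fft.fft2(xc)
    acf = np.real(np.fft.ifft2(ft * np.conj(ft))) / x.size
    var = acf[0, 0]
    out = np.zeros((width, width))
    if var == 0.0:
        return out
    for di in range(0, la + 1):
        for dj in range(-la, la + 1):
            if di == 0 and dj < 0:
                continue
            out[di + la, dj + la] = acf[di % acf.shape[0], dj % acf.shape[1]] / var
    return out


def _corrcoef(a: np.ndarray, b: np.ndarray) -> float:
    ac = a - a.mean()
    bc = b - b.mean()
    denom = np.sqrt((ac * ac).sum() * (bc * bc).sum())
    if denom == 0.0:
        return 0.0
    return float((ac * bc).sum() / denom)


def _upsample2(x: np.ndarray) -> np.ndarray:
    return np.repeat(np.repeat(x, 2, axis=0), 2, axis=1)


def raw_texture_stats(channel: np.ndarray) -> np.ndarray:
    """Raw texture-statistic vector (786 slots) of one single-channel image."""
    pyr = build_pyramid(channel, N_SCALES, N_ORIENTATIONS)
    parts: list[np.ndarray] = []

    # 1. pixel marginals (6)
    parts.append(_marginals(channel))

    # 2-3. low-pass chain marginals (12) and autocorrelations (4 x 49)
    lp_images = [channel, *pyr.lowpass_chain]  # full-res image plus N low-pass levels
    acr = []
    lp_stats = []
    for lp in lp_images[1:]:
        lp_stats.append(_sd_skew_kurt(lp))
    # the finest "low-pass" level is the input minus its high-pass residual
    l0 = channel - pyr.highpass
    lp_stats.insert(0, _sd_skew_kurt(l0))
    parts.append(np.concatenate(lp_stats))
    for lp in [l0, *pyr.lowpass_chain]:
        acr.append(_autocorr_halfplane(lp).ravel())
    parts.append(np.concatenate(acr))

    # magnitudes, centred
    mags = [[np.abs(b) for b in level] for level in pyr.bands]

    # 4. magnitude autocorrelations (9 x 49)
    acm = [
        _autocorr_halfplane(m).ravel() for level in mags for m in level
    ]
    parts.append(np.concatenate(acm))

    # 5. magnitude means (9 + 2)
    mag_means = [m.mean() for level in mags for m in level]
    mag_means.append(np.abs(pyr.highpass).mean())
    mag_means.append(np.abs(pyr.lowpass).mean())
    parts.append(np.array(mag_means))

    # 6. within-scale cross-orientation magnitude correlations (3 x K x K)
    ori_mag = []
    for level in mags:
        for a in level:
            for b in level:
                ori_mag.append(_corrcoef(a, b))
    parts.append(np.array(ori_mag))

    # 7. parent magnitude correlations (3 x K x K, coarsest slice structural zeros)
    par_mag = []
    for s in range(N_SCALES):
        if s + 1 < N_SCALES:
            parents = [_upsample2(m) for m in mags[s + 1]]
            for child in mags[s]:
                for par in parents:
                    par_mag.append(_corrcoef(child, par))
        else:
            par_mag.extend([0.0] * (N_ORIENTATIONS * N_ORIENTATIONS))
    parts.append(np.array(par_mag))

    # 8. cross-scale phase statistics (3 x K x 2K, coarsest slice structural zeros)
    phase = []
    for s in range(N_SCALES):
        if s + 1 < N_SCALES:
            doubled = []
            for p in pyr.bands[s + 1]:
                up = _upsample2(p)
                doubled.append(np.abs(up) * np.exp(2j * np.angle(up)))
            for child in pyr.bands[s]:
                cre = np.real(child)
                for par in doubled:
                    phase.append(_corrcoef(cre, np.real(par)))
                    phase.append(_corrcoef(cre, np.imag(par)))
        else:
            phase.extend([0.0] * (N_ORIENTATIONS * 2 * N_ORIENTATIONS))
    parts.append(np.array(phase))

    # 9. within-scale cross-orientation real-part correlations (3 x K(K-1)/2)
    ori_real = []
    for level in pyr.bands:
        for i in range(N_ORIENTATIONS):
            for j in range(i + 1, N_ORIENTATIONS):
                ori_real.append(_corrcoef(np.real(level[i]), np.real(level[j])))
    parts.append(np.array(ori_real))

    # 10. high-pass residual marginals (3): variance, skewness, kurtosis
    hp = _sd_skew_kurt(pyr.highpass)
    hp[0] = hp[0] ** 2
    parts.append(hp)

    out = np.concatenate(parts)
    assert np.all(np.isfinite(out))
    return out


T_RAW_DIM_PER_CHANNEL = (
    6                                        # pixel marginals
    + 3 * (N_SCALES + 1)                     # low-pass chain sd/skew/kurt
    + (N_SCALES + 1) * NEIGHBOURHOOD**2      # low-pass autocorrelations
    + N_SCALES * N_ORIENTATIONS * NEIGHBOURHOOD**2  # magnitude autocorrelations
    + N_SCALES * N_ORIENTATIONS + 2          # magnitude means
    + N_SCALES * N_ORIENTATIONS**2           # cross-orientation magnitude corr
    + N_SCALES * N_ORIENTATIONS**2           # parent magnitude corr (with zeros)
    + N_SCALES * 2 * N_ORIENTATIONS**2       # phase corr (with zeros)
    + N_SCALES * (N_ORIENTATIONS * (N_ORIENTATIONS - 1)) // 2  # real corr
    + 3                                      # high-pass marginals
)


def raw_texture_stats_pair(pair: MaterialImagePair) -> np.ndarray:
    """Per-channel raw statistics, averaged over the two frames; shape (3, 786)."""
    rows = []
    for c in range(3):
        per_frame = [raw_texture_stats(frame[:, :, c]) for frame in pair.frames]
        rows.append(0.5 * (per_frame[0] + per_frame[1]))
    return np.stack(rows)


@dataclass
class ZeroFeatureMask:
    """Per-channel boolean mask of statistics retained after zero removal.

    A slot is removed when it is exactly zero for every corpus member; on the
    layout above that removes precisely the structural zeros, keeping 447
    statistics per channel.
    """

    keep: np.ndarray  # (3, T_RAW_DIM_PER_CHANNEL) bool

    def __post_init__(self) -> None:
        self.keep = np.asarray(self.keep, dtype=bool)
        if self.keep.shape != (3, T_RAW_DIM_PER_CHANNEL):
            raise ValueError(
                f"mask shape {self.keep.shape} does not match the raw layout "
                f"(3, {T_RAW_DIM_PER_CHANNEL})")

    @property
    def masked_dim(self) -> int:
        return int(self.keep.sum())

    def apply(self, raw: np.ndarray) -> np.ndarray:
        raw = np.asarray(raw)
        if raw.shape != self.keep.shape:
            raise ValueError(
                f"raw statistics shape {raw.shape} does not match mask {self.keep.shape}")
        return np.concatenate([raw[c][self.keep[c]] for c in range(3)])

    def save(self, path) -> None:
        np.savetxt(path, self.keep.astype(int), fmt="%d")

    @classmethod
    def load(cls, path) -> "ZeroFeatureMask":
        return cls(np.loadtxt(path).astype(bool))


def fit_zero_mask(raw_stats: list[np.ndarray] | np.ndarray) -> ZeroFeatureMask:
    """Fit the zero-feature mask over a corpus of raw per-channel statistics."""
    arr = np.stack(list(raw_stats))  # (n, 3, raw_dim)
    if arr.ndim != 3:
        raise ValueError("expected a collection of (3, raw_dim) statistic arrays")
    keep = ~np.all(arr == 0.0, axis=0)
    return ZeroFeatureMask(keep)


def texture_features(pair: MaterialImagePair, mask: ZeroFeatureMask) -> np.ndarray:
    """Masked texture-statistic vector of a frame pair (1341 values for the
    canonical corpus mask)."""
    return mask.apply(raw_texture_stats_pair(pair))
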