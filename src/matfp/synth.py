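"""Procedural material stimuli with known ground-truth fingerprints, and
simulated raters.

The generator emulates the appearance axes behind the 16 rating attributes
with fully controllable parameters: an oriented sine grating (stripes), a
two-tone checkerboard, a multi-colour palette field, 1/f^beta surface noise,
plus a specular layer (smooth gloss highlight and bright sparkle speckle)
added only to the near-specular frame. Every material therefore has a
deterministic ground-truth fingerprint on the unit scale, which makes
end-to-end recovery experiments possible without any downloaded data.

Attributes without a physical generator axis (hardness, warmth, value,
naturalness, thickness, pattern complexity) are given explicit documented
surrogates of the same parameters (e.g. warmth from the hue of the base
colour, hardness inversely related to surface-noise roughness). These maps
define *this generator's* ground truth; no claim of perceptual validity for
real materials is attached to them.

Rater simulation mirrors an online slider experiment: each honest participant
applies an individual gain and bias to the true attribute value, adds Gaussian
response noise and clamps to the 0-100 slider; adversarial participants
respond to the negated truth and are therefore flagged by the
negative-correlation exclusion rule of the rating pipeline.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .images import CANONICAL_PX, MaterialImagePair
from .schema import N_ATTRIBUTES, Fingerprint, FingerprintSet

__all__ = [
    "SynthParams", "RaterConfig", "generate_pair", "truth_fingerprint",
    "simulate_ratings", "make_corpus", "CONTROLLED_ATTRIBUTES",
    "PSEUDO_CATEGORIES",
]

#: attribute ids with a direct generator axis (used by recovery experiments)
CONTROLLED_ATTRIBUTES = {
    1:  "colour vibrancy",
    2:  "surface roughness",
    4:  "striped pattern",
    5:  "chequered pattern",
    6:  "brightness",
    7:  "shininess",
    8:  "sparkle",
    10: "movement effect",
    11: "pattern scale",
    14: "multicoloured",
}

PSEUDO_CATEGORIES = (
    "striped_fabric", "wood_grain", "glossy_coating", "noisy_matte",
)


@dataclass(frozen=True)
class SynthParams:
    """Parameters of one procedural material."""

    base_rgb: tuple[float, float, float] = (0.5, 0.45, 0.4)
    n_palette: int = 1
    stripe_amp: float = 0.0
    checker_amp: float = 0.0
    pattern_period_px: int = 32
    orientation_deg: float = 0.0
    noise_beta: float = 1.0          # 1/f^beta spectral slope of the noise field
    noise_amp: float = 0.0
    gloss: float = 0.0
    sparkle_density: float = 0.0
    brightness: float = 0.7
    seed: int = 0

    def __post_init__(self) -> None:
        if self.stripe_amp + self.checker_amp + self.noise_amp > 1.0 + 1e-9:
            raise ValueError("stripe_amp + checker_amp + noise_amp must be <= 1")
        if self.pattern_period_px < 4:
            raise ValueError("pattern period must be >= 4 px")
        if self.n_palette < 1:
            raise ValueError("n_palette must be >= 1")
        for name in ("stripe_amp", "checker_amp", "noise_amp", "gloss",
                     "sparkle_density", "brightness"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")


@dataclass(frozen=True)
class RaterConfig:
    """Simulated rating-study configuration."""

    n_participants: int = 10
    response_noise_sd: float = 0.2          # on the truth scale [-1, 1]
    participant_gain_range: tuple[float, float] = (0.6, 1.0)
    participant_bias_range: tuple[float, float] = (-10.0, 10.0)  # slider units
    n_adversarial: int = 0
    slider_range: tuple[float, float] = (0.0, 100.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_participants < 1:
            raise ValueError("need at least one participant")
        if self.n_adversarial > self.n_participants:
            raise ValueError("more adversaries than participants")


# ---------------------------------------------------------------------------
# image synthesis
# ---------------------------------------------------------------------------

def _palette(params: SynthParams) -> np.ndarray:
    """n_palette colours around the base colour; index 0 is the base itself.

    Drawn from a dedicated stream of the material seed so the rendered palette
    and the ground-truth fingerprint always agree.
    """
    base = np.array(params.base_rgb)
    if params.n_palette == 1:
        return base[None, :]
    rng = np.random.default_rng([params.seed, 7])
    jitter = rng.uniform(-0.35, 0.35, size=(params.n_palette - 1, 3))
    extra = np.clip(base[None, :] + jitter, 0.0, 1.0)
    return np.vstack([base[None, :], extra])


def _colour_field(params: SynthParams, size: int, rng: np.random.Generator,
                  palette: np.ndarray) -> np.ndarray:
    if params.n_palette == 1:
        return np.broadcast_to(palette[0], (size, size, 3)).copy()
    # smooth random field quantised into n_palette regions
    field_ = _noise_field(size, beta=2.0, rng=rng)
    edges = np.quantile(field_, np.linspace(0, 1, params.n_palette + 1)[1:-1])
    labels = np.searchsorted(edges, field_)
    return palette[labels]


def _noise_field(size: int, beta: float, rng: np.random.Generator) -> np.ndarray:
    """Zero-mean, unit-SD field with a 1/f^beta amplitude spectrum."""
    white = rng.standard_normal((size, size))
    f = np.fft.fft2(white)
    fy = np.fft.fftfreq(size)[:, None]
    fx = np.fft.fftfreq(size)[None, :]
    radius = np.hypot(fy, fx)
    radius[0, 0] = 1.0
    spectrum = f / radius ** (beta / 2.0)
    spectrum[0, 0] = 0.0
    field_ = np.real(np.fft.ifft2(spectrum))
    sd = field_.std()
    return field_ / sd if sd > 0 else field_


def _square_wave(phase: np.ndarray) -> np.ndarray:
    return np.where(np.sin(phase) >= 0.0, 1.0, -1.0)


def generate_pair(params: SynthParams, size_px: int = CANONICAL_PX) -> MaterialImagePair:
    """Render the non-specular and near-specular frames of one material."""
    rng = np.random.default_rng(params.seed)
    yy, xx = np.mgrid[0:size_px, 0:size_px].astype(float)
    theta = math.radians(params.orientation_deg)
    u = xx * math.cos(theta) + yy * math.sin(theta)
    v = -xx * math.sin(theta) + yy * math.cos(theta)
    omega = 2.0 * math.pi / params.pattern_period_px

    pattern = np.zeros((size_px, size_px))
    if params.stripe_amp > 0:
        pattern += params.stripe_amp * np.sin(omega * u)
    if params.checker_amp > 0:
        pattern += params.checker_amp * _square_wave(omega * u) * _square_wave(omega * v)
    if params.noise_amp > 0:
        pattern += params.noise_amp * np.clip(
            _noise_field(size_px, params.noise_beta, rng), -2.5, 2.5) / 2.5

    palette = _palette(params)
    colour = _colour_field(params, size_px, rng, palette)
    nonspec = np.clip(params.brightness * colour * (1.0 + pattern[:, :, None]), 0.0, 1.0)

    spec = nonspec
    if params.gloss > 0 or params.sparkle_density > 0:
        spec = nonspec.copy()
        if params.gloss > 0:
            cy, cx = size_px * 0.5, size_px * 0.5
            sigma = size_px * 0.35
            highlight = np.exp(-((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * sigma**2))
            spec = spec + params.gloss * 0.8 * highlight[:, :, None]
        if params.sparkle_density > 0:
            speckle = rng.random((size_px, size_px)) < params.sparkle_density * 0.01
            spec = spec + speckle[:, :, None].astype(float)
        spec = np.clip(spec, 0.0, 1.0)

    return MaterialImagePair(nonspec, spec, material_id=f"synth{params.seed:05d}")


# ---------------------------------------------------------------------------
# ground-truth fingerprints
# ---------------------------------------------------------------------------

def _unit(x: float) -> float:
    """Affine map [0, 1] -> [-1, 1], clamped."""
    return float(np.clip(2.0 * x - 1.0, -1.0, 1.0))


def _unit_compressive(x: float) -> float:
    """Stevens-type compressive magnitude map: sqrt, then [0, 1] -> [-1, 1].

    Perceived magnitudes of physical amplitudes follow compressive power laws;
    the square root keeps low amplitudes discriminable on the rating scale
    while preserving monotonicity.
    """
    return _unit(math.sqrt(max(0.0, min(1.0, x))))


def _palette_chroma(params: SynthParams) -> float:
    """Mean relative chroma (saturation) of the palette colours."""
    pal = _palette(params)
    mx = pal.max(axis=1)
    rel = np.where(mx > 0, (mx - pal.min(axis=1)) / np.maximum(mx, 1e-12), 0.0)
    return float(rel.mean())


def truth_fingerprint(params: SynthParams) -> Fingerprint:
    """Deterministic ground-truth fingerprint of one parameter draw (unit scale)."""
    rough = min(1.0, params.noise_amp * params.noise_beta / 2.0)
    chroma = _palette_chroma(params)
    hue_warmth = _hue_warmth(params.base_rgb)
    complexity = min(1.0, 0.7 * (params.stripe_amp + params.checker_amp + params.noise_amp)
                     + 0.3 * (params.n_palette - 1) / 7.0)
    values = np.empty(N_ATTRIBUTES)
    values[0] = _unit(chroma)                                     # 1 colour vibrancy
    values[1] = _unit_compressive(rough)                          # 2 surface roughness
    values[2] = _unit(complexity)                                 # 3 pattern complexity
    values[3] = _unit_compressive(params.stripe_amp)              # 4 striped pattern
    values[4] = _unit_compressive(params.checker_amp)             # 5 chequered pattern
    values[5] = _unit(params.brightness)                          # 6 brightness
    values[6] = _unit_compressive(params.gloss)                   # 7 shininess
    values[7] = _unit_compressive(params.sparkle_density)         # 8 sparkle
    values[8] = _unit(1.0 - rough)                                # 9 hardness (surrogate)
    values[9] = _unit_compressive(min(1.0, params.gloss + params.sparkle_density))  # 10 movement
    values[10] = _unit((math.log2(params.pattern_period_px) - 2.0) / 5.0)  # 11 pattern scale
    values[11] = _unit(params.noise_amp)                          # 12 naturalness (surrogate)
    values[12] = _unit(params.noise_beta / 2.0)                   # 13 thickness (surrogate)
    values[13] = _unit((params.n_palette - 1) / 7.0)              # 14 multicoloured
    values[14] = _unit(0.5 * params.gloss + 0.5 * (1.0 - params.noise_amp))  # 15 value (surrogate)
    values[15] = _unit(hue_warmth)                                # 16 warmth (surrogate)
    return Fingerprint(f"synth{params.seed:05d}", values, scale="unit")


def _hue_warmth(rgb: tuple[float, float, float]) -> float:
    r, g, b = rgb
    chroma = max(rgb) - min(rgb)
    if chroma == 0:
        return 0.5
    hue = math.atan2(math.sqrt(3.0) * (g - b), 2.0 * r - g - b)  # 0 = red
    return 0.5 + 0.5 * math.cos(hue - math.radians(30.0))        # warm peak at orange


# ---------------------------------------------------------------------------
# rater simulation
# ---------------------------------------------------------------------------

def simulate_ratings(truths: FingerprintSet, config: RaterConfig) -> "pd.DataFrame":
    """Long-form slider responses from simulated participants.

    Honest participant ``p`` responds with
    ``clamp(gain_p * 25 * (truth + noise) + 50 + bias_p)`` in slider units;
    adversarial participants respond to ``-truth``.
    """
    import pandas as pd

    rng = np.random.default_rng(config.seed)
    lo, hi = config.slider_range
    ids = truths.ids
    truth_mat = truths.matrix(ids)
    rows = []
    for p in range(config.n_participants):
        adversarial = p < config.n_adversarial
        gain = rng.uniform(*config.participant_gain_range)
        bias = rng.uniform(*config.participant_bias_range)
        pid = f"adv{p:02d}" if adversarial else f"p{p:02d}"
        sign = -1.0 if adversarial else 1.0
        noise = rng.normal(0.0, config.response_noise_sd, size=truth_mat.shape)
        resp = np.clip(gain * 25.0 * (sign * truth_mat + noise) + 50.0 + bias, lo, hi)
        for i, mid in enumerate(ids):
            for a in range(N_ATTRIBUTES):
                rows.append((pid, mid, a + 1, resp[i, a]))
    return pd.DataFrame(rows, columns=["participant_id", "material_id",
                                       "attribute_id", "response"])


# ---------------------------------------------------------------------------
# corpus generation
# ---------------------------------------------------------------------------

def _draw_params(category: str, seed: int, rng: np.random.Generator) -> SynthParams:
    base = tuple(rng.uniform(0.15, 0.9, size=3))
    brightness = float(rng.uniform(0.1, 0.97))
    period = int(2 ** rng.uniform(2.2, 7.0))
    orientation = float(rng.uniform(0.0, 180.0))
    if category == "striped_fabric":
        striped = rng.random() < 0.5
        amp = float(rng.uniform(0.45, 0.9))
        stripe, checker = (amp, float(rng.uniform(0.0, 0.08))) if striped \
            else (float(rng.uniform(0.0, 0.08)), amp)
        noise = float(rng.uniform(0.0, max(0.0, min(0.95 - stripe - checker, 0.2))))
        return SynthParams(base, int(rng.integers(1, 9)), stripe, checker, period,
                           orientation, float(rng.uniform(0.5, 1.5)), noise,
                           float(rng.uniform(0.0, 0.15)), float(rng.uniform(0.0, 0.1)),
                           brightness, seed)
    if category == "wood_grain":
        warm = (float(rng.uniform(0.45, 0.8)), float(rng.uniform(0.25, 0.55)),
                float(rng.uniform(0.05, 0.3)))
        stripe = float(rng.uniform(0.2, 0.55))
        noise = float(rng.uniform(0.1, min(0.9 - stripe, 0.45)))
        return SynthParams(warm, int(rng.integers(1, 4)), stripe, float(rng.uniform(0.0, 0.05)),
                           int(2 ** rng.uniform(4.0, 7.0)), orientation,
                           float(rng.uniform(1.0, 2.0)), noise,
                           float(rng.uniform(0.0, 0.35)), float(rng.uniform(0.0, 0.15)),
                           brightness, seed)
    if category == "glossy_coating":
        return SynthParams(base, int(rng.integers(1, 3)), float(rng.uniform(0.0, 0.12)),
                           float(rng.uniform(0.0, 0.12)), period, orientation,
                           float(rng.uniform(0.0, 1.0)), float(rng.uniform(0.0, 0.2)),
                           float(rng.uniform(0.45, 1.0)), float(rng.uniform(0.0, 0.95)),
                           brightness, seed)
    # noisy_matte
    noise = float(rng.uniform(0.4, 0.9))
    return SynthParams(base, int(rng.integers(1, 6)), float(rng.uniform(0.0, 0.05)),
                       float(rng.uniform(0.0, 0.05)), period, orientation,
                       float(rng.uniform(0.2, 2.0)), noise,
                       float(rng.uniform(0.0, 0.1)), float(rng.uniform(0.0, 0.2)),
                       brightness, seed)


def make_corpus(
    n: int,
    seed: int = 0,
    size_px: int = CANONICAL_PX,
    render: bool = True,
) -> tuple[list[MaterialImagePair | None], FingerprintSet, dict[str, str]]:
    """Draw ``n`` materials stratified over the four pseudo-categories.

    Returns aligned (pairs, ground-truth fingerprints, categories). With
    ``render=False`` the image pairs are ``None`` placeholders, which is
    sufficient for rating-simulation experiments and much faster.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    pairs: list[MaterialImagePair | None] = []
    truths = []
    categories: dict[str, str] = {}
    for i in range(n):
        cat = PSEUDO_CATEGORIES[i % len(PSEUDO_CATEGORIES)]
        params = _draw_params(cat, seed=seed * 1_000_0 + i, rng=rng)
        truth = truth_fingerprint(params)
        pair = generate_pair(params, size_px=size_px) if render else None
        if pair is not None:
            pair.material_id = truth.material_id
        pairs.append(pair)
        truths.append(truth)
        categories[truth.material_id] = cat
    return pairs, FingerprintSet(truths, categories), categories
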