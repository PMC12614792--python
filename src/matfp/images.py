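"""Material image pairs: one non-specular and one near-specular frame.

A material sample is depicted by two frames of a rotating-light video: one
where the reflected light is directed away from the camera (diffuse appearance)
and one close to the mirror configuration (specular appearance, offset a few
degrees to avoid sensor saturation). Both frames show the same square physical
sample area, canonically 26 x 26 mm resampled to 512 x 512 px.
"""

from __future__ import annotations

from dataclasses import dataclass

import imageio.v3 as iio
import numpy as np

__all__ = ["MaterialImagePair", "load_pair", "save_pair", "CANONICAL_SAMPLE_MM", "CANONICAL_PX"]

CANONICAL_SAMPLE_MM = 26.0
CANONICAL_PX = 512


@dataclass
class MaterialImagePair:
    """Non-specular + near-specular frames with physical-scale metadata."""

    frame_nonspec: np.ndarray  # H x W x 3 sRGB in [0, 1]
    frame_spec: np.ndarray
    sample_size_mm: float = CANONICAL_SAMPLE_MM
    material_id: str = ""

    def __post_init__(self) -> None:
        self.frame_nonspec = _as_float_rgb(self.frame_nonspec)
        self.frame_spec = _as_float_rgb(self.frame_spec)
        if self.frame_nonspec.shape != self.frame_spec.shape:
            raise ValueError("the two frames must have identical shapes")
        if self.sample_size_mm <= 0:
            raise ValueError("sample_size_mm must be positive")

    @property
    def frames(self) -> tuple[np.ndarray, np.ndarray]:
        return self.frame_nonspec, self.frame_spec


def _as_float_rgb(img: np.ndarray) -> np.ndarray:
    img = np.asarray(img)
    if img.dtype == np.uint8:
        img = img.astype(np.float64) / 255.0
    elif img.dtype == np.uint16:
        img = img.astype(np.float64) / 65535.0
    else:
        img = img.astype(np.float64)
    if img.ndim == 2:
        img = np.repeat(img[:, :, None], 3, axis=2)
    if img.ndim != 3 or img.shape[2] < 3:
        raise ValueError(f"expected an H x W x 3 image, got shape {img.shape}")
    img = img[:, :, :3]
    if img.min() < -1e-6 or img.max() > 1 + 1e-6:
        raise ValueError("image values must lie in [0, 1]")
    return np.clip(img, 0.0, 1.0)


def load_pair(path_nonspec, path_spec, sample_size_mm: float = CANONICAL_SAMPLE_MM,
              material_id: str = "") -> MaterialImagePair:
    """Read a frame pair from two raster files (PNG/JPEG/TIFF)."""
    return MaterialImagePair(
        iio.imread(path_nonspec), iio.imread(path_spec),
        sample_size_mm=sample_size_mm, material_id=material_id)


def save_pair(pair: MaterialImagePair, path_nonspec, path_spec) -> None:
    for frame, path in ((pair.frame_nonspec, path_nonspec), (pair.frame_spec, path_spec)):
        iio.imwrite(path, (np.clip(frame, 0, 1) * 255).round().astype(np.uint8))
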