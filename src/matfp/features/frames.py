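"""Frame selection from video sequences and preprocessing for embedding backends."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.transform import resize

from ..images import MaterialImagePair

__all__ = ["FrameSelection", "select_frames", "preprocess_for_embedding", "center_crop"]

MM_PER_INCH = 25.4
TARGET_DPI = 250.0
CROP_PX = 224


@dataclass(frozen=True)
class FrameSelection:
    """1-based indices of the non-specular and near-specular frames of a sequence."""

    index_nonspec: int
    index_spec: int
    offset_deg: float

    def __post_init__(self) -> None:
        if not self.index_spec > self.index_nonspec:
            raise ValueError("the near-specular frame must come after the non-specular one")


def select_frames(n_frames: int, span_deg: float = 90.0, offset_deg: float = 6.0) -> FrameSelection:
    """Pick the two frames used for feature computation from an n-frame sweep.

    The camera sweeps ``span_deg`` degrees over ``n_frames`` frames ending at
    the ideal specular configuration. The non-specular frame is the sweep
    midpoint; the near-specular frame backs off ``offset_deg`` from the ideal
    specular angle (last frame) to avoid saturated highlights.
    """
    if n_frames < 2:
        raise ValueError("need at least 2 frames")
    if offset_deg >= span_deg:
        raise ValueError("offset must be smaller than the sweep span")
    step = span_deg / (n_frames - 1)
    idx_nonspec = int(np.clip(round(n_frames / 2), 1, n_frames))
    idx_spec = int(np.clip(n_frames - round(offset_deg / step), 1, n_frames))
    return FrameSelection(idx_nonspec, idx_spec, offset_deg)


def center_crop(img: np.ndarray, size: int) -> np.ndarray:
    h, w = img.shape[:2]
    if h < size or w < size:
        raise ValueError(f"image {h}x{w} smaller than crop size {size}")
    top, left = (h - size) // 2, (w - size) // 2
    return img[top:top + size, left:left + size]


def preprocess_for_embedding(pair: MaterialImagePair) -> tuple[np.ndarray, np.ndarray]:
    """Resample both frames to 250 DPI on the physical sample and centre-crop to 224 px.

    The depicted square sample of ``sample_size_mm`` is resampled to span
    ``round(sample_size_mm / 25.4 * 250)`` pixels (256 px for the canonical
    26 mm sample) and the central 224 x 224 window is taken.
    """
    target = round(pair.sample_size_mm / MM_PER_INCH * TARGET_DPI)
    if target < CROP_PX:
        raise ValueError(
            f"sample of {pair.sample_size_mm} mm resamples to {target} px < {CROP_PX} px")
    out = []
    for frame in pair.frames:
        if frame.shape[0] != target or frame.shape[1] != target:
            frame = resize(frame, (target, target, frame.shape[2]),
                           order=1, mode="reflect", anti_aliasing=True)
        out.append(np.clip(center_crop(frame, CROP_PX), 0.0, 1.0))
    return out[0], out[1]
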