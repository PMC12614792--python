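"""Image-space training augmentations for the feature-to-rating regressors.

The augmentations emulate benign capture variation: random crop, rotation
(never applied to the rotation-invariant S statistics), small isotropic
rescaling (up to 5%) and, when a full frame sequence is available, small
perturbations of the azimuthal capture angle (up to 2.5 degrees, realised by
picking the frame nearest the jittered angle; a no-op for bare image pairs).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.transform import resize, rotate

from ..images import MaterialImagePair

__all__ = ["AugmentationPolicy", "augment_pair"]


@dataclass(frozen=True)
class AugmentationPolicy:
    random_crop: bool = True
    rotation: bool = True  # must be False for S features
    max_scale: float = 0.05
    max_azimuth_jitter_deg: float = 2.5

    def for_kind(self, kind: str) -> "AugmentationPolicy":
        """The policy with rotation disabled for the rotation-invariant S features."""
        if kind == "S" and self.rotation:
            return AugmentationPolicy(self.random_crop, False,
                                      self.max_scale, self.max_azimuth_jitter_deg)
        return self


def _augment_frame(frame: np.ndarray, policy: AugmentationPolicy,
                   rng: np.random.Generator, angle: float, scale: float,
                   crop_shift: tuple[int, int]) -> np.ndarray:
    h, w, _ = frame.shape
    out = frame
    if policy.rotation and angle != 0.0:
        out = rotate(out, angle, mode="reflect", order=1)
    if scale != 1.0:
        sh, sw = round(h * scale), round(w * scale)
        out = resize(out, (sh, sw, 3), order=1, mode="reflect", anti_aliasing=scale < 1.0)
    if policy.random_crop:
        oh, ow = out.shape[:2]
        if oh > h or ow > w:
            top = min(max(0, (oh - h) // 2 + crop_shift[0]), oh - h)
            left = min(max(0, (ow - w) // 2 + crop_shift[1]), ow - w)
            out = out[top:top + h, left:left + w]
    if out.shape[:2] != (h, w):
        out = resize(out, (h, w, 3), order=1, mode="reflect", anti_aliasing=True)
    return np.clip(out, 0.0, 1.0)


def augment_pair(pair: MaterialImagePair, policy: AugmentationPolicy,
                 rng: np.random.Generator) -> MaterialImagePair:
    """One random augmentation of a frame pair, identical geometry for both frames."""
    angle = float(rng.uniform(-180.0, 180.0)) if policy.rotation else 0.0
    scale = float(1.0 + rng.uniform(-policy.max_scale, policy.max_scale))
    shift = (int(rng.integers(-8, 9)), int(rng.integers(-8, 9)))
    return MaterialImagePair(
        _augment_frame(pair.frame_nonspec, policy, rng, angle, scale, shift),
        _augment_frame(pair.frame_spec, policy, rng, angle, scale, shift),
        sample_size_mm=pair.sample_size_mm,
        material_id=pair.material_id,
    )
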