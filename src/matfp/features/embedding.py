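"""Deep-embedding features (the 1024-dim "C" representation).

A backend maps one 224 x 224 RGB image to a deterministic 512-dim vector; the
pair representation concatenates the non-specular and near-specular frame
embeddings. Backends are pluggable:

* :class:`SeededProjectionBackend` (default) — a fixed random linear projection
  of the downsampled image, fully deterministic and dependency-free. It honours
  every contract of the representation (dimensionality, determinism) and keeps
  the complete pipeline runnable offline; it does not claim the semantic power
  of a pretrained vision-language embedding.
* :class:`OpenClipBackend` — a ViT-B/32 vision-language encoder, available when
  the optional ``torch``/``open_clip_torch`` dependencies are installed.
"""

from __future__ import annotations

from typing import Protocol

import numpy as np

from ..images import MaterialImagePair
from .frames import CROP_PX, preprocess_for_embedding

__all__ = ["EmbeddingBackend", "SeededProjectionBackend", "OpenClipBackend",
           "embed_pair", "C_DIM", "EMBED_DIM"]

EMBED_DIM = 512
C_DIM = 2 * EMBED_DIM


class EmbeddingBackend(Protocol):
    def embed(self, image: np.ndarray) -> np.ndarray:
        """Map a 224 x 224 x 3 image in [0, 1] to a 512-vector, deterministically."""
        ...


class SeededProjectionBackend:
    """Fixed Gaussian projection of the 32 x 32 downsampled image to 512 dims."""

    def __init__(self, seed: int = 0, grid: int = 32) -> None:
        rng = np.random.default_rng(seed)
        self.grid = grid
        n_in = grid * grid * 3
        self.projection = rng.standard_normal((n_in, EMBED_DIM)) / np.sqrt(n_in)

    def embed(self, image: np.ndarray) -> np.ndarray:
        image = np.asarray(image, dtype=float)
        if image.shape != (CROP_PX, CROP_PX, 3):
            raise ValueError(f"backend expects a {CROP_PX}x{CROP_PX}x3 image, got {image.shape}")
        f = CROP_PX // self.grid
        pooled = image[: self.grid * f, : self.grid * f].reshape(
            self.grid, f, self.grid, f, 3).mean(axis=(1, 3))
        return pooled.ravel() @ self.projection


class OpenClipBackend:
    """ViT-B/32 image encoder adapter (requires the optional ``clip`` extra)."""

    def __init__(self, model_name: str = "ViT-B-32", pretrained: str = "openai") -> None:
        try:
            import open_clip  # type: ignore
            import torch  # type: ignore
        except ImportError as exc:  # pragma: no cover - optional dependency
            raise ImportError(
                "OpenClipBackend requires torch and open_clip_torch; "
                "install the 'clip' extra or use SeededProjectionBackend") from exc
        self._torch = torch
        self.model, _, _ = open_clip.create_model_and_transforms(
            model_name, pretrained=pretrained)
        self.model.eval()

    def embed(self, image: np.ndarray) -> np.ndarray:  # pragma: no cover - optional
        torch = self._torch
        mean = np.array([0.48145466, 0.4578275, 0.40821073])
        std = np.array([0.26862954, 0.26130258, 0.27577711])
        x = (image - mean) / std
        with torch.no_grad():
            t = torch.from_numpy(x.transpose(2, 0, 1)[None]).float()
            v = self.model.encode_image(t)[0].numpy()
        return v.astype(float)


def embed_pair(pair: MaterialImagePair, backend: EmbeddingBackend) -> np.ndarray:
    """1024-dim C feature vector: embeddings of both frames, non-specular first."""
    frame_n, frame_s = preprocess_for_embedding(pair)
    parts = []
    for frame in (frame_n, frame_s):
        v = np.asarray(backend.embed(frame), dtype=float)
        if v.shape != (EMBED_DIM,):
            raise ValueError(f"backend returned shape {v.shape}, expected ({EMBED_DIM},)")
        parts.append(v)
    return np.concatenate(parts)
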