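"""Attribute schema, visual fingerprints and the rating-space similarity metric.

A *visual fingerprint* summarises one material's appearance as a vector of 16
perceptual attribute values (colour vibrancy, surface roughness, ... warmth).
Fingerprints live on one of two scales:

``zscore``
    participant-normalised mean ratings, unbounded;
``unit``
    per-attribute min-max rescaled to [-1, 1] over a reference corpus, the
    scale on which the similarity metric is defined.

Similarity between two fingerprints ``v1``, ``v2`` is a weighted combination
of Pearson correlation and an L1 term::

    d(v1, v2) = alpha * R(v1, v2) + (1 - alpha) * (1 - sum|v1_i - v2_i| / (2 n))

with ``n = 16``.  ``alpha = 1`` compares only the *shape* of the profile,
``alpha = 0`` only absolute attribute amplitudes; ``alpha = 0.5`` is the
default.  On the unit scale ``|v1_i - v2_i| <= 2``, so the bracketed term is
bounded in [0, 1] and ``d`` in ``[-alpha, 1]``; higher means more similar.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "N_ATTRIBUTES",
    "Attribute",
    "AttributeSchema",
    "DEFAULT_SCHEMA",
    "Fingerprint",
    "FingerprintSet",
    "SimilarityMatrix",
    "fingerprint_similarity",
    "similarity_matrix",
    "retrieve_top_k",
    "typicality",
    "category_profile",
    "rescale_to_unit",
]

N_ATTRIBUTES = 16

Scale = Literal["zscore", "unit"]
ClusterLabel = Literal["gloss", "texture_and_pattern", "light_and_colour", "physical", "abstract"]


@dataclass(frozen=True)
class Attribute:
    """One perceptual attribute: rating-scale anchors and the question shown to raters."""

    id: int
    name: str
    anchor_low: str
    anchor_high: str
    question: str
    cluster: ClusterLabel


#: The 16 perceptual attributes, in canonical id order.
_ATTRIBUTE_ROWS: list[tuple[int, str, str, str, str, str]] = [
    (1, "colour vibrancy", "dull", "vibrant",
     "how richly coloured is the material, ranging from monochromatic or neutral-coloured "
     "materials to vibrantly coloured materials?", "light_and_colour"),
    (2, "surface roughness", "smooth", "rough",
     "how rough is the material, ranging from fine or smooth to coarse or grainy?",
     "texture_and_pattern"),
    (3, "pattern complexity", "plain", "complex",
     "how complex are the patterns on the material, ranging from simple to intricate?",
     "texture_and_pattern"),
    (4, "striped pattern", "no stripes", "pronounced stripes",
     "to what extent does the material exhibit stripy patterns?", "texture_and_pattern"),
    (5, "chequered pattern", "no checks", "pronounced checks",
     "to what extent does the material exhibit chequered patterns?", "texture_and_pattern"),
    (6, "brightness", "dark", "bright",
     "how bright is the material, ranging from dim or subdued to bright or luminous?",
     "light_and_colour"),
    (7, "shininess", "matt", "mirror",
     "how shiny is the material, ranging from dull or non-reflective to highly reflective?",
     "gloss"),
    (8, "sparkle", "none", "sparkling",
     "to what extent does the material exhibit sparkling and glittery effects?", "gloss"),
    (9, "hardness", "soft", "hard",
     "how hard is the material, ranging from soft or plush to firm or rigid?", "physical"),
    (10, "movement effect", "none", "extreme",
     "to what extent does the appearance change due to camera movement?", "gloss"),
    (11, "pattern scale", "fine", "large",
     "how large are the pattern elements, ranging from fine-grained or uniform to large or "
     "blotchy patterns?", "texture_and_pattern"),
    (12, "naturalness", "manmade", "natural",
     "how natural is the material, ranging from man-made to natural origin?", "abstract"),
    (13, "thickness", "flat", "thick",
     "how deep is the material structure, ranging from flat or thin to thick?", "physical"),
    (14, "multicoloured", "single", "many",
     "how multicoloured is the material, ranging from a single or uniform colour to colourful "
     "or many colours?", "light_and_colour"),
    (15, "value", "cheap", "luxurious",
     "how valuable is the material, ranging from low-cost or cheap to extravagant or "
     "luxurious?", "abstract"),
    (16, "warmth", "cold", "warm",
     "how warm is the material to the touch, ranging from cool or cold to pleasant or warm?",
     "physical"),
]


@dataclass(frozen=True)
class AttributeSchema:
    """Ordered collection of the 16 rating attributes."""

    attributes: tuple[Attribute, ...]

    def __post_init__(self) -> None:
        if len(self.attributes) != N_ATTRIBUTES:
            raise ValueError(f"schema must have exactly {N_ATTRIBUTES} attributes")
        ids = [a.id for a in self.attributes]
        if ids != list(range(1, N_ATTRIBUTES + 1)):
            raise ValueError("attribute ids must be 1..16 in order")

    @property
    def names(self) -> list[str]:
        return [a.name for a in self.attributes]

    def by_id(self, attribute_id: int) -> Attribute:
        return self.attributes[attribute_id - 1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(a.id, a.name, a.anchor_low, a.anchor_high, a.question, a.cluster)
             for a in self.attributes],
            columns=["id", "name", "anchor_low", "anchor_high", "question", "cluster"],
        )


DEFAULT_SCHEMA = AttributeSchema(
    tuple(Attribute(i, n, lo, hi, q, c) for i, n, lo, hi, q, c in _ATTRIBUTE_ROWS)
)


@dataclass
class Fingerprint:
    """16 attribute values for one material, on a declared scale."""

    material_id: str
    values: np.ndarray
    scale: Scale = "unit"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (N_ATTRIBUTES,):
            raise ValueError(f"fingerprint must have {N_ATTRIBUTES} values, got {self.values.shape}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError(f"fingerprint {self.material_id!r} contains non-finite values")
        if self.scale == "unit" and (self.values.min() < -1 - 1e-9 or self.values.max() > 1 + 1e-9):
            raise ValueError(f"unit-scale fingerprint {self.material_id!r} outside [-1, 1]")


class FingerprintSet:
    """A corpus of fingerprints sharing one scale, with optional per-material categories."""

    def __init__(
        self,
        fingerprints: Iterable[Fingerprint],
        categories: dict[str, str] | None = None,
    ) -> None:
        fps = list(fingerprints)
        ids = [f.material_id for f in fps]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate material ids in fingerprint set")
        scales = {f.scale for f in fps}
        if len(scales) > 1:
            raise ValueError(f"mixed scales in fingerprint set: {scales}")
        self._by_id: dict[str, Fingerprint] = {f.material_id: f for f in fps}
        self.categories: dict[str, str] = dict(categories or {})

    # -- container protocol -------------------------------------------------
    def __len__(self) -> int:
        return len(self._by_id)

    def __iter__(self):
        return iter(self._by_id.values())

    def __contains__(self, material_id: str) -> bool:
        return material_id in self._by_id

    def __getitem__(self, material_id: str) -> Fingerprint:
        return self._by_id[material_id]

    @property
    def ids(self) -> list[str]:
        return list(self._by_id)

    @property
    def scale(self) -> Scale:
        if not self._by_id:
            raise ValueError("empty fingerprint set has no scale")
        return next(iter(self._by_id.values())).scale

    def matrix(self, ids: Sequence[str] | None = None) -> np.ndarray:
        """Stack fingerprints (rows) in the given (default: insertion) id order."""
        ids = list(ids) if ids is not None else self.ids
        return np.stack([self._by_id[i].values for i in ids])

    # -- I/O ----------------------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        rows = []
        for fp in self:
            rows.append(
                {"material_id": fp.material_id,
                 "category": self.categories.get(fp.material_id, ""),
                 "scale": fp.scale,
                 **{f"attr{i:02d}": v for i, v in zip(range(1, 17), fp.values)}})
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "FingerprintSet":
        cols = [f"attr{i:02d}" for i in range(1, 17)]
        missing = [c for c in ["material_id", "scale", *cols] if c not in df.columns]
        if missing:
            raise ValueError(f"fingerprint table missing columns: {missing}")
        fps = [Fingerprint(str(r["material_id"]), r[cols].to_numpy(dtype=float), r["scale"])
               for _, r in df.iterrows()]
        cats = {}
        if "category" in df.columns:
            cats = {str(r["material_id"]): str(r["category"])
                    for _, r in df.iterrows() if str(r.get("category", "")) not in ("", "nan")}
        return cls(fps, cats)

    @classmethod
    def from_csv(cls, path) -> "FingerprintSet":
        return cls.from_frame(pd.read_csv(path))


@dataclass
class SimilarityMatrix:
    """Square matrix of pairwise fingerprint similarities."""

    ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError("similarity matrix shape does not match ids")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path)


# ---------------------------------------------------------------------------
# similarity metric
# ---------------------------------------------------------------------------

def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    """Pearson R with the degenerate (zero-variance) case mapped to 0."""
    ac = a - a.mean()
    bc = b - b.mean()
    denom = math.sqrt(float(ac @ ac) * float(bc @ bc))
    if denom == 0.0:
        warnings.warn(
            "zero-variance fingerprint: correlation term of the similarity set to 0",
            RuntimeWarning,
            stacklevel=3,
        )
        return 0.0
    return float(ac @ bc) / denom


def fingerprint_similarity(v1: Fingerprint, v2: Fingerprint, alpha: float = 0.5) -> float:
    """Similarity ``alpha*R + (1-alpha)*(1 - mean|diff|/2)`` between two unit-scale fingerprints.

    Symmetric in its arguments; equals 1 for identical non-constant fingerprints
    and is bounded below by ``-alpha``.
    """
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must lie in [0, 1]")
    if v1.scale != v2.scale:
        raise ValueError(f"scale mismatch: {v1.scale} vs {v2.scale}")
    if v1.scale != "unit":
        raise ValueError("similarity is defined on unit-scale fingerprints; rescale first")
    a, b = v1.values, v2.values
    r = _pearson(a, b) if alpha > 0 else 0.0
    l1 = 1.0 - float(np.abs(a - b).sum()) / (2.0 * N_ATTRIBUTES)
    return alpha * r + (1.0 - alpha) * l1


def similarity_matrix(fset: FingerprintSet, alpha: float = 0.5) -> SimilarityMatrix:
    """All pairwise similarities of a fingerprint set."""
    if len(fset) == 0:
        raise ValueError("cannot compute a similarity matrix of an empty set")
    ids = fset.ids
    n = len(ids)
    out = np.empty((n, n))
    fps = [fset[i] for i in ids]
    for i in range(n):
        out[i, i] = fingerprint_similarity(fps[i], fps[i], alpha)
        for j in range(i + 1, n):
            out[i, j] = out[j, i] = fingerprint_similarity(fps[i], fps[j], alpha)
    return SimilarityMatrix(ids, out)


def retrieve_top_k(
    query: Fingerprint,
    fset: FingerprintSet,
    k: int,
    alpha: float = 0.5,
) -> list[tuple[str, float]]:
    """The ``k`` most similar corpus members, most similar first.

    The query itself (matched by id) is excluded from the candidates. Ties are
    broken by ascending material id so retrieval is deterministic.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    candidates = [m for m in fset.ids if m != query.material_id]
    sims = [(m, fingerprint_similarity(query, fset[m], alpha)) for m in candidates]
    sims.sort(key=lambda t: (-t[1], t[0]))
    return sims[:k]


def typicality(
    material_id: str,
    fset: FingerprintSet,
    fraction: float = 0.10,
    alpha: float = 0.5,
) -> float:
    """Mean similarity to the top ``fraction`` most similar other corpus members.

    With the default fraction this averages a material's similarity to its top
    decile of neighbours; high values mark typical materials, low values
    outliers with no close match in the corpus.
    """
    if material_id not in fset:
        raise KeyError(f"unknown material {material_id!r}")
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must lie in (0, 1]")
    n_other = len(fset) - 1
    if n_other < 1:
        raise ValueError("typicality needs at least 2 corpus members")
    n_top = math.ceil(fraction * n_other)
    top = retrieve_top_k(fset[material_id], fset, k=n_top, alpha=alpha)
    return float(np.mean([s for _, s in top]))


def category_profile(fset: FingerprintSet, category: str) -> tuple[np.ndarray, np.ndarray]:
    """Per-attribute median and standard error of the mean within one category.

    The median vector is the category's characteristic fingerprint; the
    standard error quantifies within-category spread per attribute.
    """
    member_ids = [m for m in fset.ids if fset.categories.get(m) == category]
    if not member_ids:
        raise KeyError(f"no materials with category {category!r}")
    mat = fset.matrix(member_ids)
    median = np.median(mat, axis=0)
    if mat.shape[0] == 1:
        stderr = np.zeros(N_ATTRIBUTES)
    else:
        stderr = mat.std(axis=0, ddof=1) / math.sqrt(mat.shape[0])
    return median, stderr


@dataclass
class UnitRescaler:
    """Per-attribute affine map [min, max] -> [-1, 1] frozen on a reference corpus."""

    ref_min: np.ndarray
    ref_max: np.ndarray

    def transform(self, fp: Fingerprint, clip: bool = True) -> Fingerprint:
        v = 2.0 * (fp.values - self.ref_min) / (self.ref_max - self.ref_min) - 1.0
        if clip:
            v = np.clip(v, -1.0, 1.0)
        return Fingerprint(fp.material_id, v, scale="unit")


def rescale_to_unit(fset: FingerprintSet) -> tuple[FingerprintSet, UnitRescaler]:
    """Min-max rescale every attribute to [-1, 1] over the set.

    Returns the rescaled set and the frozen :class:`UnitRescaler` so that new
    fingerprints (e.g. model predictions) can be mapped onto the same scale.
    """
    if len(fset) == 0:
        raise ValueError("cannot rescale an empty set")
    mat = fset.matrix()
    lo, hi = mat.min(axis=0), mat.max(axis=0)
    flat = np.nonzero(hi <= lo)[0]
    if flat.size:
        names = [DEFAULT_SCHEMA.attributes[i].name for i in flat]
        raise ValueError(f"constant attribute(s) across the set: {names}")
    scaler = UnitRescaler(lo, hi)
    rescaled = FingerprintSet(
        (scaler.transform(fp) for fp in fset), categories=fset.categories)
    return rescaled, scaler
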