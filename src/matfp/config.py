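"""Run configuration and tabular-file validation for the command-line workflow."""

from __future__ import annotations

from dataclasses import asdict, dataclass
from pathlib import Path

import pandas as pd
import yaml

from .ratings import RATING_COLUMNS, SLIDER_RANGE
from .schema import DEFAULT_SCHEMA

__all__ = ["RunConfig", "validate_ratings_file", "write_attribute_table"]


@dataclass
class RunConfig:
    """All constants and seeds of one reproducible end-to-end run."""

    alpha: float = 0.5
    offset_deg: float = 6.0
    dpi: float = 250.0
    crop_px: int = 224
    canonical_px: int = 512
    sample_mm: float = 26.0
    kind: str = "S"                    # feature kind: S, T or C
    predictor: str = "mlp"             # "mlp" or "knn"
    knn_k: int = 2
    test_fraction: float = 0.2
    n_materials: int = 40
    size_px: int = 128                 # render size for synthetic corpora
    n_participants: int = 10
    response_noise_sd: float = 0.2
    n_adversarial: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must lie in [0, 1]")
        for name in ("offset_deg", "dpi", "crop_px", "canonical_px", "sample_mm"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.kind not in ("S", "T", "C"):
            raise ValueError(f"unknown feature kind {self.kind!r}")

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)


def validate_ratings_file(path) -> pd.DataFrame:
    """Read and schema-check a long-form ratings CSV.

    Rejects missing columns, duplicate (participant, material, attribute)
    triples, non-numeric responses and responses outside the slider range,
    reporting offending row numbers (1-based, excluding the header).
    """
    df = pd.read_csv(path)
    missing = [c for c in RATING_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    responses = pd.to_numeric(df["response"], errors="coerce")
    bad = df.index[responses.isna()].tolist()
    if bad:
        raise ValueError(f"{path}: non-numeric response in rows {[i + 1 for i in bad[:10]]}")
    df["response"] = responses.astype(float)
    lo, hi = SLIDER_RANGE
    out = df.index[(df["response"] < lo) | (df["response"] > hi)].tolist()
    if out:
        raise ValueError(
            f"{path}: responses outside [{lo:g}, {hi:g}] in rows {[i + 1 for i in out[:10]]}")
    dup_mask = df.duplicated(["participant_id", "material_id", "attribute_id"])
    if dup_mask.any():
        row = df[dup_mask].iloc[0]
        raise ValueError(
            f"{path}: duplicate triple ({row['participant_id']}, "
            f"{row['material_id']}, {row['attribute_id']})")
    df["attribute_id"] = df["attribute_id"].astype(int)
    if not df["attribute_id"].between(1, 16).all():
        raise ValueError(f"{path}: attribute ids must lie in 1..16")
    return df


def write_attribute_table(path) -> None:
    """Write the machine-readable attribute table (id, name, anchors, question)."""
    DEFAULT_SCHEMA.to_frame().to_csv(path, index=False)
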