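"""Shared fixtures: seeded fingerprints, small synthetic corpora, rating tables."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from matfp.schema import Fingerprint, FingerprintSet
from matfp.synth import RaterConfig, make_corpus, simulate_ratings


def random_unit_fingerprint(rng: np.random.Generator, material_id: str) -> Fingerprint:
    return Fingerprint(material_id, rng.uniform(-1.0, 1.0, size=16), scale="unit")


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(42)


@pytest.fixture
def unit_set(rng) -> FingerprintSet:
    """10 seeded unit-scale fingerprints with two categories."""
    fps = [random_unit_fingerprint(rng, f"m{i:02d}") for i in range(10)]
    cats = {f"m{i:02d}": ("fabric" if i < 5 else "wood") for i in range(10)}
    return FingerprintSet(fps, cats)


@pytest.fixture(scope="session")
def small_corpus():
    """8 rendered synthetic materials at 128 px (shared across feature tests)."""
    return make_corpus(8, seed=3, size_px=128)


@pytest.fixture(scope="session")
def recovery_corpus():
    """The 200-material corpus used by the predictor-recovery experiments."""
    from matfp.pipeline import extract_features

    pairs, truths, cats = make_corpus(200, seed=5, size_px=256)
    features = extract_features(pairs, "S")
    ids = [p.material_id for p in pairs]
    return features, truths.matrix(ids), truths, cats


@pytest.fixture
def ratings_50(rng) -> tuple[FingerprintSet, pd.DataFrame]:
    """50-material truth set with simulated raters: 10 raters, sd 0.2, 1 adversary."""
    _, truths, _ = make_corpus(50, seed=11, render=False)
    table = simulate_ratings(truths, RaterConfig(
        n_participants=10, response_noise_sd=0.2, n_adversarial=1, seed=12))
    return truths, table
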