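"""Comparison statistics between predicted and human fingerprints.

* ``rsm_r2`` — squared Pearson correlation between the strict upper triangles
  of the two fingerprint-similarity matrices (how well the model reproduces
  the *relational* structure of the corpus);
* ``rd_r2`` — per-attribute squared Pearson correlation across materials,
  plus its mean over the 16 attributes;
* ``mae`` — mean absolute error over materials x attributes;
* ``topk_overlap`` — per attribute, the overlap between the top-k materials
  ranked by prediction vs by human rating;
* ``rank_rci`` — per attribute, the Spearman correlation between human and
  predicted orderings within the top-n materials by human rating;
* ``aic_compare`` — Gaussian-likelihood Akaike information criterion
  ``AIC = 2 k + n ln(RSS / n)`` for competing models.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .schema import N_ATTRIBUTES, FingerprintSet, similarity_matrix

__all__ = ["EvalReport", "rsm_r2", "rd_r2", "mae", "topk_overlap", "rank_rci",
           "aic_compare", "evaluate"]


@dataclass
class EvalReport:
    rsm_r2: float
    rd_r2_per_attribute: list[float]
    rd_r2_mean: float
    mae: float
    overlap_top5_per_attribute: list[int]
    rci_per_attribute: list[float]
    aic: float | None = None

    def to_dict(self) -> dict:
        return {
            "rsm_r2": self.rsm_r2,
            "rd_r2_per_attribute": self.rd_r2_per_attribute,
            "rd_r2_mean": self.rd_r2_mean,
            "mae": self.mae,
            "overlap_top5_per_attribute": self.overlap_top5_per_attribute,
            "rci_per_attribute": self.rci_per_attribute,
            "aic": self.aic,
        }


def _aligned(pred: FingerprintSet, human: FingerprintSet) -> tuple[list[str], np.ndarray, np.ndarray]:
    if set(pred.ids) != set(human.ids):
        raise ValueError("prediction and human sets must contain the same material ids")
    ids = sorted(pred.ids)
    return ids, pred.matrix(ids), human.matrix(ids)


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    ac, bc = a - a.mean(), b - b.mean()
    denom = math.sqrt(float(ac @ ac) * float(bc @ bc))
    if denom == 0.0:
        return float("nan")
    return float(ac @ bc) / denom


def rsm_r2(pred: FingerprintSet, human: FingerprintSet, alpha: float = 0.5) -> float:
    """Squared correlation of the two similarity-matrix upper triangles."""
    ids, _, _ = _aligned(pred, human)
    if len(ids) < 3:
        raise ValueError("rsm_r2 needs at least 3 materials")
    sp = similarity_matrix(_subset(pred, ids), alpha).values
    sh = similarity_matrix(_subset(human, ids), alpha).values
    iu = np.triu_indices(len(ids), k=1)
    r = _pearson(sp[iu], sh[iu])
    return float(r * r)


def _subset(fset: FingerprintSet, ids: list[str]) -> FingerprintSet:
    return FingerprintSet((fset[i] for i in ids), categories=fset.categories)


def rd_r2(pred: FingerprintSet, human: FingerprintSet) -> tuple[np.ndarray, float]:
    """Per-attribute squared correlation across materials, and its mean."""
    _, p, h = _aligned(pred, human)
    out = np.empty(N_ATTRIBUTES)
    for a in range(N_ATTRIBUTES):
        r = _pearson(p[:, a], h[:, a])
        if math.isnan(r):
            warnings.warn(f"constant attribute {a + 1}: r^2 set to 0", RuntimeWarning)
            r = 0.0
        out[a] = r * r
    return out, float(out.mean())


def mae(pred: FingerprintSet, human: FingerprintSet) -> float:
    """Mean absolute error over all materials and attributes."""
    if pred.scale != human.scale:
        raise ValueError(f"scale mismatch: {pred.scale} vs {human.scale}")
    _, p, h = _aligned(pred, human)
    return float(np.abs(p - h).mean())


def _top_ids(values: np.ndarray, ids: list[str], k: int) -> set[str]:
    # descending by value, ties broken by ascending material id
    order = sorted(range(len(ids)), key=lambda i: (-values[i], ids[i]))
    return {ids[i] for i in order[:k]}


def topk_overlap(pred: FingerprintSet, human: FingerprintSet, k: int = 5) -> np.ndarray:
    """Per attribute, the size of the intersection of the two top-k material sets."""
    ids, p, h = _aligned(pred, human)
    if k > len(ids):
        raise ValueError(f"k={k} exceeds corpus size {len(ids)}")
    out = np.empty(N_ATTRIBUTES, dtype=int)
    for a in range(N_ATTRIBUTES):
        out[a] = len(_top_ids(p[:, a], ids, k) & _top_ids(h[:, a], ids, k))
    return out


def rank_rci(pred: FingerprintSet, human: FingerprintSet, top_n: int = 100) -> np.ndarray:
    """Spearman rank correlation within the top-n materials by human rating.

    For each attribute the ``top_n`` highest-rated materials (by the human
    data) are selected and the Spearman correlation between their human and
    predicted values is computed with ranks taken within that subset.
    """
    ids, p, h = _aligned(pred, human)
    if len(ids) < 2:
        raise ValueError("rank_rci needs at least 2 materials")
    n = min(top_n, len(ids))
    out = np.empty(N_ATTRIBUTES)
    for a in range(N_ATTRIBUTES):
        order = sorted(range(len(ids)), key=lambda i: (-h[i, a], ids[i]))[:n]
        hp, pp = h[order, a], p[order, a]
        if np.all(pp == pp[0]) or np.all(hp == hp[0]):
            warnings.warn(f"all-tied subset for attribute {a + 1}: RCI set to 0",
                          RuntimeWarning)
            out[a] = 0.0
        else:
            out[a] = stats.spearmanr(hp, pp).statistic
    return out


def aic_compare(models: list[dict]) -> list[float]:
    """Gaussian AIC per model from ``{"n_params": int, "residuals": array}`` entries."""
    out = []
    for m in models:
        res = np.asarray(m["residuals"], dtype=float).ravel()
        if res.size == 0:
            raise ValueError("empty residuals")
        rss = float(res @ res)
        if rss == 0.0:
            raise ValueError("zero residual sum of squares: AIC degenerate")
        n = res.size
        out.append(2.0 * m["n_params"] + n * math.log(rss / n))
    return out


def evaluate(pred: FingerprintSet, human: FingerprintSet, alpha: float = 0.5,
             k: int = 5, top_n: int = 100,
             n_params: int | None = None) -> EvalReport:
    """All comparison statistics in one report."""
    per_attr, mean_r2 = rd_r2(pred, human)
    aic = None
    if n_params is not None:
        _, p, h = _aligned(pred, human)
        aic = aic_compare([{"n_params": n_params, "residuals": p - h}])[0]
    return EvalReport(
        rsm_r2=rsm_r2(pred, human, alpha),
        rd_r2_per_attribute=[float(v) for v in per_attr],
        rd_r2_mean=mean_r2,
        mae=mae(pred, human),
        overlap_top5_per_attribute=[int(v) for v in topk_overlap(pred, human, k)],
        rci_per_attribute=[float(v) for v in rank_rci(pred, human, top_n)],
        aic=aic,
    )
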