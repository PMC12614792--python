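"""Feature-to-fingerprint regressors: 2NN interpolation and MLP networks.

Two inference routes map an image-computable feature vector to the 16
attribute values:

* **kNN interpolation** (``k = 2`` by default, "2NN"): find the k training
  materials with the closest features in the L2 sense and blend their
  fingerprints with inverse-distance weights. A zero-distance match returns
  that material's fingerprint exactly.
* **MLP regression**: a small fully connected network per feature kind —
  T: 1341-256-64-32-16, S: 28-16-16-16, C: 1024-512-512-16 — with ReLU hidden
  activations, an identity output layer and a mean-squared-error objective.

Features are standardised per dimension over the training set before either
route (stored with the model), so L2 distances and gradient conditioning are
not dominated by feature scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from sklearn.neural_network import MLPRegressor

from .features.augment import AugmentationPolicy
from .schema import N_ATTRIBUTES, Fingerprint

__all__ = [
    "MLP_ARCHITECTURES", "TrainTestSplit", "split_dataset",
    "FeatureStandardizer", "KnnModel", "knn_predict",
    "MlpConfig", "MlpModel", "train_mlp", "mlp_predict",
]

#: Layer dimensions (input .. output) per feature kind.
MLP_ARCHITECTURES: dict[str, tuple[int, ...]] = {
    "T": (1341, 256, 64, 32, 16),
    "S": (28, 16, 16, 16),
    "C": (1024, 512, 512, 16),
}


# ---------------------------------------------------------------------------
# dataset split
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TrainTestSplit:
    train_ids: tuple[str, ...]
    test_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        if set(self.train_ids) & set(self.test_ids):
            raise ValueError("train and test ids overlap")


def split_dataset(
    ids_with_categories: dict[str, str],
    test_fraction: float = 0.2,
    seed: int = 0,
) -> TrainTestSplit:
    """Stratified random split: ``round(test_fraction * n)`` test members per
    category (at least 1 when the category has >= 2 members; a singleton
    category goes entirely to training)."""
    if not ids_with_categories:
        raise ValueError("empty corpus")
    rng = np.random.default_rng(seed)
    by_cat: dict[str, list[str]] = {}
    for mid in sorted(ids_with_categories):
        by_cat.setdefault(ids_with_categories[mid], []).append(mid)
    train, test = [], []
    for cat in sorted(by_cat):
        members = by_cat[cat]
        n = len(members)
        n_test = int(round(test_fraction * n))
        if n >= 2:
            n_test = max(1, n_test)
        else:
            n_test = 0
        picked = rng.choice(members, size=n_test, replace=False) if n_test else []
        test.extend(picked)
        train.extend(m for m in members if m not in set(picked))
    return TrainTestSplit(tuple(sorted(train)), tuple(sorted(test)))


# ---------------------------------------------------------------------------
# feature standardisation
# ---------------------------------------------------------------------------

@dataclass
class FeatureStandardizer:
    mean: np.ndarray
    sd: np.ndarray

    @classmethod
    def fit(cls, features: np.ndarray) -> "FeatureStandardizer":
        mean = features.mean(axis=0)
        sd = features.std(axis=0)
        sd = np.where(sd == 0.0, 1.0, sd)
        return cls(mean, sd)

    def transform(self, features: np.ndarray) -> np.ndarray:
        return (np.asarray(features, dtype=float) - self.mean) / self.sd


# ---------------------------------------------------------------------------
# kNN interpolation
# ---------------------------------------------------------------------------

@dataclass
class KnnModel:
    """Stored training exemplars for inverse-distance kNN interpolation."""

    kind: str
    features: np.ndarray          # (n, d) raw training features
    fingerprints: np.ndarray      # (n, 16)
    ids: tuple[str, ...]
    k: int = 2
    standardizer: FeatureStandardizer = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        self.fingerprints = np.asarray(self.fingerprints, dtype=float)
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.features.shape[0] != self.fingerprints.shape[0]:
            raise ValueError("features and fingerprints disagree in length")
        if self.features.shape[0] < self.k:
            raise ValueError(
                f"need at least k={self.k} training samples, got {self.features.shape[0]}")
        if self.fingerprints.shape[1] != N_ATTRIBUTES:
            raise ValueError("fingerprints must have 16 attributes")
        if self.standardizer is None:
            self.standardizer = FeatureStandardizer.fit(self.features)
        self._std_features = self.standardizer.transform(self.features)


def knn_predict(model: KnnModel, query: np.ndarray, material_id: str = "") -> Fingerprint:
    """Inverse-distance interpolation of the k nearest training fingerprints."""
    q = model.standardizer.transform(np.atleast_2d(query))[0]
    if q.shape != (model.features.shape[1],):
        raise ValueError(
            f"query dimension {q.shape} does not match model ({model.features.shape[1]},)")
    d = np.linalg.norm(model._std_features - q, axis=1)
    order = np.lexsort((model.ids, d))[: model.k]
    dk = d[order]
    if dk[0] == 0.0:
        values = model.fingerprints[order[0]]
    else:
        w = 1.0 / dk
        w = w / w.sum()
        values = w @ model.fingerprints[order]
    return Fingerprint(material_id or "prediction", np.clip(values, -1.0, 1.0), scale="unit")


# ---------------------------------------------------------------------------
# MLP regression
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MlpConfig:
    """Training configuration for the fingerprint MLPs.

    The default regime is full-batch L-BFGS with a small grid of L2 penalties
    and several random restarts; the (penalty, restart) pair with the lowest
    mean-squared error on a held-out validation slice of the training
    materials is kept. For small networks this optimises far more reliably
    than stochastic first-order training; ``solver="adam"`` (learning rate
    1e-3, batch 32, up to ``max_epochs``, early stopping on the validation
    slice) is available as an alternative.
    """

    solver: str = "lbfgs"
    alpha_grid: tuple[float, ...] = (0.3, 1.0, 3.0)
    n_restarts: int = 8
    ensemble_top_k: int = 5
    max_epochs: int = 3000
    validation_fraction: float = 0.15
    tol: float = 1e-7
    seed: int = 0
    # adam-only settings
    learning_rate: float = 1e-3
    batch_size: int = 32
    n_iter_no_change: int = 50


@dataclass
class MlpModel:
    """A trained feature-kind-specific MLP with its standardisation constants.

    ``members`` holds one or more networks of the kind's architecture; the
    prediction is the average over members (a small restart ensemble, which
    stabilises very small networks). Targets are standardised per attribute
    during training; the stored constants invert that at prediction time.
    """

    kind: str
    members: list[MLPRegressor]
    standardizer: FeatureStandardizer
    layer_dims: tuple[int, ...]
    target_mean: np.ndarray = field(default_factory=lambda: np.zeros(N_ATTRIBUTES))
    target_sd: np.ndarray = field(default_factory=lambda: np.ones(N_ATTRIBUTES))

    @property
    def n_parameters(self) -> int:
        """Trainable weights of a single member network."""
        dims = self.layer_dims
        return int(sum(dims[i] * dims[i + 1] + dims[i + 1] for i in range(len(dims) - 1)))

    def predict_matrix(self, standardized_features: np.ndarray) -> np.ndarray:
        raw = np.mean([m.predict(standardized_features) for m in self.members], axis=0)
        return raw * self.target_sd + self.target_mean


def train_mlp(
    features: np.ndarray,
    fingerprints: np.ndarray,
    kind: str,
    policy: AugmentationPolicy | None = None,
    config: MlpConfig = MlpConfig(),
    augmenter: Callable[[np.random.Generator], tuple[np.ndarray, np.ndarray]] | None = None,
) -> MlpModel:
    """Fit the kind-specific MLP by minimising mean squared error.

    ``augmenter``, when given, is called with a seeded generator and must
    return extra (features, targets) pairs produced by image-space
    augmentation of the training materials (crop/rotation/scale per the
    policy; rotation is never applied for the rotation-invariant S features —
    :meth:`AugmentationPolicy.for_kind` enforces this upstream where the
    augmented features are generated).
    """
    if kind not in MLP_ARCHITECTURES:
        raise ValueError(f"unknown feature kind {kind!r}")
    dims = MLP_ARCHITECTURES[kind]
    X = np.asarray(features, dtype=float)
    y = np.asarray(fingerprints, dtype=float)
    if X.ndim != 2 or X.shape[1] != dims[0]:
        raise ValueError(f"{kind} features must have {dims[0]} columns, got {X.shape}")
    if y.shape != (X.shape[0], N_ATTRIBUTES):
        raise ValueError(f"fingerprints must be (n, {N_ATTRIBUTES}), got {y.shape}")
    if X.shape[0] < 2:
        raise ValueError("need at least 2 training samples")

    n_orig = X.shape[0]
    # validation slice drawn from the original (non-augmented) materials
    rng = np.random.default_rng(config.seed)
    n_val = int(round(config.validation_fraction * n_orig)) if n_orig >= 20 else 0
    val_idx = rng.choice(n_orig, size=n_val, replace=False) if n_val else np.array([], int)
    val_mask = np.zeros(n_orig, dtype=bool)
    val_mask[val_idx] = True

    if augmenter is not None:
        extra_X, extra_y = augmenter(np.random.default_rng(config.seed))
        if len(extra_X):
            X = np.vstack([X, np.asarray(extra_X, dtype=float)])
            y = np.vstack([y, np.asarray(extra_y, dtype=float)])
            val_mask = np.concatenate([val_mask, np.zeros(len(extra_X), dtype=bool)])

    train_mask = ~val_mask
    standardizer = FeatureStandardizer.fit(X[train_mask])
    Xs = standardizer.transform(X)
    y_mean = y[train_mask].mean(axis=0)
    y_sd = y[train_mask].std(axis=0)
    y_sd = np.where(y_sd == 0.0, 1.0, y_sd)
    ys = (y - y_mean) / y_sd

    def _make(alpha: float, seed: int) -> MLPRegressor:
        common = dict(hidden_layer_sizes=dims[1:-1], activation="relu",
                      alpha=alpha, random_state=seed, tol=config.tol)
        if config.solver == "lbfgs":
            return MLPRegressor(solver="lbfgs", max_iter=config.max_epochs, **common)
        return MLPRegressor(
            solver="adam", learning_rate_init=config.learning_rate,
            max_iter=config.max_epochs,
            batch_size=min(config.batch_size, int(train_mask.sum())),
            early_stopping=False, n_iter_no_change=config.n_iter_no_change,
            shuffle=True, **common)

    fits: list[tuple[float, int, MLPRegressor]] = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # convergence warnings are expected at small budgets
        for alpha in config.alpha_grid:
            for restart in range(max(1, config.n_restarts)):
                seed = (config.seed * 1009 + restart * 97 + int(alpha * 1000)) % (2**31 - 1)
                reg = _make(alpha, seed)
                reg.fit(Xs[train_mask], ys[train_mask])
                eval_mask = val_mask if n_val else train_mask
                pred = reg.predict(Xs[eval_mask]) * y_sd + y_mean
                resid = np.clip(pred, -1.0, 1.0) - y[eval_mask]
                fits.append((float((resid**2).mean()), len(fits), reg))
    fits.sort(key=lambda t: (t[0], t[1]))
    members = [reg for _, _, reg in fits[: max(1, config.ensemble_top_k)]]
    return MlpModel(kind=kind, members=members, standardizer=standardizer,
                    layer_dims=dims, target_mean=y_mean, target_sd=y_sd)


def mlp_predict(model: MlpModel, query: np.ndarray, material_id: str = "") -> Fingerprint:
    """Deterministic forward pass of the trained MLP for one feature vector."""
    q = np.asarray(query, dtype=float)
    if q.shape != (model.layer_dims[0],):
        raise ValueError(f"query dimension {q.shape} does not match {model.layer_dims[0]}")
    if not np.all(np.isfinite(q)):
        raise ValueError("non-finite feature values")
    values = model.predict_matrix(model.standardizer.transform(q[None]))[0]
    return Fingerprint(material_id or "prediction", np.clip(values, -1.0, 1.0), scale="unit")


def mlp_predict_batch(model: MlpModel, queries: np.ndarray) -> np.ndarray:
    """Forward pass for a feature matrix; rows align with the input order."""
    Q = np.asarray(queries, dtype=float)
    if not np.all(np.isfinite(Q)):
        raise ValueError("non-finite feature values")
    return np.clip(model.predict_matrix(model.standardizer.transform(Q)), -1.0, 1.0)
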