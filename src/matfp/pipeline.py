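"""End-to-end workflow: synthesise/aggregate -> features -> split -> train ->
predict -> evaluate.

Every stage is seeded from the :class:`~matfp.config.RunConfig`, so two runs
with identical configuration produce identical fingerprints and reports.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .config import RunConfig
from .evaluation import EvalReport, evaluate
from .features import (FEATURE_DIMS, SeededProjectionBackend, embed_pair,
                       fit_zero_mask, raw_texture_stats_pair, stat_features)
from .images import MaterialImagePair
from .predictors import (KnnModel, MlpConfig, knn_predict, mlp_predict_batch,
                         split_dataset, train_mlp)
from .ratings import aggregate_ratings
from .schema import Fingerprint, FingerprintSet, rescale_to_unit
from .synth import RaterConfig, make_corpus, simulate_ratings

__all__ = ["PipelineResult", "extract_features", "run_pipeline"]


@dataclass
class PipelineResult:
    report: EvalReport
    human: FingerprintSet          # aggregated "human" fingerprints (unit scale)
    predicted: FingerprintSet      # model predictions on the test set
    test_ids: tuple[str, ...]
    train_ids: tuple[str, ...]


def extract_features(pairs: list[MaterialImagePair], kind: str,
                     backend=None, mask=None) -> np.ndarray:
    """Feature matrix (one row per pair) of the requested kind."""
    if kind == "S":
        return np.stack([stat_features(p) for p in pairs])
    if kind == "T":
        raw = [raw_texture_stats_pair(p) for p in pairs]
        if mask is None:
            mask = fit_zero_mask(raw)
        return np.stack([mask.apply(r) for r in raw])
    if kind == "C":
        backend = backend or SeededProjectionBackend()
        return np.stack([embed_pair(p, backend) for p in pairs])
    raise ValueError(f"unknown feature kind {kind!r}")


def run_pipeline(config: RunConfig, out_dir=None) -> PipelineResult:
    """Run the full synthetic study: corpus, ratings, aggregation, prediction.

    Stages: (1) generate a stratified synthetic corpus, (2) simulate raters and
    aggregate their responses into mean fingerprints, (3) extract image
    features, (4) split by category, (5) train the regressor, (6) predict and
    evaluate on the held-out materials. Any stage failure aborts with the
    stage name in the error message.
    """
    stage = "synthesize"
    try:
        pairs, truths, categories = make_corpus(
            config.n_materials, seed=config.seed, size_px=config.size_px)

        stage = "aggregate"
        ratings = simulate_ratings(truths, RaterConfig(
            n_participants=config.n_participants,
            response_noise_sd=config.response_noise_sd,
            n_adversarial=config.n_adversarial,
            seed=config.seed + 1))
        report = aggregate_ratings(ratings)
        human_unit, _ = rescale_to_unit(report.fingerprints)
        human_unit.categories.update(categories)

        stage = "features"
        features = extract_features(pairs, config.kind)
        ids = [p.material_id for p in pairs]
        feat_by_id = {mid: features[i] for i, mid in enumerate(ids)}

        stage = "split"
        split = split_dataset(categories, config.test_fraction, seed=config.seed + 2)

        stage = "train"
        X_train = np.stack([feat_by_id[m] for m in split.train_ids])
        y_train = human_unit.matrix(split.train_ids)
        if config.predictor == "knn":
            model = KnnModel(config.kind, X_train, y_train, split.train_ids, k=config.knn_k)
        else:
            if X_train.shape[1] != FEATURE_DIMS[config.kind] and config.kind == "T":
                raise ValueError("texture mask did not produce the canonical dimension")
            if config.kind == "S":
                mlp_cfg = MlpConfig(seed=config.seed + 3)
            else:
                # the T and C networks are much larger; keep the restart grid small
                mlp_cfg = MlpConfig(seed=config.seed + 3, alpha_grid=(0.3, 1.0),
                                    n_restarts=2, ensemble_top_k=2, max_epochs=400)
            model = train_mlp(X_train, y_train, config.kind, config=mlp_cfg)

        stage = "predict"
        X_test = np.stack([feat_by_id[m] for m in split.test_ids])
        if config.predictor == "knn":
            preds = [knn_predict(model, x, mid) for x, mid in zip(X_test, split.test_ids)]
        else:
            mat = mlp_predict_batch(model, X_test)
            preds = [Fingerprint(mid, row, scale="unit")
                     for mid, row in zip(split.test_ids, mat)]
        predicted = FingerprintSet(preds, categories)

        stage = "evaluate"
        human_test = FingerprintSet((human_unit[m] for m in split.test_ids), categories)
        eval_report = evaluate(predicted, human_test, alpha=config.alpha,
                               k=min(5, len(split.test_ids)),
                               top_n=min(100, len(split.test_ids)))
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        human_unit.to_csv(out / "fingerprints.csv")
        predicted.to_csv(out / "predictions.csv")
        (out / "report.json").write_text(
            json.dumps(eval_report.to_dict(), indent=2, sort_keys=True))
        config.to_yaml(out / "config.yaml")

    return PipelineResult(eval_report, human_unit, predicted,
                          split.test_ids, split.train_ids)
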