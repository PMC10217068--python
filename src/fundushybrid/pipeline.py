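"""End-to-end orchestration of the six classification systems.

Strategies
----------
========================  ================================================
name                      feature assembly
========================  ================================================
s1_mobilenet              backbone A -> PCA(450)
s1_densenet               backbone B -> PCA(450)
s2_fuse_before            concat(A, B) -> PCA(710)
s2_fuse_after             PCA(450) per backbone -> concat (900)
s3_mobilenet_hand         PCA(450) of A || handcrafted 255  (705)
s3_densenet_hand          PCA(450) of B || handcrafted 255  (705)
========================  ================================================

All strategies share the enhancement, split, training and evaluation code
paths; only the feature-assembly stage differs.  PCA is fitted on the full
feature matrix (the reduction is unsupervised); requested component counts
are capped at N-1 on toy-sized datasets, with the cap logged.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import classifier_eval as ce
from .dataset import (
    LabeledImageSet,
    SyntheticConfig,
    augment_image,
    generate_synthetic_dataset,
    split_dataset,
)
from .deep_features import BackboneSpec, apply_pca, effective_components, extract_deep_features, fit_pca
from .enhancement import enhance
from .errors import InvalidArgumentError
from .fusion import fuse_after_pca, fuse_before_pca, fuse_cnn_handcrafted
from .handcrafted import BLOCK_MAP, handcrafted_vector

__all__ = ["StrategyConfig", "PipelineResult", "run_pipeline", "STRATEGIES"]

logger = logging.getLogger(__name__)

STRATEGIES = (
    "s1_mobilenet",
    "s1_densenet",
    "s2_fuse_before",
    "s2_fuse_after",
    "s3_mobilenet_hand",
    "s3_densenet_hand",
)


@dataclass(frozen=True)
class StrategyConfig:
    strategy: str = "s3_mobilenet_hand"
    seed: int = 0
    backbone_a: BackboneSpec = BackboneSpec(name="toy-mobilenet")
    backbone_b: BackboneSpec = BackboneSpec(name="toy-densenet121")
    pca_single: int = 450
    pca_joint: int = 710
    mlp_hidden_units: int = 15
    mlp_max_epochs: int = 100
    validation_patience: int = 6
    augment_training: bool = False
    synthetic: SyntheticConfig | None = None
    output_dir: str | None = None

    def __post_init__(self):
        if self.strategy not in STRATEGIES:
            raise InvalidArgumentError(f"unknown strategy {self.strategy!r}")


@dataclass
class PipelineResult:
    strategy: str
    feature_width: int
    confusion: np.ndarray
    metrics: dict
    auc: dict
    trace: ce.TrainingTrace
    split: object
    error_histogram: dict


def _capped_pca(X: np.ndarray, requested: int, stage: str):
    eff = effective_components(requested, X.shape[0], X.shape[1])
    if eff < requested:
        logger.warning("%s: PCA components capped %d -> %d (N=%d)", stage, requested, eff, X.shape[0])
    model = fit_pca(X, eff)
    return apply_pca(model, X)


def _assemble_features(cfg: StrategyConfig, images: list, train_idx=None) -> np.ndarray:
    """Feature-assembly stage; the only part that differs across strategies."""
    need_a = cfg.strategy in ("s1_mobilenet", "s2_fuse_before", "s2_fuse_after", "s3_mobilenet_hand")
    need_b = cfg.strategy in ("s1_densenet", "s2_fuse_before", "s2_fuse_after", "s3_densenet_hand")
    A = extract_deep_features(images, cfg.backbone_a) if need_a else None
    B = extract_deep_features(images, cfg.backbone_b) if need_b else None

    if cfg.strategy == "s1_mobilenet":
        return _capped_pca(A, cfg.pca_single, cfg.strategy)
    if cfg.strategy == "s1_densenet":
        return _capped_pca(B, cfg.pca_single, cfg.strategy)
    if cfg.strategy == "s2_fuse_before":
        n = A.shape[0]
        eff = effective_components(cfg.pca_joint, n, A.shape[1] + B.shape[1])
        if eff < cfg.pca_joint:
            logger.warning("s2_fuse_before: PCA components capped %d -> %d", cfg.pca_joint, eff)
        fused, _ = fuse_before_pca(A, B, pca_dim=eff)
        return fused
    if cfg.strategy == "s2_fuse_after":
        eff = effective_components(cfg.pca_single, A.shape[0], A.shape[1])
        A_red = _capped_pca(A, cfg.pca_single, cfg.strategy)
        B_red = _capped_pca(B, cfg.pca_single, cfg.strategy)
        return fuse_after_pca(A_red, B_red, per_model_dim=eff)

    # strategy 3: globally scaled CNN PCA block + min-max handcrafted block
    C = A if cfg.strategy == "s3_mobilenet_hand" else B
    eff = effective_components(cfg.pca_single, C.shape[0], C.shape[1])
    C_red = _capped_pca(C, cfg.pca_single, cfg.strategy)
    H = np.stack([handcrafted_vector(im).values for im in images])
    if train_idx is None:
        train_idx = np.arange(C_red.shape[0])
    C_red = _scale_pca_block(C_red, train_idx)
    H = _minmax_scale_columns(H, train_idx)
    return fuse_cnn_handcrafted(C_red, H, cnn_dim=eff, hand_dim=sum(BLOCK_MAP.values()))


def _minmax_scale_columns(X: np.ndarray, train_idx) -> np.ndarray:
    """Column-wise min-max scaling to [0,1] using training-row statistics."""
    train_idx = np.asarray(train_idx, dtype=int)
    lo = X[train_idx].min(axis=0)
    hi = X[train_idx].max(axis=0)
    span = np.where(hi > lo, hi - lo, 1.0)
    return (X - lo) / span


def _scale_pca_block(C: np.ndarray, train_idx) -> np.ndarray:
    """Scale a PCA score block by one global factor.

    A single scalar preserves the variance ordering of the components;
    per-column scaling would stretch near-noise trailing components to the
    same range as the leading ones.
    """
    train_idx = np.asarray(train_idx, dtype=int)
    peak = np.abs(C[train_idx]).max()
    return C / peak if peak > 0 else C


def run_pipeline(cfg: StrategyConfig, image_set: LabeledImageSet | None = None) -> PipelineResult:
    """Execute enhance -> split -> (augment) -> features -> train -> evaluate.

    ``image_set`` defaults to the synthetic dataset described by
    ``cfg.synthetic`` (or the stock SyntheticConfig seeded from ``cfg.seed``).
    Artifacts are written under ``cfg.output_dir`` when set.
    """
    if image_set is None:
        synth = cfg.synthetic or SyntheticConfig(seed=cfg.seed)
        image_set = generate_synthetic_dataset(synth)
    classes = image_set.classes

    logger.info("pipeline %s: %d images, classes=%s", cfg.strategy, len(image_set), classes)
    enhanced = [enhance(image_set.image(i)) for i in range(len(image_set))]
    labels = np.asarray(image_set.labels)

    split = split_dataset(image_set, seed=cfg.seed)

    images, y = list(enhanced), labels
    if cfg.augment_training:
        # the augmented training set holds exactly 9 variants per original
        # (reference counts are 9x the raw training counts); variants are
        # appended after the originals so validation/test indices stay valid,
        # and the original training rows are dropped from the train partition
        aug_images, aug_labels, aug_idx = [], [], []
        next_idx = len(images)
        for i in split.train:
            for var in augment_image(images[i], seed=cfg.seed):
                aug_images.append(var)
                aug_labels.append(labels[i])
                aug_idx.append(next_idx)
                next_idx += 1
        n_before = len(split.train)
        images = images + aug_images
        y = np.concatenate([labels, np.asarray(aug_labels)]) if aug_labels else labels
        split = replace(split, train=tuple(aug_idx))
        logger.info("augmentation: training rows %d -> %d", n_before, len(split.train))

    X = _assemble_features(cfg, images, train_idx=split.train)
    logger.info("%s: feature width %d", cfg.strategy, X.shape[1])

    mlp = ce.MLPConfig(
        input_dim=X.shape[1],
        hidden_units=cfg.mlp_hidden_units,
        output_classes=len(classes),
        max_epochs=cfg.mlp_max_epochs,
        validation_patience=cfg.validation_patience,
        seed=cfg.seed,
    )
    model, trace = ce.train_ann(X, y, split, mlp)

    test_idx = np.asarray(split.test, dtype=int)
    cm = ce.evaluate(model, X[test_idx], y[test_idx], classes=classes)
    metrics = ce.metrics_from_confusion(cm, classes=classes)
    probs = ce.predict_proba(model, X[test_idx])
    auc = ce.roc_auc(probs, y[test_idx], classes)

    onehot = np.zeros((len(y), len(classes)))
    for i, lab in enumerate(y):
        onehot[i, classes.index(lab)] = 1.0
    phase_tags = np.empty(len(y), dtype=object)
    phase_tags[:] = "train"
    phase_tags[np.asarray(split.validation, dtype=int)] = "validation"
    phase_tags[test_idx] = "test"
    all_probs = ce.predict_proba(model, X)
    hist = ce.error_histogram(onehot, all_probs, phase_tags, bins=20)

    result = PipelineResult(
        strategy=cfg.strategy,
        feature_width=X.shape[1],
        confusion=cm,
        metrics=metrics,
        auc=auc,
        trace=trace,
        split=split,
        error_histogram=hist,
    )
    if cfg.output_dir:
        _write_artifacts(cfg, result, image_set, y)
    return result


def _write_artifacts(cfg: StrategyConfig, res: PipelineResult, image_set, y) -> None:
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    classes = image_set.classes

    partition = np.empty(len(y), dtype=object)
    partition[:] = "train"
    partition[np.asarray(res.split.validation, dtype=int)] = "validation"
    partition[np.asarray(res.split.test, dtype=int)] = "test"
    pd.DataFrame({"index": np.arange(len(y)), "label": y, "partition": partition}).to_csv(
        out / "split.csv", index=False
    )

    pd.DataFrame(res.confusion, index=classes, columns=classes).to_csv(out / "confusion.csv")

    with open(out / "metrics.json", "w") as fh:
        json.dump(
            {
                "strategy": res.strategy,
                "feature_width": res.feature_width,
                "metrics": res.metrics,
                "auc": res.auc,
                "best_epoch": res.trace.best_epoch,
                "stop_reason": res.trace.stop_reason,
            },
            fh,
            indent=2,
        )

    trace_df = pd.DataFrame(
        {
            "epoch": np.arange(res.trace.epochs_run),
            "gradient_norm": res.trace.gradient_norm,
            **{f"ce_{k}": v for k, v in res.trace.cross_entropy.items()},
            **{f"mse_{k}": v for k, v in res.trace.mse.items()},
        }
    )
    trace_df.to_csv(out / "trace.csv", index=False)
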