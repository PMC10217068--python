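"""Shallow neural-network classifier and the full evaluation suite.

The classifier is a softmax pattern-recognition network (default: one
hidden layer of 15 tanh units) trained by full-batch gradient descent with
momentum on the cross-entropy objective.  Training stops when validation
loss fails to improve for a fixed number of consecutive epochs, when the
gradient norm falls under a floor, or at the epoch cap; the weights of the
best validation epoch are restored.

Evaluation covers the multiclass confusion matrix, one-vs-rest percentage
metrics (accuracy, precision, specificity, sensitivity), per-class diagonal
recall (the per-class "accuracy" convention of confusion-matrix figures),
one-vs-rest ROC AUC and the per-phase error histogram.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidArgumentError

__all__ = [
    "MLPConfig",
    "ANNModel",
    "TrainingTrace",
    "train_ann",
    "predict_proba",
    "predict",
    "evaluate",
    "metrics_from_confusion",
    "roc_auc",
    "error_histogram",
]


@dataclass(frozen=True)
class MLPConfig:
    input_dim: int
    hidden_units: int = 15
    hidden_layers: int = 1
    output_classes: int = 4
    max_epochs: int = 100
    validation_patience: int = 6
    gradient_floor: float = 1e-6
    learning_rate: float = 0.3
    momentum: float = 0.9
    #: per-feature standardisation scale is floored at this fraction of the
    #: largest feature std, so near-constant (noise) features are not blown
    #: up to unit variance — essential when the input is a PCA score matrix
    scale_floor: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if self.input_dim < 1 or self.hidden_units < 1 or self.hidden_layers < 1:
            raise InvalidArgumentError("network dimensions must be positive")
        if self.validation_patience < 1:
            raise InvalidArgumentError("patience must be >= 1")


@dataclass
class TrainingTrace:
    cross_entropy: dict = field(default_factory=lambda: {"train": [], "validation": [], "test": []})
    mse: dict = field(default_factory=lambda: {"train": [], "validation": [], "test": []})
    gradient_norm: list = field(default_factory=list)
    best_epoch: int = -1
    stop_reason: str = ""

    @property
    def epochs_run(self) -> int:
        return len(self.gradient_norm)


@dataclass
class ANNModel:
    weights: list  # [(W, b), ...] input->hidden(s)->output
    feature_mean: np.ndarray
    feature_scale: np.ndarray
    classes: tuple
    config: MLPConfig


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def _forward(weights, X):
    acts = [X]
    a = X
    for W, b in weights[:-1]:
        a = np.tanh(a @ W + b)
        acts.append(a)
    W, b = weights[-1]
    probs = _softmax(a @ W + b)
    return acts, probs


def _losses(probs: np.ndarray, onehot: np.ndarray) -> tuple:
    eps = 1e-12
    ce = float(-np.mean(np.sum(onehot * np.log(probs + eps), axis=1)))
    mse = float(np.mean((onehot - probs) ** 2))
    return ce, mse


def train_ann(X, y, split, cfg: MLPConfig):
    """Train the network on the split's training rows.

    Returns ``(model, trace)``.  Features are standardised with statistics
    of the training rows; the transform is stored in the model so that
    prediction-time inputs are handled identically.  Fully deterministic
    for a fixed config, data and split.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise InvalidArgumentError("X rows must match label count")
    if X.shape[1] != cfg.input_dim:
        raise InvalidArgumentError(f"X width {X.shape[1]} != cfg.input_dim {cfg.input_dim}")

    classes = tuple(sorted(set(y.tolist())))
    train_idx = np.asarray(split.train, dtype=int)
    if len(set(y[train_idx].tolist())) < 2:
        raise InvalidArgumentError("training set holds fewer than two classes")
    if len(classes) > cfg.output_classes:
        raise InvalidArgumentError("more observed classes than output units")

    class_pos = {c: k for k, c in enumerate(classes)}
    onehot = np.zeros((X.shape[0], cfg.output_classes))
    for i, lab in enumerate(y):
        onehot[i, class_pos[lab]] = 1.0

    mean = X[train_idx].mean(axis=0)
    scale = X[train_idx].std(axis=0)
    if scale.max() > 0 and cfg.scale_floor > 0:
        scale = np.maximum(scale, cfg.scale_floor * scale.max())
    scale[scale == 0] = 1.0
    Z = (X - mean) / scale

    phases = {
        "train": train_idx,
        "validation": np.asarray(split.validation, dtype=int),
        "test": np.asarray(split.test, dtype=int),
    }

    rng = np.random.default_rng(cfg.seed)
    sizes = [cfg.input_dim] + [cfg.hidden_units] * cfg.hidden_layers + [cfg.output_classes]
    weights = []
    for fan_in, fan_out in zip(sizes[:-1], sizes[1:]):
        W = rng.standard_normal((fan_in, fan_out)) / np.sqrt(fan_in)
        weights.append([W, np.zeros(fan_out)])
    velocity = [[np.zeros_like(W), np.zeros_like(b)] for W, b in weights]

    trace = TrainingTrace()
    best_val = np.inf
    best_weights = [[W.copy(), b.copy()] for W, b in weights]
    best_epoch = -1
    since_improve = 0
    stop_reason = "max_epochs"

    Xtr, Ttr = Z[train_idx], onehot[train_idx]
    n_tr = len(train_idx)

    for epoch in range(cfg.max_epochs):
        acts, probs = _forward(weights, Xtr)
        delta = (probs - Ttr) / n_tr
        grads = []
        for layer in range(len(weights) - 1, -1, -1):
            a_prev = acts[layer]
            gW = a_prev.T @ delta
            gb = delta.sum(axis=0)
            grads.append((gW, gb))
            if layer > 0:
                W, _ = weights[layer]
                delta = (delta @ W.T) * (1.0 - acts[layer] ** 2)
        grads.reverse()

        gnorm = float(np.sqrt(sum(float((g**2).sum() + (h**2).sum()) for g, h in grads)))
        trace.gradient_norm.append(gnorm)

        for layer, (gW, gb) in enumerate(grads):
            vW, vb = velocity[layer]
            vW *= cfg.momentum
            vW -= cfg.learning_rate * gW
            vb *= cfg.momentum
            vb -= cfg.learning_rate * gb
            weights[layer][0] += vW
            weights[layer][1] += vb

        for phase, idx in phases.items():
            if idx.size == 0:
                trace.cross_entropy[phase].append(float("nan"))
                trace.mse[phase].append(float("nan"))
                continue
            _, p = _forward(weights, Z[idx])
            ce, mse = _losses(p, onehot[idx])
            trace.cross_entropy[phase].append(ce)
            trace.mse[phase].append(mse)

        val_ce = trace.cross_entropy["validation"][-1]
        if phases["validation"].size == 0:
            val_ce = trace.cross_entropy["train"][-1]
        if val_ce < best_val - 1e-12:
            best_val = val_ce
            best_epoch = epoch
            best_weights = [[W.copy(), b.copy()] for W, b in weights]
            since_improve = 0
        else:
            since_improve += 1
            if since_improve >= cfg.validation_patience:
                stop_reason = "validation_patience"
                break

        if gnorm < cfg.gradient_floor:
            stop_reason = "gradient_floor"
            break

    trace.best_epoch = best_epoch
    trace.stop_reason = stop_reason
    model = ANNModel(
        weights=best_weights,
        feature_mean=mean,
        feature_scale=scale,
        classes=classes,
        config=cfg,
    )
    return model, trace


def predict_proba(model: ANNModel, X) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != model.feature_mean.shape[0]:
        raise InvalidArgumentError("feature width does not match the trained model")
    Z = (X - model.feature_mean) / model.feature_scale
    _, probs = _forward(model.weights, Z)
    return probs[:, : len(model.classes)] / probs[:, : len(model.classes)].sum(
        axis=1, keepdims=True
    )


def predict(model: ANNModel, X) -> np.ndarray:
    probs = predict_proba(model, X)
    return np.asarray(model.classes)[np.argmax(probs, axis=1)]


def evaluate(model: ANNModel, X_test, y_test, classes=None) -> np.ndarray:
    """K x K confusion matrix: rows = true class, columns = predicted."""
    classes = tuple(classes) if classes is not None else model.classes
    y_test = np.asarray(y_test)
    preds = predict(model, X_test)
    if y_test.shape[0] != preds.shape[0]:
        raise InvalidArgumentError("label count does not match prediction count")
    pos = {c: k for k, c in enumerate(classes)}
    cm = np.zeros((len(classes), len(classes)), dtype=int)
    for t, p in zip(y_test, preds):
        cm[pos[t], pos[p]] += 1
    return cm


def _ovr_counts(cm: np.ndarray, k: int) -> tuple:
    tp = cm[k, k]
    fn = cm[k].sum() - tp
    fp = cm[:, k].sum() - tp
    tn = cm.sum() - tp - fn - fp
    return tp, tn, fp, fn


def _pct(num: float, den: float) -> float:
    return 100.0 * num / den if den > 0 else 0.0


def metrics_from_confusion(cm: np.ndarray, classes=None) -> dict:
    """Per-class one-vs-rest percentage metrics plus macro averages.

    For each class (treated as positive against the rest):
    accuracy (TP+TN over all), precision, specificity, sensitivity; and
    ``class_accuracy`` — the diagonal recall shown in per-class rows of
    confusion-matrix figures.  ``average ratio`` rows hold unweighted means.
    """
    cm = np.asarray(cm)
    if cm.ndim != 2 or cm.shape[0] != cm.shape[1] or cm.sum() <= 0:
        raise InvalidArgumentError("confusion matrix must be square and non-empty")
    k_classes = classes if classes is not None else [f"class_{k}" for k in range(cm.shape[0])]
    report = {"per_class": {}, "average_ratio": {}}
    for k, name in enumerate(k_classes):
        tp, tn, fp, fn = _ovr_counts(cm, k)
        report["per_class"][name] = {
            "accuracy": _pct(tp + tn, tp + tn + fp + fn),
            "precision": _pct(tp, tp + fp),
            "specificity": _pct(tn, tn + fp),
            "sensitivity": _pct(tp, tp + fn),
            "class_accuracy": _pct(tp, tp + fn),
        }
    for metric in ("accuracy", "precision", "specificity", "sensitivity", "class_accuracy"):
        report["average_ratio"][metric] = float(
            np.mean([report["per_class"][name][metric] for name in k_classes])
        )
    report["pooled_accuracy"] = _pct(np.trace(cm), cm.sum())
    return report


def roc_auc(scores: np.ndarray, y, classes) -> dict:
    """One-vs-rest ROC AUC per class (percent) and their macro mean.

    Classes absent from ``y`` get ``None`` and are excluded from the macro.
    """
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(y)
    if scores.ndim != 2 or scores.shape[0] != y.shape[0]:
        raise InvalidArgumentError("scores must be N x K aligned with labels")
    if not np.allclose(scores.sum(axis=1), 1.0, atol=1e-6):
        raise InvalidArgumentError("score rows must sum to 1")

    from sklearn.metrics import roc_auc_score

    out = {"per_class": {}, "macro": None}
    vals = []
    for k, name in enumerate(classes):
        pos = (y == name).astype(int)
        if pos.sum() == 0 or pos.sum() == len(pos):
            out["per_class"][name] = None
            continue
        auc = 100.0 * float(roc_auc_score(pos, scores[:, k]))
        out["per_class"][name] = auc
        vals.append(auc)
    if vals:
        out["macro"] = float(np.mean(vals))
    return out


def error_histogram(targets, outputs, phase_tags, bins: int = 20) -> dict:
    """Per-phase histogram of (target - output) over all output units.

    Bin edges are shared across phases and span the observed error range.
    Returns ``{"bin_edges": ..., "counts": {phase: ...}}``.
    """
    targets = np.asarray(targets, dtype=float)
    outputs = np.asarray(outputs, dtype=float)
    phase_tags = np.asarray(phase_tags)
    if targets.size == 0 or targets.shape != outputs.shape:
        raise InvalidArgumentError("targets/outputs must be non-empty and aligned")
    if phase_tags.shape[0] != targets.shape[0]:
        raise InvalidArgumentError("one phase tag per sample is required")

    errors = targets - outputs
    lo, hi = float(errors.min()), float(errors.max())
    if lo == hi:
        lo, hi = lo - 0.5, hi + 0.5
    edges = np.linspace(lo, hi, bins + 1)
    counts = {}
    for phase in np.unique(phase_tags):
        e = errors[phase_tags == phase].ravel()
        counts[str(phase)], _ = np.histogram(e, bins=edges)
    return {"bin_edges": edges, "counts": counts}
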