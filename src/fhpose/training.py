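"""Training protocol, data splitting, dropout grid search, and evaluation.

Training follows the reference protocol: Adam on categorical cross-entropy
with minibatches of 16, a stratified 70/15/15 train/validation/test split,
and dropout-rate selection by grid search on validation accuracy.  Epoch
count is capped at 200 with early stopping (patience 20 on validation loss);
the weights with the best validation loss are restored.

Evaluation metrics are computed from the confusion matrix: per-class
precision and recall, per-class F1 (harmonic mean of the two), overall
accuracy, and the macro F1 — the unweighted mean of per-class F1 scores.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import ShapeError, TrainingError, ValidationError
from .preprocess import normalize_pose
from .skeleton import upper_body_subset
from .synthetic import PoseDataset

_CE_EPS = 1e-12  # clamp inside the log of cross-entropy


@dataclass(frozen=True)
class TrainConfig:
    batch_size: int = 16
    learning_rate: float = 1e-3
    optimizer: str = "adam"
    loss: str = "categorical_cross_entropy"
    max_epochs: int = 200
    patience: int = 20
    dropout_grid: tuple[float, ...] = (0.0, 0.1, 0.2, 0.3, 0.5)
    split_ratios: tuple[float, float, float] = (0.70, 0.15, 0.15)
    seed: int = 0

    def validate(self):
        if self.batch_size < 1:
            raise ValidationError("batch_size must be at least 1")
        if abs(sum(self.split_ratios) - 1.0) > 1e-9:
            raise ValidationError("split ratios must sum to 1")
        if self.optimizer != "adam":
            raise ValidationError("only the Adam optimizer is supported")


# ---------------------------------------------------------------------------
# Splitting
# ---------------------------------------------------------------------------

def _largest_remainder(n: int, ratios) -> np.ndarray:
    quotas = np.asarray(ratios, dtype=float) * n
    base = np.floor(quotas).astype(int)
    remainder = quotas - base
    deficit = n - base.sum()
    # Ties broken toward the earlier split (stable sort on -remainder).
    order = np.argsort(-remainder, kind="stable")
    for k in order[:deficit]:
        base[k] += 1
    return base


def stratified_split_indices(labels, ratios=(0.70, 0.15, 0.15), seed: int = 0):
    """Disjoint, exhaustive, stratified index sets for train/val/test.

    Overall split sizes follow largest-remainder rounding of the ratios;
    per-class quotas are largest-remainder rounded too, then adjusted to the
    overall sizes, preferring adjustments that keep every class represented
    in every split when that is feasible.
    """
    labels = np.asarray(labels)
    n = len(labels)
    ratios = tuple(float(r) for r in ratios)
    if abs(sum(ratios) - 1.0) > 1e-9:
        raise ValidationError("split ratios must sum to 1")
    if n < 10:
        raise ValidationError("splitting requires at least 10 samples")

    sizes = _largest_remainder(n, ratios)
    classes = np.unique(labels)
    quota = {c: _largest_remainder(int(np.sum(labels == c)), ratios) for c in classes}

    def col_sums():
        return np.sum([quota[c] for c in classes], axis=0)

    # Rebalance per-class quotas so the split totals match the global sizes.
    for _ in range(n):
        cols = col_sums()
        if np.array_equal(cols, sizes):
            break
        s = int(np.argmax(cols - sizes))   # most over-full split
        t = int(np.argmin(cols - sizes))   # most under-full split
        candidates = [c for c in classes if quota[c][s] > 0]
        # Prefer a class that stays present in split s after the move.
        keep = [c for c in candidates if quota[c][s] > 1]
        pool = keep or candidates
        c = max(pool, key=lambda c: quota[c][s])
        quota[c][s] -= 1
        quota[c][t] += 1

    rng = np.random.default_rng(seed)
    parts = [[], [], []]
    for c in classes:
        idx = np.flatnonzero(labels == c)
        rng.shuffle(idx)
        start = 0
        for split, count in enumerate(quota[c]):
            parts[split].extend(idx[start:start + count])
            start += count
    return tuple(np.array(sorted(p), dtype=int) for p in parts)


def split_dataset(dataset: PoseDataset, ratios=(0.70, 0.15, 0.15), seed: int = 0):
    """Split a :class:`PoseDataset` into stratified train/val/test subsets."""
    tr, va, te = stratified_split_indices(dataset.labels, ratios, seed)
    return dataset.subset(tr), dataset.subset(va), dataset.subset(te)


# ---------------------------------------------------------------------------
# Loss and optimizer
# ---------------------------------------------------------------------------

def one_hot(labels, n_classes: int = 2) -> np.ndarray:
    labels = np.asarray(labels, dtype=int)
    out = np.zeros((labels.size, n_classes))
    out[np.arange(labels.size), labels.ravel()] = 1.0
    return out


def cross_entropy(probs, target_onehot) -> float:
    """Categorical cross-entropy, natural log, epsilon-clamped at 1e-12.

    For a batch (2-D inputs) the mean per-sample loss is returned.
    """
    p = np.atleast_2d(np.asarray(probs, dtype=float))
    t = np.atleast_2d(np.asarray(target_onehot, dtype=float))
    if p.shape != t.shape:
        raise ShapeError("probability and target shapes differ")
    if not np.allclose(p.sum(axis=1), 1.0, atol=1e-6):
        raise ValidationError("probabilities must sum to 1")
    if not np.allclose(t.sum(axis=1), 1.0) or np.any((t != 0) & (t != 1)):
        raise ValidationError("targets must be one-hot encoded")
    per_sample = -np.log(np.clip(np.sum(p * t, axis=1), _CE_EPS, None))
    return float(per_sample.mean())


class Adam:
    """Standard Adam update on a dict of parameter arrays."""

    def __init__(self, params, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params, grads):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for k, g in grads.items():
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            m_hat = self.m[k] / (1 - b1 ** self.t)
            v_hat = self.v[k] / (1 - b2 ** self.t)
            params[k] -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)


# ---------------------------------------------------------------------------
# Model-input preparation
# ---------------------------------------------------------------------------

def poses_to_model_inputs(poses, kind: str = "gcn", align_yaw: bool = True) -> np.ndarray:
    """Normalize 17-joint poses and shape them for a model.

    ``kind='gcn'`` returns (n, 13, 3) node features; ``kind='ffnn'`` returns
    the flattened (n, 39) matrix (joint-major order).
    """
    X = np.stack([
        upper_body_subset(normalize_pose(p, align_yaw=align_yaw)[0]) for p in poses
    ])
    if kind == "gcn":
        return X
    if kind == "ffnn":
        return X.reshape(len(X), -1)
    raise ValidationError(f"unknown model kind {kind!r}")


# ---------------------------------------------------------------------------
# Training loop
# ---------------------------------------------------------------------------

def train_model(model, train_data, val_data, config: TrainConfig | None = None):
    """Minibatch Adam training with early stopping; returns (params, history).

    ``train_data`` / ``val_data`` are ``(X, labels)`` pairs already shaped
    for the model.  The model is left holding the weights with the best
    validation loss.  Deterministic under a fixed config seed (one thread).
    """
    config = config or TrainConfig()
    config.validate()
    X_tr, y_tr = train_data
    X_va, y_va = val_data
    if len(y_tr) == 0 or len(y_va) == 0:
        raise ValidationError("training and validation splits must be non-empty")
    n_classes = model.config.n_classes
    Y_tr = one_hot(y_tr, n_classes)
    Y_va = one_hot(y_va, n_classes)

    rng = np.random.default_rng(config.seed)
    opt = Adam(model.params, lr=config.learning_rate)
    history = {"train_loss": [], "train_acc": [], "val_loss": [], "val_acc": []}
    best_loss, best_params, best_epoch = np.inf, model.get_params(), -1

    n = len(y_tr)
    for epoch in range(config.max_epochs):
        order = rng.permutation(n)
        epoch_loss, seen = 0.0, 0
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            loss, grads = model.loss_and_grads(X_tr[idx], Y_tr[idx], rng=rng)
            if not np.isfinite(loss):
                raise TrainingError(f"loss diverged to a non-finite value at epoch {epoch}")
            opt.step(model.params, grads)
            epoch_loss += loss * len(idx)
            seen += len(idx)
        probs_tr = model.forward(X_tr)
        probs_va = model.forward(X_va)
        val_loss = cross_entropy(probs_va, Y_va)
        history["train_loss"].append(epoch_loss / seen)
        history["train_acc"].append(float(np.mean(probs_tr.argmax(1) == np.asarray(y_tr))))
        history["val_loss"].append(val_loss)
        history["val_acc"].append(float(np.mean(probs_va.argmax(1) == np.asarray(y_va))))
        if val_loss < best_loss - 1e-12:
            best_loss, best_params, best_epoch = val_loss, model.get_params(), epoch
        if epoch - best_epoch >= config.patience:
            break

    model.set_params(best_params)
    history["best_epoch"] = best_epoch
    return best_params, history


def grid_search_dropout(model_factory, train_data, val_data,
                        config: TrainConfig | None = None):
    """Select the dropout rate maximizing validation accuracy.

    ``model_factory(dropout_rate, seed)`` must return a fresh model.  Returns
    ``(best_rate, table)`` where the table is one row per grid value.  Ties
    are broken toward the lowest rate.
    """
    config = config or TrainConfig()
    config.validate()
    if len(config.dropout_grid) == 0:
        raise ValidationError("dropout grid must be non-empty")
    table = []
    for rate in config.dropout_grid:
        model = model_factory(rate, config.seed)
        _, history = train_model(model, train_data, val_data, config)
        probs = model.forward(val_data[0])
        val_acc = float(np.mean(probs.argmax(1) == np.asarray(val_data[1])))
        table.append({
            "dropout_rate": float(rate),
            "val_accuracy": val_acc,
            "val_loss": float(min(history["val_loss"])),
            "epochs_run": len(history["val_loss"]),
        })
    best = max(table, key=lambda row: (row["val_accuracy"], -row["dropout_rate"]))
    return best["dropout_rate"], table


# ---------------------------------------------------------------------------
# Evaluation
# ---------------------------------------------------------------------------

@dataclass
class EvalReport:
    """Confusion matrix and derived metrics for one model on one split."""

    confusion_matrix: np.ndarray            # [true, predicted] counts
    precision: np.ndarray                   # per class, NaN when undefined
    recall: np.ndarray
    f1: np.ndarray
    accuracy: float
    macro_f1: float
    undefined: tuple[str, ...] = ()         # which metrics were undefined

    def to_json(self) -> str:
        def clean(a):
            return [None if not np.isfinite(v) else float(v) for v in np.ravel(a)]
        return json.dumps({
            "confusion_matrix": self.confusion_matrix.astype(int).tolist(),
            "precision": clean(self.precision),
            "recall": clean(self.recall),
            "f1": clean(self.f1),
            "accuracy": self.accuracy,
            "macro_f1": None if not np.isfinite(self.macro_f1) else self.macro_f1,
            "undefined": list(self.undefined),
        })

    def to_text(self) -> str:
        """Percent-scale table in the conventional row order."""
        def pct(v):
            return "undefined" if not np.isfinite(v) else f"{100 * v:.2f}"
        lines = []
        for c in range(len(self.precision)):
            lines.append(f"Precision (class {c})   {pct(self.precision[c])}")
            lines.append(f"Recall (class {c})      {pct(self.recall[c])}")
            lines.append(f"F1-score (class {c})    {pct(self.f1[c])}")
        lines.append(f"Overall accuracy      {pct(self.accuracy)}")
        lines.append(f"F1-score (macro)      {pct(self.macro_f1)}")
        return "\n".join(lines)


def report_from_predictions(y_true, y_pred, n_classes: int = 2) -> EvalReport:
    """Build an :class:`EvalReport` from label vectors.

    A metric whose denominator is zero (class absent from the truth or the
    predictions) is reported as NaN and named in ``undefined`` rather than
    silently set to zero.
    """
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if y_true.shape != y_pred.shape or y_true.size == 0:
        raise ValidationError("prediction and truth vectors must be non-empty and equal length")
    C = np.zeros((n_classes, n_classes))
    for t, p in zip(y_true, y_pred):
        C[t, p] += 1
    precision = np.full(n_classes, np.nan)
    recall = np.full(n_classes, np.nan)
    f1 = np.full(n_classes, np.nan)
    undefined = []
    for c in range(n_classes):
        tp = C[c, c]
        pred_c = C[:, c].sum()
        true_c = C[c, :].sum()
        if pred_c > 0:
            precision[c] = tp / pred_c
        else:
            undefined.append(f"precision_class{c}")
        if true_c > 0:
            recall[c] = tp / true_c
        else:
            undefined.append(f"recall_class{c}")
        if np.isfinite(precision[c]) and np.isfinite(recall[c]) and precision[c] + recall[c] > 0:
            f1[c] = 2 * precision[c] * recall[c] / (precision[c] + recall[c])
        else:
            undefined.append(f"f1_class{c}")
    accuracy = float(np.trace(C) / C.sum())
    macro = float(np.mean(f1)) if np.all(np.isfinite(f1)) else float("nan")
    if not np.isfinite(macro):
        undefined.append("macro_f1")
    return EvalReport(C, precision, recall, f1, accuracy, macro, tuple(undefined))


def evaluate(model, X, y_true, n_classes: int | None = None) -> EvalReport:
    """Evaluate a model on shaped inputs; argmax ties resolve to class 0."""
    if len(np.asarray(y_true)) == 0:
        raise ValidationError("test set must be non-empty")
    probs = model.forward(X)
    y_pred = np.atleast_2d(probs).argmax(axis=1)   # np.argmax: first max wins
    return report_from_predictions(y_true, y_pred,
                                   n_classes or model.config.n_classes)


def macro_f1(per_class_f1) -> float:
    """Unweighted (arithmetic) mean of per-class F1 scores."""
    scores = np.asarray(per_class_f1, dtype=float)
    if scores.size == 0:
        raise ValidationError("macro F1 requires at least one class score")
    return float(scores.mean())


def history_to_csv(history, path) -> None:
    import pandas as pd
    keys = ["train_loss", "train_acc", "val_loss", "val_acc"]
    pd.DataFrame({k: history[k] for k in keys}).to_csv(path, index_label="epoch")
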