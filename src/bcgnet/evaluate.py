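"""Splitting, training orchestration, cross-validation and diagnostic metrics.

The hold-out protocol is an 80/10/10 train/validation/test split; ten-fold
cross-validation re-initializes a fresh model per fold, trains on the other
nine folds (carving out 1/9 of them as validation) and tests on the held-out
fold.  HPT is the positive class throughout.  Splitting defaults to the
epoch level, matching the segment-count bookkeeping of the protocol it
follows; subject-level grouping is available (``unit="subject"``) and is the
safer choice for real data because epoch-level splits leak subject identity
across partitions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .cnn_model import CLASSES, CNNModel, Hyperparams, build_model, default_modelspec

__all__ = [
    "SplitSpec",
    "ConfusionCounts",
    "Metrics",
    "split_holdout",
    "train",
    "confusion_matrix",
    "metrics_from_confusion",
    "f1_score",
    "kfold_crossval",
    "images_to_inputs",
    "labels_to_onehot",
]

POSITIVE = "HPT"
NEGATIVE = "HC"


@dataclass(frozen=True)
class SplitSpec:
    fractions: tuple[float, float, float] = (0.8, 0.1, 0.1)
    unit: str = "epoch"  # or "subject"
    seed: int = 0


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(self.tp + other.tp, self.fp + other.fp,
                               self.tn + other.tn, self.fn + other.fn)


@dataclass(frozen=True)
class Metrics:
    accuracy: float
    sensitivity: float
    specificity: float
    precision: float
    f1: float


def images_to_inputs(images: np.ndarray) -> np.ndarray:
    """Scale 8-bit images to [0, 1] floats shaped (n, side, side, 1)."""
    x = np.asarray(images, dtype=float) / 255.0
    if x.ndim == 3:
        x = x[..., None]
    return x


def labels_to_onehot(labels: Sequence[str]) -> np.ndarray:
    idx = np.array([CLASSES.index(l) for l in labels])
    out = np.zeros((len(idx), len(CLASSES)))
    out[np.arange(len(idx)), idx] = 1.0
    return out


def split_holdout(
    labels_or_n,
    spec: SplitSpec = SplitSpec(),
    subject_ids: Sequence[str] | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Disjoint, exhaustive train/val/test index sets via a seeded shuffle.

    ``labels_or_n`` may be an integer dataset size or a label sequence (only
    its length is used).  With ``spec.unit == "subject"`` the shuffle and
    the fractions apply to unique subject ids and every epoch follows its
    subject into a single partition.
    """
    fr = spec.fractions
    if abs(sum(fr) - 1.0) > 1e-9 or any(f <= 0 for f in fr):
        raise ValueError("fractions must be positive and sum to 1")
    n = labels_or_n if isinstance(labels_or_n, (int, np.integer)) else len(labels_or_n)
    if n == 0:
        raise ValueError("dataset is empty")
    rng = np.random.default_rng(spec.seed)

    if spec.unit == "subject":
        if subject_ids is None:
            raise ValueError("subject-level split requires subject_ids")
        subjects = sorted(set(subject_ids))
        order = rng.permutation(len(subjects))
        n_tr = int(round(fr[0] * len(subjects)))
        n_val = int(round(fr[1] * len(subjects)))
        tr_s = {subjects[i] for i in order[:n_tr]}
        val_s = {subjects[i] for i in order[n_tr : n_tr + n_val]}
        sid = np.asarray(subject_ids)
        idx = np.arange(n)
        train_idx = idx[np.isin(sid, list(tr_s))]
        val_idx = idx[np.isin(sid, list(val_s))]
        test_idx = idx[~np.isin(sid, list(tr_s | val_s))]
        return train_idx, val_idx, test_idx

    order = rng.permutation(n)
    n_tr = int(round(fr[0] * n))
    n_val = int(round(fr[1] * n))
    return order[:n_tr], order[n_tr : n_tr + n_val], order[n_tr + n_val :]


def train(
    model: CNNModel,
    x_train: np.ndarray,
    y_train: np.ndarray,
    x_val: np.ndarray | None,
    y_val: np.ndarray | None,
    hp: Hyperparams | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Run ``hp.epochs`` training epochs; returns one history row per epoch.

    Batches of ``hp.batch_size`` are drawn after a per-epoch seeded shuffle;
    the Adam learning rate follows ``lr / (1 + decay * epochs_completed)``.
    """
    hp = hp or model.hp
    if len(x_train) == 0:
        raise ValueError("empty training set")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 2]))
    rows = []
    for epoch in range(hp.epochs):
        model.optimizer.epochs_completed = epoch
        order = rng.permutation(len(x_train))
        losses, accs = [], []
        for start in range(0, len(order), hp.batch_size):
            sel = order[start : start + hp.batch_size]
            out = model.train_step(x_train[sel], y_train[sel])
            losses.append(out["loss"])
            accs.append(out["accuracy"])
        row = {
            "epoch": epoch,
            "train_loss": float(np.mean(losses)),
            "train_accuracy": float(np.mean(accs)),
        }
        if x_val is not None and len(x_val):
            val = model.evaluate_loss(x_val, y_val)
            row["val_loss"] = val["loss"]
            row["val_accuracy"] = val["accuracy"]
        rows.append(row)
    return pd.DataFrame(rows)


def confusion_matrix(y_true: Sequence[str], y_pred: Sequence[str]) -> ConfusionCounts:
    """Count tp/fp/tn/fn with HPT as the positive class."""
    if len(y_true) != len(y_pred):
        raise ValueError("y_true and y_pred must have equal length")
    tp = fp = tn = fn = 0
    for t, p in zip(y_true, y_pred):
        if t not in CLASSES or p not in CLASSES:
            raise ValueError(f"unknown label in ({t!r}, {p!r})")
        if t == POSITIVE:
            tp += p == POSITIVE
            fn += p == NEGATIVE
        else:
            tn += p == NEGATIVE
            fp += p == POSITIVE
    return ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn)


def _safe_ratio(num: float, den: float, name: str) -> float:
    if den == 0:
        warnings.warn(f"{name} undefined (zero denominator); reporting NaN",
                      RuntimeWarning, stacklevel=3)
        return float("nan")
    return num / den


def f1_score(precision: float, sensitivity: float) -> float:
    """Harmonic mean 2 P R / (P + R); NaN when both are zero."""
    if precision + sensitivity == 0:
        return float("nan")
    return 2.0 * precision * sensitivity / (precision + sensitivity)


def metrics_from_confusion(c: ConfusionCounts) -> Metrics:
    """Accuracy, sensitivity, specificity, precision and F1 from counts.

    Undefined ratios (zero denominators) are reported as NaN with a
    warning, never silently as 0.
    """
    if c.n == 0:
        raise ValueError("empty confusion matrix")
    acc = (c.tp + c.tn) / c.n
    sens = _safe_ratio(c.tp, c.tp + c.fn, "sensitivity")
    spec = _safe_ratio(c.tn, c.tn + c.fp, "specificity")
    prec = _safe_ratio(c.tp, c.tp + c.fp, "precision")
    if np.isnan(prec) or np.isnan(sens) or prec + sens == 0:
        warnings.warn("f1 undefined; reporting NaN", RuntimeWarning, stacklevel=2)
        f1 = float("nan")
    else:
        f1 = f1_score(prec, sens)
    return Metrics(accuracy=acc, sensitivity=sens, specificity=spec,
                   precision=prec, f1=f1)


@dataclass
class HoldoutResult:
    confusion: ConfusionCounts
    metrics: Metrics
    history: pd.DataFrame
    indices: tuple[np.ndarray, np.ndarray, np.ndarray]
    model: CNNModel | None = None


def run_holdout(
    images: np.ndarray,
    labels: Sequence[str],
    hp: Hyperparams = Hyperparams(),
    split: SplitSpec = SplitSpec(),
    seed: int = 0,
    subject_ids: Sequence[str] | None = None,
    keep_model: bool = False,
) -> HoldoutResult:
    """Full hold-out protocol: split, train, score the test partition."""
    labels = list(labels)
    tr, va, te = split_holdout(labels, split, subject_ids=subject_ids)
    x = images_to_inputs(images)
    y = labels_to_onehot(labels)
    model = build_model(default_modelspec(l1=hp.l1), hp, seed=seed)
    history = train(model, x[tr], y[tr], x[va], y[va], hp, seed=seed)
    pred = model.predict_labels(x[te])
    truth = [labels[i] for i in te]
    conf = confusion_matrix(truth, pred)
    return HoldoutResult(confusion=conf, metrics=metrics_from_confusion(conf),
                         history=history, indices=(tr, va, te),
                         model=model if keep_model else None)


@dataclass
class CrossValResult:
    fold_metrics: list[Metrics]
    fold_confusions: list[ConfusionCounts]
    mean: dict = field(default_factory=dict)
    std: dict = field(default_factory=dict)
    pooled: ConfusionCounts | None = None

    def frame(self) -> pd.DataFrame:
        rows = []
        for i, (m, c) in enumerate(zip(self.fold_metrics, self.fold_confusions)):
            rows.append({"fold": i, "tp": c.tp, "fp": c.fp, "tn": c.tn, "fn": c.fn,
                         "accuracy": m.accuracy, "sensitivity": m.sensitivity,
                         "specificity": m.specificity, "precision": m.precision,
                         "f1": m.f1})
        return pd.DataFrame(rows)


def kfold_crossval(
    images: np.ndarray,
    labels: Sequence[str],
    k: int = 10,
    hp: Hyperparams = Hyperparams(),
    seed: int = 0,
) -> CrossValResult:
    """Seeded k-fold CV with a freshly initialized model per fold.

    Folds are near-equal (sizes differ by at most 1) and disjoint; each
    instance is tested exactly once, so the pooled confusion counts sum to
    the dataset size.  Within each training portion 1/9 is carved out as a
    validation set.
    """
    from sklearn.model_selection import KFold

    labels = list(labels)
    n = len(labels)
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > n:
        raise ValueError(f"k={k} exceeds dataset size {n}")
    x = images_to_inputs(images)
    y = labels_to_onehot(labels)
    kf = KFold(n_splits=k, shuffle=True, random_state=seed)
    fold_metrics, fold_confusions = [], []
    for fold, (train_idx, test_idx) in enumerate(kf.split(np.arange(n))):
        rng = np.random.default_rng(np.random.SeedSequence([seed, 3, fold]))
        order = rng.permutation(len(train_idx))
        n_val = max(1, len(train_idx) // 9)
        val_idx = train_idx[order[:n_val]]
        fit_idx = train_idx[order[n_val:]]
        model = build_model(default_modelspec(l1=hp.l1), hp, seed=seed + fold)
        train(model, x[fit_idx], y[fit_idx], x[val_idx], y[val_idx], hp,
              seed=seed + fold)
        pred = model.predict_labels(x[test_idx])
        truth = [labels[i] for i in test_idx]
        conf = confusion_matrix(truth, pred)
        fold_confusions.append(conf)
        fold_metrics.append(metrics_from_confusion(conf))
    pooled = fold_confusions[0]
    for c in fold_confusions[1:]:
        pooled = pooled + c
    names = ("accuracy", "sensitivity", "specificity", "precision", "f1")
    mean = {nm: float(np.mean([getattr(m, nm) for m in fold_metrics])) for nm in names}
    std = {nm: float(np.std([getattr(m, nm) for m in fold_metrics])) for nm in names}
    return CrossValResult(fold_metrics=fold_metrics, fold_confusions=fold_confusions,
                          mean=mean, std=std, pooled=pooled)
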