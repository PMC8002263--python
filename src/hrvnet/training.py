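"""Subject-wise cross-validation, the optimisation protocol, and metrics.

Evaluation is inter-patient: fold assignment is by subject, so no
individual contributes segments to both the training and the test side of
any fold.  A small inner validation subset of training subjects drives the
reduce-on-plateau learning-rate schedule (using the test fold for
scheduling would leak).  Optimisation follows the fixed protocol: Adam,
mean-squared-error loss against {0, 1} labels, batch size 16, initial
learning rate 1e-4 cut by 10× after 5 epochs without validation-loss
improvement.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from sklearn.metrics import auc as _sk_auc
from sklearn.metrics import roc_curve as _sk_roc_curve

from .autograd import Tensor
from .model import NetworkConfig, UNetPlusPlus1D, mse_loss, mse_loss_tensor
from .preprocessing import RRSegment, segments_to_arrays


@dataclass(frozen=True)
class TrainConfig:
    """Optimisation hyperparameters (protocol-fixed defaults)."""

    batch_size: int = 16
    epochs: int = 70
    initial_lr: float = 1e-4
    plateau_factor: float = 0.1
    plateau_patience: int = 5
    val_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.batch_size < 1 or self.epochs < 0 or self.initial_lr <= 0:
            raise ValueError("invalid training configuration")
        if not 0.0 < self.plateau_factor < 1.0:
            raise ValueError("plateau_factor must lie in (0, 1)")
        if self.plateau_patience < 1:
            raise ValueError("plateau_patience must be ≥ 1")

    def to_dict(self) -> dict:
        return {
            "batch_size": self.batch_size,
            "epochs": self.epochs,
            "initial_lr": self.initial_lr,
            "plateau_factor": self.plateau_factor,
            "plateau_patience": self.plateau_patience,
            "val_fraction": self.val_fraction,
            "seed": self.seed,
        }


@dataclass(frozen=True)
class Fold:
    train: frozenset[str]
    val: frozenset[str]
    test: frozenset[str]


@dataclass(frozen=True)
class FoldSplit:
    """A subject-level partition into k parts plus the per-fold role split."""

    parts: tuple[frozenset[str], ...]
    folds: tuple[Fold, ...]


class Adam:
    """Adam optimizer over a fixed parameter list; ``lr`` is mutable."""

    def __init__(self, params: Sequence[Tensor], lr: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1 ** self.t
        b2t = 1.0 - self.beta2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            m *= self.beta1
            m += (1 - self.beta1) * p.grad
            v *= self.beta2
            v += (1 - self.beta2) * p.grad ** 2
            p.data -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()


class ReduceLROnPlateau:
    """Cut the learning rate by ``factor`` after ``patience`` epochs without
    a new best validation loss; the patience counter resets on each cut."""

    def __init__(self, lr: float, factor: float = 0.1, patience: int = 5):
        self.lr = lr
        self.factor = factor
        self.patience = patience
        self.best = np.inf
        self.since_improvement = 0

    def step(self, val_loss: float) -> float:
        if val_loss < self.best:
            self.best = val_loss
            self.since_improvement = 0
        else:
            self.since_improvement += 1
            if self.since_improvement >= self.patience:
                self.lr *= self.factor
                self.since_improvement = 0
        return self.lr


def lr_schedule_step(
    history: Sequence[float], current_lr: float, cfg: TrainConfig
) -> float:
    """Replay a validation-loss history through the plateau rule.

    ``current_lr`` is the rate in force before the first recorded epoch.
    """
    if len(history) == 0:
        raise ValueError("validation-loss history is empty")
    sched = ReduceLROnPlateau(current_lr, cfg.plateau_factor, cfg.plateau_patience)
    for loss in history:
        sched.step(loss)
    return sched.lr


def subject_wise_kfold(
    subject_ids: Sequence[str],
    k: int = 10,
    seed: int = 0,
    labels: Mapping[str, int] | None = None,
    val_fraction: float = 0.1,
) -> FoldSplit:
    """Partition subjects into k near-equal parts by seeded permutation.

    Part sizes differ by at most one.  When ``labels`` are given the
    permutation is stratified: subjects are permuted within each class and
    dealt round-robin, so every part is as class-balanced as arithmetic
    allows (and sizes still spread ≤ 1).  For fold f, part f is the test
    set; a ``val_fraction`` share of the remaining subjects (at least one,
    and when ``labels`` are given at least one per class where possible)
    forms the inner validation set; the rest train.
    """
    subjects = list(subject_ids)
    if len(set(subjects)) != len(subjects):
        raise ValueError("duplicate subject ids")
    if len(subjects) < k:
        raise ValueError(f"{len(subjects)} subjects cannot fill {k} folds")
    if k < 2:
        raise ValueError("k must be ≥ 2")
    rng = np.random.default_rng(seed)
    if labels is None:
        perm = [subjects[i] for i in rng.permutation(len(subjects))]
    else:
        perm = []
        for cls in sorted({labels[s] for s in subjects}):
            members = [s for s in subjects if labels[s] == cls]
            perm.extend(members[i] for i in rng.permutation(len(members)))
    # deal the (possibly class-ordered) stream round-robin across parts
    part_lists: list[list[str]] = [[] for _ in range(k)]
    for pos, s in enumerate(perm):
        part_lists[pos % k].append(s)
    parts: list[frozenset[str]] = [frozenset(p) for p in part_lists]
    folds: list[Fold] = []
    for f in range(k):
        test = parts[f]
        rest = [s for s in perm if s not in test]
        n_val = max(1, round(val_fraction * len(rest)))
        val = list(rest[:n_val])
        if labels is not None:
            # ensure each class present in rest is represented in val
            for cls in sorted({labels[s] for s in rest}):
                if not any(labels[s] == cls for s in val):
                    for s in rest:
                        if labels[s] == cls and s not in val:
                            val.append(s)
                            break
        train_list = [s for s in rest if s not in set(val)]
        if labels is not None:
            # the training side must keep every class; shrink val if needed
            for cls in sorted({labels[s] for s in rest}):
                if not any(labels[s] == cls for s in train_list):
                    mover = next(s for s in val if labels[s] == cls)
                    val.remove(mover)
                    train_list.append(mover)
        if not train_list:
            train_list, val = val, []
        folds.append(Fold(train=frozenset(train_list), val=frozenset(val),
                          test=test))
    return FoldSplit(parts=tuple(parts), folds=tuple(folds))


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
        return ConfusionCounts(
            self.tp + other.tp, self.fp + other.fp,
            self.tn + other.tn, self.fn + other.fn,
        )


def confusion_counts(
    labels: Sequence[int], scores: Sequence[float], threshold: float = 0.5
) -> ConfusionCounts:
    """Count TP/FP/TN/FN with score ≥ threshold ⇒ predicted CHF-positive."""
    y = np.asarray(labels)
    p = np.asarray(scores, dtype=np.float64)
    if y.size == 0:
        raise ValueError("confusion_counts requires at least one sample")
    if y.shape != p.shape:
        raise ValueError("labels and scores differ in length")
    if not np.isin(y, (0, 1)).all():
        raise ValueError("labels must be binary")
    pred = p >= threshold
    pos = y == 1
    return ConfusionCounts(
        tp=int(np.sum(pred & pos)),
        fp=int(np.sum(pred & ~pos)),
        tn=int(np.sum(~pred & ~pos)),
        fn=int(np.sum(~pred & pos)),
    )


def compute_metrics(cc: ConfusionCounts) -> dict[str, float]:
    """Accuracy, recall, precision and F1 from confusion counts.

    Degenerate denominators (no predicted or no actual positives) yield 0
    for the affected metric and for F1.
    """
    if cc.n == 0:
        raise ValueError("empty confusion counts")
    accuracy = (cc.tp + cc.tn) / cc.n
    recall = cc.tp / (cc.tp + cc.fn) if cc.tp + cc.fn else 0.0
    precision = cc.tp / (cc.tp + cc.fp) if cc.tp + cc.fp else 0.0
    f1 = (
        2 * precision * recall / (precision + recall)
        if precision + recall
        else 0.0
    )
    return {
        "accuracy": accuracy,
        "recall": recall,
        "precision": precision,
        "f1": f1,
    }


def roc_auc(
    labels: Sequence[int], scores: Sequence[float]
) -> tuple[np.ndarray, np.ndarray, float]:
    """ROC curve (FPR, TPR over the full threshold sweep) and trapezoidal AUC."""
    y = np.asarray(labels)
    p = np.asarray(scores, dtype=np.float64)
    if len(set(y.tolist())) < 2:
        raise ValueError("roc_auc requires both classes present")
    fpr, tpr, _ = _sk_roc_curve(y, p, drop_intermediate=False)
    return fpr, tpr, float(_sk_auc(fpr, tpr))


@dataclass
class FoldResult:
    fold_index: int
    confusion: ConfusionCounts
    metrics: dict[str, float]
    roc: tuple[np.ndarray, np.ndarray]
    auc: float
    curves: dict[str, list[float]]
    labels: np.ndarray
    scores: np.ndarray
    test_subjects: frozenset[str]
    model: "UNetPlusPlus1D | None" = None


@dataclass
class EvalReport:
    """Per-fold and pooled confusion counts, metrics, ROC and AUC."""

    folds: list[FoldResult]
    pooled_confusion: ConfusionCounts
    pooled_metrics: dict[str, float]
    pooled_roc: tuple[np.ndarray, np.ndarray]
    pooled_auc: float

    def metric_summary(self) -> dict[str, tuple[float, float]]:
        """Mean ± standard deviation of each metric across folds."""
        out: dict[str, tuple[float, float]] = {}
        for name in ("accuracy", "recall", "precision", "f1"):
            vals = np.array([f.metrics[name] for f in self.folds])
            out[name] = (float(vals.mean()), float(vals.std()))
        aucs = [f.auc for f in self.folds]
        out["auc"] = (float(np.nanmean(aucs)), float(np.nanstd(aucs)))
        return out


def _segments_by_subject(
    segments: Sequence[RRSegment], subjects: frozenset[str]
) -> list[RRSegment]:
    return [s for s in segments if s.subject_id in subjects]


def _epoch_passes(
    model: UNetPlusPlus1D, x: np.ndarray, y: np.ndarray
) -> tuple[float, float]:
    scores = model.predict(x)
    return mse_loss(y, scores), float(np.mean((scores >= 0.5) == (y == 1)))


def train_fold(
    train_segments: Sequence[RRSegment],
    val_segments: Sequence[RRSegment],
    net_cfg: NetworkConfig | None = None,
    train_cfg: TrainConfig | None = None,
) -> tuple[UNetPlusPlus1D, dict[str, list[float]]]:
    """Train one model on one fold; fully reproducible from the seed.

    Returns the trained model and per-epoch train/validation loss and
    accuracy curves.
    """
    net_cfg = net_cfg or NetworkConfig()
    train_cfg = train_cfg or TrainConfig()
    x_train, y_train = segments_to_arrays(train_segments)
    if len(set(y_train.tolist())) < 2:
        raise ValueError("training set must contain both classes")
    x_val, y_val = (
        segments_to_arrays(val_segments) if len(val_segments) else (None, None)
    )
    model = UNetPlusPlus1D(net_cfg, seed=train_cfg.seed)
    optim = Adam(model.parameters(), lr=train_cfg.initial_lr)
    sched = ReduceLROnPlateau(
        train_cfg.initial_lr, train_cfg.plateau_factor, train_cfg.plateau_patience
    )
    rng = np.random.default_rng(train_cfg.seed)
    curves: dict[str, list[float]] = {
        "train_loss": [], "train_acc": [], "val_loss": [], "val_acc": [],
        "lr": [],
    }
    n = len(y_train)
    for _ in range(train_cfg.epochs):
        order = rng.permutation(n)
        model.set_training(True)
        for start in range(0, n, train_cfg.batch_size):
            idx = order[start:start + train_cfg.batch_size]
            optim.zero_grad()
            scores = model.forward(x_train[idx])
            loss = mse_loss_tensor(y_train[idx], scores)
            loss.backward()
            optim.step()
        tr_loss, tr_acc = _epoch_passes(model, x_train, y_train)
        curves["train_loss"].append(tr_loss)
        curves["train_acc"].append(tr_acc)
        if x_val is not None:
            va_loss, va_acc = _epoch_passes(model, x_val, y_val)
        else:
            va_loss, va_acc = tr_loss, tr_acc
        curves["val_loss"].append(va_loss)
        curves["val_acc"].append(va_acc)
        optim.lr = sched.step(va_loss)
        curves["lr"].append(optim.lr)
    model.set_training(False)
    return model, curves


def run_cross_validation(
    segments: Sequence[RRSegment],
    net_cfg: NetworkConfig | None = None,
    train_cfg: TrainConfig | None = None,
    k: int = 10,
) -> EvalReport:
    """Subject-wise k-fold cross-validation over a segment collection.

    Every fold trains a fresh model on its training subjects (scheduling on
    the inner validation subjects) and is evaluated once on its untouched
    test subjects; leakage-freedom is asserted programmatically.
    """
    train_cfg = train_cfg or TrainConfig()
    subjects = sorted({s.subject_id for s in segments})
    labels = {s.subject_id: s.label for s in segments}
    if len({s.label for s in segments}) < 2:
        raise ValueError("cohort must contain both classes")
    split = subject_wise_kfold(
        subjects, k=k, seed=train_cfg.seed, labels=labels,
        val_fraction=train_cfg.val_fraction,
    )
    fold_results: list[FoldResult] = []
    all_labels: list[np.ndarray] = []
    all_scores: list[np.ndarray] = []
    for f, fold in enumerate(split.folds):
        if (fold.train | fold.val) & fold.test:
            raise AssertionError("subject leakage between train/val and test")
        # every fold starts from the identical seeded initialization, so the
        # fold score distributions are commensurable when pooled
        model, curves = train_fold(
            _segments_by_subject(segments, fold.train),
            _segments_by_subject(segments, fold.val),
            net_cfg,
            train_cfg,
        )
        x_test, y_test = segments_to_arrays(
            _segments_by_subject(segments, fold.test)
        )
        scores = model.predict(x_test)
        cc = confusion_counts(y_test, scores)
        try:
            fpr, tpr, auc_val = roc_auc(y_test, scores)
        except ValueError:  # single-class test part (small cohorts)
            fpr, tpr, auc_val = np.array([0.0, 1.0]), np.array([0.0, 1.0]), np.nan
        fold_results.append(
            FoldResult(
                fold_index=f,
                confusion=cc,
                metrics=compute_metrics(cc),
                roc=(fpr, tpr),
                auc=auc_val,
                curves=curves,
                labels=y_test,
                scores=scores,
                test_subjects=fold.test,
                model=model,
            )
        )
        all_labels.append(y_test)
        all_scores.append(scores)
    pooled_labels = np.concatenate(all_labels)
    pooled_scores = np.concatenate(all_scores)
    pooled_cc = confusion_counts(pooled_labels, pooled_scores)
    fpr, tpr, pooled_auc = roc_auc(pooled_labels, pooled_scores)
    return EvalReport(
        folds=fold_results,
        pooled_confusion=pooled_cc,
        pooled_metrics=compute_metrics(pooled_cc),
        pooled_roc=(fpr, tpr),
        pooled_auc=pooled_auc,
    )
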