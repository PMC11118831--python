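"""Subject-disjoint splitting, BCE/Adam training, metrics, cross-validation.

Identity leakage is the cardinal sin of per-epoch EEG classification:
epochs from one subject are highly correlated, so a subject whose epochs
straddle train and test inflates accuracy.  Every split here is therefore
subject-disjoint at the test boundary: ~20% of subjects (label-stratified)
are held out for testing, and the remaining subjects' epochs are shuffled
70/30 into train/validation pools.  The 5-fold cross-validation partitions
subjects, never epochs.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn import metrics as skm

from .autodiff import Tensor
from .errors import ConfigError, SplitError
from .model import ConvMixerECA, ModelConfig
from .preprocess import EpochSet

__all__ = [
    "TrainConfig",
    "SplitPlan",
    "ConfusionMatrix",
    "MetricsReport",
    "TrainResult",
    "split_subjects",
    "assign_epochs",
    "train",
    "evaluate",
    "confusion",
    "metrics",
    "roc_auc",
    "crossval",
]


@dataclass
class TrainConfig:
    """Optimization settings: Adam at lr 1e-4 on BCE for 30 cycles, batch 64."""

    lr: float = 1e-4
    epochs: int = 30
    batch_size: int = 64
    val_fraction: float = 0.30
    test_subject_fraction: float = 0.20
    seed: int = 0
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-8

    def __post_init__(self):
        if not (0 < self.val_fraction < 1) or not (0 < self.test_subject_fraction < 1):
            raise ConfigError("fractions must be in (0, 1)")
        if self.batch_size < 1:
            raise ConfigError("batch_size must be >= 1")


@dataclass
class SplitPlan:
    """Subject-level partition: held-out test subjects vs. train/val pool.

    The test boundary is subject-disjoint.  Within the training subjects,
    the train/validation assignment is made at the *epoch* level (seeded),
    matching a 70/30 split of the training data.
    """

    trainval_subjects: frozenset
    test_subjects: frozenset
    val_fraction: float
    seed: int

    def __post_init__(self):
        if self.trainval_subjects & self.test_subjects:
            raise SplitError("test subjects overlap the train/val pool")


@dataclass
class ConfusionMatrix:
    """Binary confusion counts; positive class = ADHD-like (label 1)."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass
class MetricsReport:
    accuracy: float
    precision: float
    recall: float
    f1: float
    tpr: float
    tnr: float
    fpr: float
    fnr: float
    auc: float | None = None
    roc_points: list[tuple[float, float]] | None = None
    fold_accuracies: list[float] | None = None

    def as_percent_dict(self, decimals: int = 2) -> dict[str, float]:
        """Rates as percentages rounded to `decimals`, matching report style."""
        out = {}
        for name in ("accuracy", "precision", "recall", "f1", "tpr", "tnr", "fpr", "fnr"):
            out[name] = round(100.0 * getattr(self, name), decimals)
        if self.auc is not None:
            out["auc"] = round(self.auc, 4)
        return out


@dataclass
class TrainResult:
    model: ConvMixerECA
    curves: pd.DataFrame                       # epoch, train/val loss & accuracy
    best_epoch: int
    best_params: dict[str, np.ndarray] = field(repr=False, default_factory=dict)


# -------------------------------------------------------------------- splits
def _stratified_subject_sample(subjects: np.ndarray, labels: np.ndarray,
                               fraction: float, rng: np.random.Generator,
                               ) -> set:
    chosen: set = set()
    for lab in np.unique(labels):
        group = subjects[labels == lab]
        n_take = max(1, int(round(fraction * len(group))))
        if n_take >= len(group):
            raise SplitError(
                f"cannot hold out {n_take} of {len(group)} subjects for label {lab}"
            )
        chosen.update(rng.choice(group, size=n_take, replace=False).tolist())
    return chosen


def subject_table(es: EpochSet) -> tuple[np.ndarray, np.ndarray]:
    """Unique subjects and their labels, in first-appearance order."""
    subjects, first = np.unique(es.subject_ids, return_index=True)
    order = np.argsort(first)
    subjects = subjects[order]
    labels = np.asarray([es.labels[es.subject_ids == s][0] for s in subjects])
    return subjects, labels


def split_subjects(subjects: np.ndarray, labels: np.ndarray,
                   cfg: TrainConfig) -> SplitPlan:
    """Label-stratified subject split: ~20% of each class held out for test."""
    subjects = np.asarray(subjects)
    labels = np.asarray(labels)
    if len(subjects) != len(labels):
        raise SplitError("subjects and labels must align")
    if len(np.unique(subjects)) != len(subjects):
        raise SplitError("duplicate subject IDs in the subject table")
    for lab in np.unique(labels):
        if (labels == lab).sum() < 2:
            raise SplitError(f"need >= 2 subjects of label {lab} to split")
    rng = np.random.default_rng(cfg.seed)
    test = _stratified_subject_sample(subjects, labels, cfg.test_subject_fraction, rng)
    trainval = frozenset(subjects.tolist()) - test
    return SplitPlan(
        trainval_subjects=frozenset(trainval),
        test_subjects=frozenset(test),
        val_fraction=cfg.val_fraction,
        seed=cfg.seed,
    )


def assign_epochs(plan: SplitPlan, es: EpochSet
                  ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Epoch indices for (train, val, test) under the plan.

    Test epochs are exactly those of the held-out subjects.  The remaining
    epochs are shuffled with the plan's seed and split
    (1 - val_fraction)/val_fraction into train/validation.
    """
    sids = es.subject_ids
    is_test = np.isin(sids, list(plan.test_subjects))
    test_idx = np.flatnonzero(is_test)
    pool = np.flatnonzero(~is_test)
    if not set(sids[pool]) <= plan.trainval_subjects:
        raise SplitError("epoch set contains subjects unknown to the split plan")
    rng = np.random.default_rng(plan.seed + 1)
    pool = rng.permutation(pool)
    n_val = int(round(plan.val_fraction * len(pool)))
    return np.sort(pool[n_val:]), np.sort(pool[:n_val]), np.sort(test_idx)


# ------------------------------------------------------------------ training
class _Adam:
    def __init__(self, params: dict[str, Tensor], cfg: TrainConfig):
        self.params = params
        self.cfg = cfg
        self.m = {k: np.zeros_like(t.data) for k, t in params.items()}
        self.v = {k: np.zeros_like(t.data) for k, t in params.items()}
        self.t = 0

    def step(self) -> None:
        c = self.cfg
        self.t += 1
        for k, p in self.params.items():
            if p.grad is None:
                continue
            g = p.grad
            self.m[k] = c.beta1 * self.m[k] + (1 - c.beta1) * g
            self.v[k] = c.beta2 * self.v[k] + (1 - c.beta2) * g * g
            mhat = self.m[k] / (1 - c.beta1**self.t)
            vhat = self.v[k] / (1 - c.beta2**self.t)
            p.data = p.data - c.lr * mhat / (np.sqrt(vhat) + c.eps)

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.zero_grad()


def _loss_and_correct(model: ConvMixerECA, x: np.ndarray, y: np.ndarray
                      ) -> tuple[Tensor, int]:
    logits = model.forward_tensor(Tensor(x))
    if model.config.head == "single-logit-sigmoid":
        loss = logits.bce_with_logits(y.reshape(-1, 1).astype(np.float64))
        pred = (logits.data[:, 0] > 0).astype(np.int64)
    else:
        loss = logits.softmax_cross_entropy(y.astype(np.int64))
        pred = logits.data.argmax(axis=1)
    return loss, int((pred == y).sum())


def batch_loss(model: ConvMixerECA, x: np.ndarray, y: np.ndarray) -> float:
    """Mean classification loss of the current parameters on one batch."""
    loss, _ = _loss_and_correct(model, x, y)
    return float(loss.data)


def evaluate_loss_acc(model: ConvMixerECA, x: np.ndarray, y: np.ndarray,
                      batch_size: int = 256) -> tuple[float, float]:
    total_loss, correct, n = 0.0, 0, len(y)
    for lo in range(0, n, batch_size):
        xb, yb = x[lo : lo + batch_size], y[lo : lo + batch_size]
        loss, c = _loss_and_correct(model, xb, yb)
        total_loss += float(loss.data) * len(yb)
        correct += c
    return total_loss / n, correct / n


def train(model: ConvMixerECA, x_train: np.ndarray, y_train: np.ndarray,
          x_val: np.ndarray, y_val: np.ndarray, cfg: TrainConfig,
          verbose: bool = False) -> TrainResult:
    """Minimize BCE with Adam; retain the best-validation-loss checkpoint.

    Each cycle reshuffles the training epochs with a seeded generator
    (fresh "random interruption" of the data per cycle) and sweeps
    minibatches of ``cfg.batch_size``.
    """
    if len(x_train) < 1 or len(x_val) < 1:
        raise ConfigError("empty train or validation partition")
    opt = _Adam(model.params, cfg)
    rng = np.random.default_rng(cfg.seed + 2)
    records = []
    best_val = np.inf
    best_params = model.parameter_arrays()
    best_epoch = -1
    for epoch in range(cfg.epochs):
        order = rng.permutation(len(x_train))
        run_loss, run_correct = 0.0, 0
        t0 = time.time()
        for lo in range(0, len(order), cfg.batch_size):
            idx = order[lo : lo + cfg.batch_size]
            opt.zero_grad()
            loss, c = _loss_and_correct(model, x_train[idx], y_train[idx])
            if not np.isfinite(loss.data):
                raise FloatingPointError(
                    f"non-finite loss at cycle {epoch}, batch {lo // cfg.batch_size}"
                )
            loss.backward()
            opt.step()
            run_loss += float(loss.data) * len(idx)
            run_correct += c
        train_loss = run_loss / len(order)
        train_acc = run_correct / len(order)
        val_loss, val_acc = evaluate_loss_acc(model, x_val, y_val)
        records.append(
            {"epoch": epoch, "train_loss": train_loss, "val_loss": val_loss,
             "train_acc": train_acc, "val_acc": val_acc}
        )
        if val_loss < best_val:
            best_val = val_loss
            best_params = model.parameter_arrays()
            best_epoch = epoch
        if verbose:
            print(
                f"cycle {epoch + 1:3d}/{cfg.epochs}  "
                f"train loss {train_loss:.4f} acc {train_acc:.3f}  "
                f"val loss {val_loss:.4f} acc {val_acc:.3f}  "
                f"({time.time() - t0:.1f}s)"
            )
    model.load_parameter_arrays(best_params)
    return TrainResult(
        model=model,
        curves=pd.DataFrame.from_records(records),
        best_epoch=best_epoch,
        best_params=best_params,
    )


# ------------------------------------------------------------------- metrics
def confusion(predicted: np.ndarray, true: np.ndarray,
              ) -> ConfusionMatrix:
    """Binary confusion counts with the ADHD-like class as positive."""
    predicted = np.asarray(predicted).astype(np.int64)
    true = np.asarray(true).astype(np.int64)
    if predicted.shape != true.shape:
        raise ValueError(f"length mismatch: {predicted.shape} vs {true.shape}")
    if not (set(np.unique(predicted)) <= {0, 1} and set(np.unique(true)) <= {0, 1}):
        raise ValueError("labels must be binary 0/1")
    cm = skm.confusion_matrix(true, predicted, labels=[0, 1])
    return ConfusionMatrix(tp=int(cm[1, 1]), fp=int(cm[0, 1]),
                           fn=int(cm[1, 0]), tn=int(cm[0, 0]))


def metrics(cm: ConfusionMatrix) -> MetricsReport:
    """Accuracy, precision, recall, F1 and the four rates from the counts.

    Degenerate denominators follow the usual conventions: precision is 0
    when nothing was predicted positive; F1 is 0 when its denominator is 0.
    """
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    tp, fp, fn, tn = cm.tp, cm.fp, cm.fn, cm.tn
    accuracy = (tp + tn) / cm.total
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * tp / (2 * tp + fp + fn) if 2 * tp + fp + fn else 0.0
    tnr = tn / (tn + fp) if tn + fp else 0.0
    return MetricsReport(
        accuracy=accuracy, precision=precision, recall=recall, f1=f1,
        tpr=recall, tnr=tnr,
        fpr=1.0 - tnr if tn + fp else 0.0,
        fnr=1.0 - recall if tp + fn else 0.0,
    )


def roc_auc(scores: np.ndarray, true: np.ndarray
            ) -> tuple[list[tuple[float, float]], float]:
    """ROC points (threshold sweep over unique scores) and trapezoidal AUC."""
    scores = np.asarray(scores, dtype=np.float64)
    true = np.asarray(true).astype(np.int64)
    if scores.shape != true.shape:
        raise ValueError("scores and labels must align")
    if len(np.unique(true)) < 2:
        raise ValueError("ROC needs both classes present")
    fpr, tpr, _ = skm.roc_curve(true, scores)
    return list(zip(fpr.tolist(), tpr.tolist())), float(skm.auc(fpr, tpr))


def evaluate(model: ConvMixerECA, x: np.ndarray, y: np.ndarray,
             threshold: float = 0.5) -> tuple[MetricsReport, ConfusionMatrix]:
    """Test-set metrics at the given probability threshold, with ROC/AUC."""
    proba = model.predict_proba(x)
    cm = confusion((proba >= threshold).astype(np.int64), y)
    report = metrics(cm)
    if len(np.unique(y)) == 2:
        report.roc_points, report.auc = roc_auc(proba, y)
    return report, cm


# ---------------------------------------------------------- cross-validation
def stratified_subject_folds(subjects: np.ndarray, labels: np.ndarray,
                             n_folds: int, seed: int) -> list[np.ndarray]:
    """Label-stratified partition of subjects into n_folds disjoint sets."""
    rng = np.random.default_rng(seed)
    folds: list[list] = [[] for _ in range(n_folds)]
    for lab in np.unique(labels):
        group = rng.permutation(subjects[labels == lab])
        if len(group) < n_folds:
            raise SplitError(
                f"label {lab} has {len(group)} subjects; need >= {n_folds}"
            )
        for i, s in enumerate(group):
            folds[i % n_folds].append(s)
    return [np.asarray(f) for f in folds]


def crossval(es: EpochSet, model_cfg: ModelConfig, train_cfg: TrainConfig,
             n_folds: int = 5, verbose: bool = False,
             ) -> tuple[list[MetricsReport], float, float]:
    """Subject-level k-fold cross-validation.

    Each fold's subjects are tested exactly once; the remaining subjects'
    epochs are split 70/30 train/val, standardized with that fold's
    training statistics, and a fresh model is trained per fold.  Returns
    per-fold reports and the mean/sd of fold accuracy.
    """
    subjects, labels = subject_table(es)
    folds = stratified_subject_folds(subjects, labels, n_folds, train_cfg.seed)
    reports: list[MetricsReport] = []
    for i, test_subjects in enumerate(folds):
        plan = SplitPlan(
            trainval_subjects=frozenset(subjects.tolist()) - frozenset(test_subjects.tolist()),
            test_subjects=frozenset(test_subjects.tolist()),
            val_fraction=train_cfg.val_fraction,
            seed=train_cfg.seed + i,
        )
        tr_idx, va_idx, te_idx = assign_epochs(plan, es)
        assert not (set(es.subject_ids[tr_idx]) | set(es.subject_ids[va_idx])) & set(
            es.subject_ids[te_idx]
        ), "subject leakage across the CV test boundary"
        x = es.epochs
        mean = x[tr_idx].mean(axis=(0, 2))
        sd = np.maximum(x[tr_idx].std(axis=(0, 2)), 1e-8)

        def z(a):
            return (a - mean[None, :, None]) / sd[None, :, None]

        model = ConvMixerECA(model_cfg, seed=train_cfg.seed + i)
        result = train(model, z(x[tr_idx]), es.labels[tr_idx],
                       z(x[va_idx]), es.labels[va_idx], train_cfg, verbose=verbose)
        report, _ = evaluate(result.model, z(x[te_idx]), es.labels[te_idx])
        report.fold_accuracies = None
        reports.append(report)
        if verbose:
            print(f"fold {i + 1}/{n_folds}: accuracy {report.accuracy:.4f}")
    accs = np.asarray([r.accuracy for r in reports])
    return reports, float(accs.mean()), float(accs.std(ddof=1) if len(accs) > 1 else 0.0)
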