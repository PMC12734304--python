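"""Training harness and evaluation statistics.

Training follows the protocol the classifier was designed for: SGD with
momentum 0.9 and weight decay 1e-4, label-smoothed cross-entropy (eps 0.1)
plus an L1 sparsity penalty on the prunable BatchNorm scales (lambda 1e-4),
gradient accumulation to an effective batch of 16, a reduce-on-plateau LR
schedule monitoring the training loss, progressive channel pruning every few
epochs, minority-class oversampling, and mild Gaussian-noise / gamma
augmentation applied to training folds only.  Evaluation uses subject-level
stratified five-fold cross-validation with accuracy, sensitivity, specificity,
precision/recall/F1, pairwise-ranking AUC, and a one-sample one-sided
Student t-test of the fold accuracies against a baseline mean.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats
from sklearn.model_selection import StratifiedKFold

from .blocks import VoxNet, NetworkConfig, build_network
from .engine import ReduceLROnPlateau, SGD, label_smoothing_loss, softmax
from .phantoms import Volume, augment_gamma, augment_gaussian_noise, oversample_balance
from .pruning import (PruneSchedule, PruneState, add_sparsity_grad, apply_masks,
                      prune_step, sparsity_penalty)


@dataclass
class TrainConfig:
    epochs: int = 100
    batch_size: int = 4
    accumulation_steps: int = 4          # effective batch 16
    lr: float = 0.005
    momentum: float = 0.9
    weight_decay: float = 1e-4
    label_smoothing: float = 0.1
    sparsity_lambda: float = 1e-4
    plateau_factor: float = 0.1
    plateau_patience: int = 10
    plateau_threshold: float = 1e-4
    augment: bool = True
    augment_noise_sd: float = 0.01
    augment_gamma_range: Tuple[float, float] = (0.8, 1.25)
    seed: int = 0

    def __post_init__(self):
        if min(self.lr, self.momentum, self.weight_decay) < 0:
            raise ValueError("rates must be non-negative")
        if not 0 <= self.label_smoothing < 1:
            raise ValueError(f"label_smoothing must be in [0,1), got {self.label_smoothing}")
        if self.batch_size < 1 or self.accumulation_steps < 1 or self.epochs < 0:
            raise ValueError("batch_size/accumulation_steps/epochs must be positive")


@dataclass
class ConfusionCounts:
    tp: int = 0
    tn: int = 0
    fp: int = 0
    fn: int = 0

    @classmethod
    def from_predictions(cls, y_true, y_pred, positive: int = 1) -> "ConfusionCounts":
        y_true = np.asarray(y_true)
        y_pred = np.asarray(y_pred)
        pos = y_true == positive
        return cls(tp=int((pos & (y_pred == positive)).sum()),
                   tn=int((~pos & (y_pred != positive)).sum()),
                   fp=int((~pos & (y_pred == positive)).sum()),
                   fn=int((pos & (y_pred != positive)).sum()))

    @property
    def total(self):
        return self.tp + self.tn + self.fp + self.fn


@dataclass
class EvalResult:
    acc: Optional[float] = None
    sen: Optional[float] = None
    spe: Optional[float] = None
    precision: Optional[float] = None
    recall: Optional[float] = None
    f1: Optional[float] = None
    auc: Optional[float] = None
    undefined: Tuple[str, ...] = ()

    def to_dict(self):
        return {"acc": self.acc, "sen": self.sen, "spe": self.spe,
                "precision": self.precision, "recall": self.recall,
                "f1": self.f1, "auc": self.auc,
                "undefined": list(self.undefined)}


def confusion_metrics(counts: ConfusionCounts) -> EvalResult:
    """ACC/SEN/SPE/precision/recall/F1; zero-denominator metrics are reported
    as None and flagged rather than coerced to 0."""
    if counts.total < 1:
        raise ValueError("confusion table is empty")
    undefined = []

    def ratio(num, den, name):
        if den == 0:
            undefined.append(name)
            return None
        return num / den

    acc = (counts.tp + counts.tn) / counts.total
    sen = ratio(counts.tp, counts.tp + counts.fn, "sen")
    spe = ratio(counts.tn, counts.tn + counts.fp, "spe")
    precision = ratio(counts.tp, counts.tp + counts.fp, "precision")
    recall = sen
    if precision is None or recall is None or (precision + recall) == 0:
        f1 = None
        undefined.append("f1")
    else:
        f1 = 2 * precision * recall / (precision + recall)
    return EvalResult(acc=acc, sen=sen, spe=spe, precision=precision,
                      recall=recall, f1=f1, undefined=tuple(undefined))


def roc_auc(scores, labels) -> float:
    """AUC as the Mann-Whitney pair statistic: the fraction of
    (positive, negative) pairs ranked correctly, ties counted 0.5."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    if pos.size == 0 or neg.size == 0:
        raise ValueError("AUC needs both classes present")
    diff = pos[:, None] - neg[None, :]
    return float(((diff > 0).sum() + 0.5 * (diff == 0).sum()) / diff.size)


@dataclass
class TTestResult:
    mean: float
    baseline: float
    sd: float
    n: int
    t: float
    p: float

    @property
    def df(self) -> int:
        return self.n - 1


def students_t_pvalue(t: float, df: int, two_sided: bool = False) -> float:
    """Upper-tail (or two-sided) Student-t probability."""
    p = float(stats.t.sf(t, df))
    return 2 * min(p, 1 - p) if two_sided else p


def one_sample_ttest(fold_accuracies, baseline_mean: float,
                     two_sided: bool = False) -> TTestResult:
    """One-sample t-test of fold accuracies against a baseline mean.

    ``t = (xbar - mu0) / (s / sqrt(n))`` with the n-1 sample sd; the p-value
    is the one-sided upper tail (improvement over baseline) by default.
    """
    x = np.asarray(fold_accuracies, dtype=float)
    if x.size < 2:
        raise ValueError("need at least two folds")
    s = float(x.std(ddof=1))
    if s == 0:
        raise ValueError("zero variance across folds: t statistic undefined")
    xbar = float(x.mean())
    t = (xbar - baseline_mean) / (s / math.sqrt(x.size))
    return TTestResult(mean=xbar, baseline=float(baseline_mean), sd=s,
                       n=int(x.size), t=t,
                       p=students_t_pvalue(t, x.size - 1, two_sided=two_sided))


# ---------------------------------------------------------------------------
# cross-validation splits
# ---------------------------------------------------------------------------

def kfold_split(subjects, labels, k: int = 5, seed: int = 0) -> np.ndarray:
    """Stratified subject-level fold assignment (one fold index per record).

    All volumes of one subject share a fold; folds are stratified on the
    subject's label and deterministic for a seed.
    """
    subjects = np.asarray(subjects, dtype=object)
    labels = np.asarray(labels, dtype=int)
    uniq, first_idx = np.unique(subjects, return_index=True)
    subj_labels = labels[first_idx]
    for cls in (0, 1):
        if (subj_labels == cls).sum() < k:
            raise ValueError(
                f"need at least {k} subjects per class, class {cls} has "
                f"{(subj_labels == cls).sum()}")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    subj_fold = {}
    for fold, (_, test_idx) in enumerate(skf.split(uniq, subj_labels)):
        for si in test_idx:
            subj_fold[uniq[si]] = fold
    return np.array([subj_fold[s] for s in subjects], dtype=int)


# ---------------------------------------------------------------------------
# training loop
# ---------------------------------------------------------------------------

def _augment_batch(batch: np.ndarray, cfg: TrainConfig, rng) -> np.ndarray:
    out = np.empty_like(batch)
    lo, hi = cfg.augment_gamma_range
    for i in range(batch.shape[0]):
        v = Volume(data=batch[i, 0])
        v = augment_gaussian_noise(v, cfg.augment_noise_sd, seed=int(rng.integers(2 ** 31)))
        v = augment_gamma(v, float(rng.uniform(lo, hi)))
        out[i, 0] = v.data
    return out


def _as_batch(volumes: Sequence[Volume]) -> Tuple[np.ndarray, np.ndarray]:
    x = np.stack([v.data for v in volumes])[:, None].astype(np.float32)
    y = np.array([v.label for v in volumes], dtype=int)
    return x, y


def evaluate(model: VoxNet, volumes: Sequence[Volume], batch_size: int = 8):
    """Scores, predictions and positive-class probabilities on a dataset."""
    x, y = _as_batch(volumes)
    preds, probs = [], []
    for i in range(0, len(x), batch_size):
        scores = model.forward(x[i:i + batch_size], training=False)
        p = softmax(scores, axis=1)
        preds.append(np.argmax(p, axis=1))
        probs.append(p[:, 1])
    return y, np.concatenate(preds), np.concatenate(probs)


def recalibrate_bn(model: VoxNet, volumes: Sequence[Volume], passes: int = 2,
                   batch_size: int = 8):
    """Refresh BatchNorm running statistics with forward passes (no updates).

    After fast weight movement (high LR, few epochs) the exponentially
    averaged running statistics lag the final weights; a couple of
    statistics-only passes over the training data realigns eval-mode
    behaviour with train-mode behaviour.
    """
    x, _ = _as_batch(volumes)
    for _ in range(passes):
        for i in range(0, len(x), batch_size):
            model.forward(x[i:i + batch_size], training=True)


def train(model: VoxNet, volumes: Sequence[Volume], cfg: TrainConfig,
          schedule: Optional[PruneSchedule] = None,
          state: Optional[PruneState] = None,
          val_volumes: Optional[Sequence[Volume]] = None,
          checkpoint_dir=None) -> Tuple[VoxNet, List[dict], Optional[PruneState]]:
    """Train a model in place; returns (model, per-epoch history, prune state).

    The loss is label-smoothed cross-entropy plus the L1 BN-gamma sparsity
    penalty; gradients are accumulated over ``accumulation_steps``
    micro-batches per optimiser update; pruning (when a schedule is given)
    runs every ``interval_epochs`` epochs; masks are re-applied after each
    update so pruned channels stay dead.  Aborts on non-finite loss, keeping
    the last finite state.
    """
    rng = np.random.default_rng(cfg.seed)
    if schedule is not None and state is None:
        state = PruneState.from_model(model)
    opt = SGD(model.params(), lr=cfg.lr, momentum=cfg.momentum,
              weight_decay=cfg.weight_decay)
    plateau = ReduceLROnPlateau(opt, factor=cfg.plateau_factor,
                                patience=cfg.plateau_patience,
                                threshold=cfg.plateau_threshold)
    x_all, y_all = _as_batch(volumes)
    history: List[dict] = []
    n = len(volumes)
    for epoch in range(1, cfg.epochs + 1):
        order = rng.permutation(n)
        losses, correct = [], 0
        micro = 0
        opt.zero_grad()
        for start in range(0, n, cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            xb = x_all[idx]
            if cfg.augment:
                xb = _augment_batch(xb, cfg, rng)
            yb = y_all[idx]
            scores = model.forward(xb, training=True)
            loss, dscores = label_smoothing_loss(scores, yb, cfg.label_smoothing)
            if cfg.sparsity_lambda > 0:
                loss += sparsity_penalty(model, cfg.sparsity_lambda)
            if not np.isfinite(loss):
                warnings.warn(f"non-finite loss at epoch {epoch}; aborting training")
                return model, history, state
            losses.append(loss)
            correct += int((np.argmax(scores, axis=1) == yb).sum())
            model.backward(dscores / cfg.accumulation_steps)
            micro += 1
            if micro % cfg.accumulation_steps == 0 or start + cfg.batch_size >= n:
                if cfg.sparsity_lambda > 0:
                    add_sparsity_grad(model, cfg.sparsity_lambda / cfg.accumulation_steps)
                opt.step()
                opt.zero_grad()
                if state is not None:
                    apply_masks(model, state)
        train_loss = float(np.mean(losses))
        record = {"epoch": epoch, "train_loss": train_loss,
                  "train_acc": correct / n, "lr": opt.lr,
                  "pruned_fraction": state.cumulative_pruned_fraction if state else 0.0}
        if val_volumes:
            yv, pv, _ = evaluate(model, val_volumes)
            record["val_acc"] = float((yv == pv).mean())
        history.append(record)
        plateau.step(train_loss)
        if schedule is not None and epoch % schedule.interval_epochs == 0:
            state = prune_step(model, state, schedule)
            record["pruned_fraction"] = state.cumulative_pruned_fraction
        if checkpoint_dir is not None:
            from .blocks import save_checkpoint
            save_checkpoint(f"{checkpoint_dir}/epoch{epoch:03d}.npz", model,
                            extra={"epoch": epoch, "history": history[-1],
                                   "prune_state": state.to_jsonable() if state else None})
    if cfg.epochs > 0:
        recalibrate_bn(model, volumes)
    return model, history, state


@dataclass
class FoldOutcome:
    fold: int
    result: EvalResult
    n_test: int


def cross_validate(volumes: Sequence[Volume], net_config: NetworkConfig,
                   cfg: TrainConfig, schedule: Optional[PruneSchedule] = None,
                   k: int = 5) -> Tuple[List[FoldOutcome], Dict[str, float]]:
    """Subject-level stratified k-fold CV.

    Oversampling and augmentation touch training folds only; each fold trains
    a freshly seeded model and is evaluated on its held-out subjects.
    Returns per-fold outcomes and an aggregate of mean and sd per metric.
    """
    subjects = [v.subject_id for v in volumes]
    labels = [v.label for v in volumes]
    folds = kfold_split(subjects, labels, k=k, seed=cfg.seed)
    outcomes: List[FoldOutcome] = []
    for fold in range(k):
        test_idx = np.nonzero(folds == fold)[0]
        train_idx = np.nonzero(folds != fold)[0]
        train_labels = [labels[i] for i in train_idx]
        resampled = oversample_balance(train_labels, seed=cfg.seed + fold)
        train_vols = [volumes[train_idx[i]] for i in resampled]
        model = build_network(net_config, seed=cfg.seed + fold)
        fold_cfg = TrainConfig(**{**cfg.__dict__, "seed": cfg.seed + 1000 + fold})
        model, _, state = train(model, train_vols, fold_cfg, schedule=schedule)
        y, pred, prob = evaluate(model, [volumes[i] for i in test_idx])
        res = confusion_metrics(ConfusionCounts.from_predictions(y, pred))
        try:
            res.auc = roc_auc(prob, y)
        except ValueError:
            res.undefined = res.undefined + ("auc",)
        outcomes.append(FoldOutcome(fold=fold, result=res, n_test=len(test_idx)))
    aggregate: Dict[str, float] = {}
    for metric in ("acc", "sen", "spe", "precision", "recall", "f1", "auc"):
        vals = [getattr(o.result, metric) for o in outcomes
                if getattr(o.result, metric) is not None]
        if vals:
            aggregate[f"{metric}_mean"] = float(np.mean(vals))
            aggregate[f"{metric}_sd"] = float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0
    return outcomes, aggregate
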