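"""Multi-stage supervised loss and the training loop.

The total training objective combines the main-head cross-entropy with the
three auxiliary-stage losses:

    L_total = (1 - lambda) * L_main + lambda * (L_aux1 + L_aux2 + L_aux3)

with lambda = 0.1 by default.  Auxiliary heads run only in training-mode
forward passes; evaluation and inference use the main head alone.
Optimization follows a plain adaptive-moment (Adam) recipe: batch size 32,
learning rate 1e-3, no scheduler, no weight decay, no early stopping.
"""

from __future__ import annotations

import copy
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, List, Optional, Sequence, Union

import numpy as np

from . import _engine as E
from ._engine import autograd as F
from .data import DatasetSplit, ImageRecord, stratified_split
from .errors import ConfigError, DataError, UsageError
from .network import LightWaveNet

__all__ = [
    "LossConfig",
    "TrainConfig",
    "EpochRecord",
    "TrainingLog",
    "cross_entropy",
    "multi_stage_loss",
    "recalibrate_bn",
    "train",
    "cross_validate",
]

logger = logging.getLogger(__name__)

_EPS = 1e-12


@dataclass(frozen=True)
class LossConfig:
    lambda_aux: float = 0.1
    num_aux_stages: int = 3

    def __post_init__(self):
        if not 0.0 <= self.lambda_aux <= 1.0:
            raise ConfigError(f"lambda_aux must lie in [0, 1], got {self.lambda_aux}")
        if self.num_aux_stages < 0:
            raise ConfigError("num_aux_stages must be >= 0")


@dataclass(frozen=True)
class TrainConfig:
    batch_size: int = 32
    learning_rate: float = 1e-3
    epochs: int = 100
    folds: Optional[int] = None

    def __post_init__(self):
        if self.batch_size < 1 or self.epochs < 1:
            raise ConfigError("batch_size and epochs must be positive")
        if self.learning_rate <= 0:
            raise ConfigError("learning_rate must be > 0")


def cross_entropy(pred_probs: np.ndarray, label: int) -> float:
    """Cross-entropy of a probability vector against a one-hot label.

    Equals ``-log p(true class)``; a zero probability at the true class is
    floored at 1e-12 so the result stays a large finite number.
    """
    p = np.asarray(pred_probs, dtype=np.float64)
    if p.ndim != 1:
        raise ValueError(f"expected a probability vector, got ndim={p.ndim}")
    if not 0 <= label < p.shape[0]:
        raise ValueError(f"label {label} out of range for {p.shape[0]} classes")
    if not math.isclose(float(p.sum()), 1.0, abs_tol=1e-5):
        raise ValueError("probabilities must sum to 1")
    return float(-np.log(max(float(p[label]), _EPS)))


def multi_stage_loss(
    main: float, aux: Sequence[float], lambda_aux: float, num_aux_stages: int = 3
) -> float:
    """``(1 - lambda) * main + lambda * sum(aux)`` with exactly the expected aux terms."""
    if not 0.0 <= lambda_aux <= 1.0:
        raise ConfigError(f"lambda_aux must lie in [0, 1], got {lambda_aux}")
    aux = list(aux)
    if len(aux) != num_aux_stages:
        raise UsageError(
            f"expected {num_aux_stages} auxiliary losses, got {len(aux)}"
        )
    return (1.0 - lambda_aux) * float(main) + lambda_aux * float(sum(aux))


@dataclass
class EpochRecord:
    epoch: int
    train_loss: float
    train_main_loss: float
    train_aux_loss: float
    val_accuracy: float

    def to_dict(self) -> dict:
        return {
            "epoch": self.epoch,
            "train_loss": self.train_loss,
            "train_main_loss": self.train_main_loss,
            "train_aux_loss": self.train_aux_loss,
            "val_accuracy": self.val_accuracy,
        }


@dataclass
class TrainingLog:
    epochs: List[EpochRecord]
    best_epoch: int
    best_val_accuracy: float

    def to_csv(self, path: Union[str, Path]) -> None:
        with open(path, "w") as fh:
            fh.write("epoch,train_loss,train_main_loss,train_aux_loss,val_accuracy\n")
            for r in self.epochs:
                fh.write(
                    f"{r.epoch},{r.train_loss:.6f},{r.train_main_loss:.6f},"
                    f"{r.train_aux_loss:.6f},{r.val_accuracy:.6f}\n"
                )


def recalibrate_bn(
    model: LightWaveNet, images: np.ndarray, batch_size: int = 32
) -> None:
    """Re-estimate all batch-norm statistics from the given images.

    Momentum-averaged running statistics are a poor estimate after few
    optimizer steps (they still remember the initial weights), so before
    any eval-mode use the statistics are recomputed as the plain average of
    batch statistics over a forward sweep — the usual precise-BN procedure.
    Weights are untouched; only normalization buffers change.
    """
    bns = [m for m in model.modules() if isinstance(m, E.BatchNorm2d)]
    if not bns or len(images) == 0:
        return
    saved = [(m.momentum,) for m in bns]
    for m in bns:
        m.running_mean[...] = 0.0
        m.running_var[...] = 0.0
    was_training = model.training
    model.train(True)
    try:
        with E.no_grad():
            for i, lo in enumerate(range(0, len(images), batch_size), start=1):
                for m in bns:
                    m.momentum = 1.0 / i  # cumulative average of batch stats
                model.forward(images[lo : lo + batch_size])
    finally:
        for m, (mom,) in zip(bns, saved):
            m.momentum = mom
        model.train(was_training)


def _accuracy(model: LightWaveNet, records: Sequence[ImageRecord], batch_size: int) -> float:
    images = np.stack([r.pixels for r in records])
    labels = np.array([r.label for r in records])
    probs = model.predict_proba(images, batch_size=batch_size)
    return float((probs.argmax(axis=1) == labels).mean())


def train(
    model: LightWaveNet,
    splits: DatasetSplit,
    tcfg: TrainConfig = TrainConfig(),
    lcfg: LossConfig = LossConfig(),
    seed: int = 0,
    log_path: Optional[Union[str, Path]] = None,
) -> TrainingLog:
    """Train in place; the best-validation-accuracy weights are restored at the end.

    Every epoch records the total/main/aux training losses and validation
    accuracy; with ``log_path`` each record is also appended as a JSON line.
    Batch order is driven solely by ``seed``, so runs are reproducible.
    """
    if not splits.train or not splits.validation:
        raise DataError("training needs non-empty train and validation partitions")
    rng = np.random.default_rng(seed)
    images = np.stack([r.pixels for r in splits.train])
    labels = np.array([r.label for r in splits.train])
    n = len(labels)
    lam = lcfg.lambda_aux

    opt = E.Adam(model.parameters(), lr=tcfg.learning_rate)
    log_fh = open(log_path, "w") if log_path else None
    epochs: List[EpochRecord] = []
    best_acc, best_epoch, best_state = -1.0, -1, None
    try:
        for epoch in range(1, tcfg.epochs + 1):
            model.train()
            perm = rng.permutation(n)
            tot = tot_main = tot_aux = 0.0
            nb = 0
            for lo in range(0, n, tcfg.batch_size):
                idx = perm[lo : lo + tcfg.batch_size]
                out = model.forward(images[idx])
                main_l = F.cross_entropy_logits(out.main_logits, labels[idx])
                aux_ls = [
                    F.cross_entropy_logits(a, labels[idx]) for a in out.aux_logits
                ]
                aux_sum = aux_ls[0]
                for a in aux_ls[1:]:
                    aux_sum = F.add(aux_sum, a)
                total = F.add(F.smul(main_l, 1.0 - lam), F.smul(aux_sum, lam))
                opt.zero_grad()
                total.backward()
                opt.step()
                tot += total.item()
                tot_main += main_l.item()
                tot_aux += aux_sum.item()
                nb += 1
            recalibrate_bn(model, images, tcfg.batch_size)
            val_acc = _accuracy(model, splits.validation, tcfg.batch_size)
            rec = EpochRecord(epoch, tot / nb, tot_main / nb, tot_aux / nb, val_acc)
            epochs.append(rec)
            if log_fh:
                log_fh.write(json.dumps(rec.to_dict()) + "\n")
                log_fh.flush()
            logger.info(
                "epoch %d: loss=%.4f (main %.4f, aux %.4f) val_acc=%.4f",
                epoch, rec.train_loss, rec.train_main_loss, rec.train_aux_loss, val_acc,
            )
            if val_acc > best_acc:
                best_acc, best_epoch = val_acc, epoch
                best_state = copy.deepcopy(model.state_dict())
    finally:
        if log_fh:
            log_fh.close()
    if best_state is not None:
        model.load_state_dict(best_state)
    model.eval()
    return TrainingLog(epochs, best_epoch, best_acc)


def _fold_assignments(labels: np.ndarray, k: int, seed: int) -> np.ndarray:
    """Stratified fold labels; degrades to per-class round-robin with a warning
    when some class has fewer than k members."""
    counts = np.bincount(labels)
    min_count = counts[counts > 0].min()
    if min_count >= k:
        from sklearn.model_selection import StratifiedKFold

        skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed % (2**32 - 1))
        folds = np.empty(len(labels), dtype=int)
        for f, (_, test_idx) in enumerate(skf.split(np.zeros(len(labels)), labels)):
            folds[test_idx] = f
        return folds
    logger.warning(
        "some class has fewer than %d samples; fold stratification degrades "
        "to per-class round-robin", k,
    )
    rng = np.random.default_rng(seed)
    folds = np.empty(len(labels), dtype=int)
    for label in np.unique(labels):
        idx = np.nonzero(labels == label)[0]
        rng.shuffle(idx)
        folds[idx] = np.arange(len(idx)) % k
    return folds


@dataclass
class CrossValResult:
    fold_accuracies: List[float]
    mean_accuracy: float
    fold_assignments: np.ndarray


def cross_validate(
    records: Sequence[ImageRecord],
    model_factory: Callable[[int], LightWaveNet],
    k: int = 5,
    tcfg: TrainConfig = TrainConfig(),
    lcfg: LossConfig = LossConfig(),
    seed: int = 0,
) -> CrossValResult:
    """k-fold cross-validation with stratified fold assignment.

    Each fold is held out once; the remaining records are re-split 5:1 into
    train/validation (model selection never sees the held-out fold).
    """
    if k < 2:
        raise ConfigError(f"cross-validation needs k >= 2, got {k}")
    if not records:
        raise DataError("cannot cross-validate an empty record list")
    labels = np.array([r.label for r in records])
    folds = _fold_assignments(labels, k, seed)
    accs = []
    for f in range(k):
        held = [r for r, fl in zip(records, folds) if fl == f]
        rest = [r for r, fl in zip(records, folds) if fl != f]
        inner = stratified_split(rest, ratios=(5, 1, 0), seed=seed + f)
        split = DatasetSplit(inner.train, inner.validation, held, ratios=(5, 1, 0))
        model = model_factory(seed + f)
        train(model, split, tcfg, lcfg, seed=seed + f)
        accs.append(_accuracy(model, held, tcfg.batch_size))
        logger.info("fold %d/%d accuracy: %.4f", f + 1, k, accs[-1])
    return CrossValResult(accs, float(np.mean(accs)), folds)
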