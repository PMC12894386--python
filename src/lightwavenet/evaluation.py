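"""Evaluation: classification metrics, paired significance, robustness, CAM.

Per-class precision, recall and F1 are computed one-vs-rest and
macro-averaged; accuracy is the fraction of correct predictions.  McNemar's
paired test compares two classifiers through their discordant predictions
(exact binomial for small discordance, continuity-corrected chi-squared
otherwise).  The noise sweep re-evaluates a model under increasing Gaussian
pixel noise, and Grad-CAM projects class evidence back onto the image.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import List, Optional, Sequence, Tuple, Union

import numpy as np
from scipy import ndimage

from . import _engine as E
from ._engine import autograd as F
from .data import ImageRecord, add_gaussian_noise
from .errors import DataError, UsageError
from .network import LightWaveNet

__all__ = [
    "EvalReport",
    "evaluate",
    "evaluate_predictions",
    "mcnemar_test",
    "noise_sweep",
    "export_features",
    "intra_class_variance",
    "grad_cam",
    "save_heatmap_overlay",
]


@dataclass
class EvalReport:
    confusion: np.ndarray  # rows = true class, columns = predicted
    per_class_precision: np.ndarray
    per_class_recall: np.ndarray
    per_class_f1: np.ndarray
    macro_precision: float
    macro_recall: float
    macro_f1: float
    accuracy: float
    n: int
    zero_division_classes: List[int]

    def to_dict(self) -> dict:
        return {
            "confusion": self.confusion.tolist(),
            "per_class": {
                "precision": self.per_class_precision.tolist(),
                "recall": self.per_class_recall.tolist(),
                "f1": self.per_class_f1.tolist(),
            },
            "macro": {
                "precision": self.macro_precision,
                "recall": self.macro_recall,
                "f1": self.macro_f1,
            },
            "accuracy": self.accuracy,
            "n": self.n,
            "zero_division_classes": self.zero_division_classes,
        }

    def to_json(self, path: Union[str, Path]) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    def confusion_to_csv(self, path: Union[str, Path]) -> None:
        np.savetxt(path, self.confusion, fmt="%d", delimiter=",")


def evaluate_predictions(
    y_true: np.ndarray, y_pred: np.ndarray, num_classes: Optional[int] = None
) -> EvalReport:
    """Metrics from label/prediction vectors (order-invariant)."""
    from sklearn.metrics import confusion_matrix, precision_recall_fscore_support

    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("labels and predictions must have equal length")
    if num_classes is None:
        num_classes = int(max(y_true.max(), y_pred.max())) + 1
    labels = np.arange(num_classes)
    cm = confusion_matrix(y_true, y_pred, labels=labels)
    prec, rec, f1, _ = precision_recall_fscore_support(
        y_true, y_pred, labels=labels, zero_division=0
    )
    zero_div = [int(c) for c in labels if cm[:, c].sum() == 0 or cm[c, :].sum() == 0]
    return EvalReport(
        confusion=cm,
        per_class_precision=prec,
        per_class_recall=rec,
        per_class_f1=f1,
        macro_precision=float(prec.mean()),
        macro_recall=float(rec.mean()),
        macro_f1=float(f1.mean()),
        accuracy=float((y_true == y_pred).mean()),
        n=int(len(y_true)),
        zero_division_classes=zero_div,
    )


def predict_labels(
    model: LightWaveNet, records: Sequence[ImageRecord], batch_size: int = 32
) -> np.ndarray:
    images = np.stack([r.pixels for r in records])
    return model.predict_proba(images, batch_size=batch_size).argmax(axis=1)


def evaluate(
    model: LightWaveNet, records: Sequence[ImageRecord], batch_size: int = 32
) -> EvalReport:
    if not records:
        raise DataError("cannot evaluate on an empty record list")
    y_true = np.array([r.label for r in records])
    y_pred = predict_labels(model, records, batch_size)
    return evaluate_predictions(y_true, y_pred, num_classes=model.config.num_classes)


def mcnemar_test(
    preds_a: np.ndarray, preds_b: np.ndarray, labels: np.ndarray
) -> dict:
    """Paired McNemar test on two classifiers' predictions.

    b = A correct and B wrong, c = A wrong and B correct.  Exact two-sided
    binomial p-value when b + c < 25, else chi-squared with continuity
    correction.
    """
    preds_a, preds_b, labels = map(np.asarray, (preds_a, preds_b, labels))
    if not (preds_a.shape == preds_b.shape == labels.shape):
        raise ValueError("prediction and label vectors must have equal length")
    a_ok = preds_a == labels
    b_ok = preds_b == labels
    b = int(np.sum(a_ok & ~b_ok))
    c = int(np.sum(~a_ok & b_ok))
    if b + c == 0:
        p = 1.0
    else:
        from statsmodels.stats.contingency_tables import mcnemar

        table = [[int(np.sum(a_ok & b_ok)), b], [c, int(np.sum(~a_ok & ~b_ok))]]
        exact = (b + c) < 25
        res = mcnemar(table, exact=exact, correction=True)
        p = float(min(res.pvalue, 1.0))
    return {"b_count": b, "c_count": c, "p_value": p}


def noise_sweep(
    model: LightWaveNet,
    records: Sequence[ImageRecord],
    levels: Sequence[float] = (0.0, 0.05, 0.10, 0.15),
    seed: int = 0,
    batch_size: int = 32,
) -> dict:
    """Accuracy under increasing Gaussian pixel noise; level 0 is the clean run."""
    if not records:
        raise DataError("cannot sweep over an empty record list")
    y_true = np.array([r.label for r in records])
    out = {}
    children = np.random.SeedSequence(seed).spawn(len(levels))
    for level, ss in zip(levels, children):
        rng = np.random.default_rng(ss)
        noisy = [add_gaussian_noise(r, level, rng) for r in records]
        y_pred = predict_labels(model, noisy, batch_size)
        out[float(level)] = float((y_pred == y_true).mean())
    return out


def export_features(
    model: LightWaveNet,
    records: Sequence[ImageRecord],
    stage: int = 4,
    batch_size: int = 32,
) -> Tuple[np.ndarray, np.ndarray]:
    """Globally averaged stage features, (n, d) plus the label vector."""
    if stage not in (1, 2, 3, 4):
        raise ValueError(f"stage must be 1..4, got {stage}")
    if not records:
        raise DataError("cannot export features of an empty record list")
    images = np.stack([r.pixels for r in records])
    labels = np.array([r.label for r in records])
    was_training = model.training
    model.eval()
    try:
        feats = []
        with E.no_grad():
            for lo in range(0, len(images), batch_size):
                out = model.forward(images[lo : lo + batch_size], collect_features=True)
                feats.append(out.stage_features[stage - 1].data)
        return np.concatenate(feats, axis=0), labels
    finally:
        model.train(was_training)


def intra_class_variance(features: np.ndarray, labels: np.ndarray) -> float:
    """Mean over classes of the mean squared deviation from the class centroid."""
    features = np.asarray(features, dtype=np.float64)
    labels = np.asarray(labels)
    variances = []
    for label in np.unique(labels):
        x = features[labels == label]
        centroid = x.mean(axis=0)
        variances.append(float(np.mean(np.sum((x - centroid) ** 2, axis=1))))
    return float(np.mean(variances))


def grad_cam(
    model: LightWaveNet,
    image: np.ndarray,
    target_class: int,
    stage: int = 4,
) -> np.ndarray:
    """Class-activation heatmap in [0, 1] at the input's spatial size.

    Channel weights are the globally averaged gradients of the target-class
    logit at the chosen stage; the heatmap is the rectified weighted sum of
    that stage's feature maps, bilinearly upsampled and min-max normalized
    (an all-constant map yields all zeros).
    """
    if stage not in (1, 2, 3, 4):
        raise ValueError(f"stage must be 1..4, got {stage}")
    if not E.grad_enabled():
        raise UsageError(
            "grad_cam needs gradient tracking; call it outside a no_grad() block"
        )
    image = np.asarray(image, dtype=np.float32)
    if image.ndim != 3 or image.shape[0] != 3:
        raise ValueError(f"expected a 3 x H x W image, got shape {image.shape}")
    if not 0 <= target_class < model.config.num_classes:
        raise ValueError(f"target class {target_class} out of range")
    was_training = model.training
    model.eval()
    try:
        out = model.forward(image[None], collect_maps=True)
        fmap = out.stage_maps[stage - 1]
        onehot = np.zeros_like(out.main_logits.data)
        onehot[0, target_class] = 1.0
        score = F.tsum(F.mul(out.main_logits, E.Tensor(onehot)))
        score.backward()
    finally:
        model.train(was_training)
    if fmap.grad is None:
        raise UsageError("no gradient reached the requested stage")
    weights = fmap.grad.mean(axis=(2, 3))  # (1, C)
    cam = np.maximum((weights[:, :, None, None] * fmap.data).sum(axis=1), 0.0)[0]
    h, w = image.shape[1:]
    cam = ndimage.zoom(cam, (h / cam.shape[0], w / cam.shape[1]), order=1)
    cam = cam[:h, :w]
    lo, hi = cam.min(), cam.max()
    if hi - lo < 1e-12:
        return np.zeros((h, w), dtype=np.float32)
    return ((cam - lo) / (hi - lo)).astype(np.float32)


def save_heatmap_overlay(
    image: np.ndarray, cam: np.ndarray, path: Union[str, Path], alpha: float = 0.5
) -> None:
    """Blend a red-yellow rendering of the heatmap over the image, save PNG."""
    from PIL import Image as PILImage

    heat = np.stack([cam, cam**2, np.zeros_like(cam)], axis=0)  # red->yellow ramp
    blend = np.clip((1 - alpha) * image + alpha * heat, 0, 1)
    arr = (blend.transpose(1, 2, 0) * 255).round().astype(np.uint8)
    PILImage.fromarray(arr).save(path)
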