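"""Segmentation metrics and cross-validation protocols.

Metrics follow the standard confusion-matrix definitions —

    accuracy    = (TP + TN) / (TP + FP + TN + FN)
    sensitivity = TP / (TP + FN)
    specificity = TN / (TN + FP)
    JC          = |PR ∩ GT| / |PR ∪ GT| = TP / (TP + FP + FN)

reported as percentages, plus the tie-aware ROC AUC. The Jaccard
coefficient (intersection-over-union) is the primary metric: accuracy and
specificity are inflated by the prevalent negative class, so by default all
metrics are computed over foreground (tissue) pixels only; a flag enables
whole-image evaluation. Zero-denominator metrics (e.g. sensitivity with no
positives) are reported as NaN ("undefined") and excluded from averages.

Cross-validation follows leave-one-out over tissue samples: each sample is
the test fold exactly once, the segmenter is retrained from scratch per
fold, and per-fold metrics are aggregated by unweighted mean and sample
standard deviation. Named train/test splits by sample id are supported for
single-split protocols.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from .io import LabelMask

__all__ = [
    "ConfusionCounts",
    "MetricsReport",
    "SegmentationResult",
    "FoldPlan",
    "confusion_counts",
    "metrics_from_counts",
    "roc_auc",
    "evaluate_segmentation",
    "run_loocv",
    "run_named_split",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be nonnegative")

    @property
    def evaluated_pixels(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass(frozen=True)
class MetricsReport:
    """Percent-scale metrics; NaN marks an undefined (0/0) value."""

    accuracy: float
    sensitivity: float
    specificity: float
    jc: float
    auc: float = float("nan")

    def as_dict(self) -> dict[str, float]:
        return {"accuracy": self.accuracy, "sensitivity": self.sensitivity,
                "specificity": self.specificity, "jc": self.jc,
                "auc": self.auc}


@dataclass
class SegmentationResult:
    """Per-pixel tumor probability/score and binary mask for one cube."""

    mask: np.ndarray                     # 2-D binary prediction
    scores: np.ndarray                   # 2-D continuous scores (for ROC)
    foreground: np.ndarray               # 2-D evaluation mask
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask).astype(np.uint8)
        self.scores = np.asarray(self.scores, dtype=float)
        self.foreground = np.asarray(self.foreground).astype(bool)
        if not (self.mask.shape == self.scores.shape
                == self.foreground.shape):
            raise ValueError("mask, scores and foreground must share shape")


@dataclass
class FoldPlan:
    """Train/test sample-id assignments for a cross-validation scheme."""

    folds: list[tuple[list, list]]
    scheme: str = "loocv"

    def __post_init__(self) -> None:
        if self.scheme == "loocv":
            tested = [s for _, test in self.folds for s in test]
            if len(tested) != len(set(tested)):
                raise ValueError("loocv: a sample is tested more than once")
            for train, test in self.folds:
                if set(train) & set(test):
                    raise ValueError("loocv: train/test overlap in a fold")


# --------------------------------------------------------------------------
# Metrics
# --------------------------------------------------------------------------

def confusion_counts(pred: np.ndarray, gt: LabelMask | np.ndarray,
                     evaluation_mask: np.ndarray | None = None
                     ) -> ConfusionCounts:
    """Pixel confusion counts restricted to ``evaluation_mask == 1``."""
    pred = np.asarray(pred).astype(bool)
    gt_values = (gt.values if isinstance(gt, LabelMask)
                 else np.asarray(gt)).astype(bool)
    if pred.shape != gt_values.shape:
        raise ValueError("prediction and ground truth dims must agree")
    if evaluation_mask is None:
        evaluation_mask = np.ones_like(pred, dtype=bool)
    evaluation_mask = np.asarray(evaluation_mask).astype(bool)
    if evaluation_mask.shape != pred.shape:
        raise ValueError("evaluation mask dims must agree")
    if not evaluation_mask.any():
        raise ValueError("evaluation mask is empty")
    p = pred[evaluation_mask]
    g = gt_values[evaluation_mask]
    return ConfusionCounts(
        tp=int(np.sum(p & g)), tn=int(np.sum(~p & ~g)),
        fp=int(np.sum(p & ~g)), fn=int(np.sum(~p & g)))


def _ratio(num: int, den: int) -> float:
    return float("nan") if den == 0 else 100.0 * num / den


def metrics_from_counts(counts: ConfusionCounts) -> MetricsReport:
    """Accuracy / sensitivity / specificity / JC from confusion counts."""
    if counts.evaluated_pixels == 0:
        raise ValueError("no evaluated pixels")
    return MetricsReport(
        accuracy=_ratio(counts.tp + counts.tn, counts.evaluated_pixels),
        sensitivity=_ratio(counts.tp, counts.tp + counts.fn),
        specificity=_ratio(counts.tn, counts.tn + counts.fp),
        jc=_ratio(counts.tp, counts.tp + counts.fp + counts.fn))


def roc_auc(scores: np.ndarray, gt: LabelMask | np.ndarray,
            evaluation_mask: np.ndarray | None = None) -> float:
    """Tie-aware ROC AUC over the evaluation mask; NaN if single-class."""
    scores = np.asarray(scores, dtype=float)
    gt_values = (gt.values if isinstance(gt, LabelMask)
                 else np.asarray(gt)).astype(int)
    if evaluation_mask is None:
        evaluation_mask = np.ones_like(gt_values, dtype=bool)
    evaluation_mask = np.asarray(evaluation_mask).astype(bool)
    y = gt_values[evaluation_mask].ravel()
    s = scores[evaluation_mask].ravel()
    if len(np.unique(y)) < 2:
        return float("nan")
    return float(roc_auc_score(y, s))


def evaluate_segmentation(result: SegmentationResult,
                          gt: LabelMask,
                          foreground_only: bool = True) -> MetricsReport:
    """Metrics for one segmentation result against its ground truth."""
    eval_mask = result.foreground if foreground_only else None
    counts = confusion_counts(result.mask, gt, eval_mask)
    report = metrics_from_counts(counts)
    auc = roc_auc(result.scores, gt, eval_mask)
    return MetricsReport(accuracy=report.accuracy,
                         sensitivity=report.sensitivity,
                         specificity=report.specificity,
                         jc=report.jc, auc=auc)


# --------------------------------------------------------------------------
# Cross-validation protocols
# --------------------------------------------------------------------------

def _nanmean(values: Sequence[float]) -> float:
    arr = np.asarray(values, dtype=float)
    return float(np.nanmean(arr)) if np.isfinite(arr).any() else float("nan")


def _nanstd(values: Sequence[float]) -> float:
    arr = np.asarray(values, dtype=float)
    finite = arr[np.isfinite(arr)]
    if finite.size < 2:
        return float("nan")
    return float(np.std(finite, ddof=1))


def _aggregate(per_fold: list[dict]) -> dict:
    metrics = ("accuracy", "sensitivity", "specificity", "jc", "auc")
    return {
        "mean": {m: _nanmean([f[m] for f in per_fold]) for m in metrics},
        "std": {m: _nanstd([f[m] for f in per_fold]) for m in metrics},
    }


def run_loocv(samples: Sequence[tuple],
              segmenter_factory: Callable,
              seed: int = 0,
              foreground_only: bool = True,
              sample_ids: Sequence[str] | None = None
              ) -> tuple[pd.DataFrame, dict]:
    """Leave-one-out cross-validation over tissue samples.

    ``samples`` is a sequence of ``(cube, labels)`` pairs (any segmenter
    input paired with its :class:`~hsiseg.io.LabelMask`);
    ``segmenter_factory(train_samples, seed)`` must return a callable
    ``segment(cube) -> SegmentationResult`` trained only on the given
    samples. Returns a per-fold metrics table and a mean/std summary.
    Folds whose segmenter raises are marked failed and excluded from the
    aggregate.
    """
    if len(samples) < 2:
        raise ValueError("LOOCV needs at least 2 samples")
    ids = list(sample_ids) if sample_ids is not None \
        else [f"sample_{i}" for i in range(len(samples))]
    plan = FoldPlan(
        folds=[([ids[j] for j in range(len(samples)) if j != i], [ids[i]])
               for i in range(len(samples))],
        scheme="loocv")
    rows, per_fold = [], []
    for i, (train_ids, test_ids) in enumerate(plan.folds):
        train = [samples[j] for j in range(len(samples)) if ids[j] != test_ids[0]]
        cube, labels = samples[i]
        try:
            segment = segmenter_factory(train, seed)
            result = segment(cube)
            report = evaluate_segmentation(result, labels,
                                           foreground_only=foreground_only)
            row = {"fold": i, "sample_id": test_ids[0], "failed": False,
                   **report.as_dict()}
            per_fold.append(report.as_dict())
        except Exception as exc:       # fold failure: report and move on
            row = {"fold": i, "sample_id": test_ids[0], "failed": True,
                   "error": str(exc), "accuracy": np.nan,
                   "sensitivity": np.nan, "specificity": np.nan,
                   "jc": np.nan, "auc": np.nan}
        rows.append(row)
    if not per_fold:
        raise RuntimeError("every LOOCV fold failed")
    return pd.DataFrame(rows), _aggregate(per_fold)


def run_named_split(samples: dict,
                    split_table: dict[str, Sequence[str]],
                    segmenter_factory: Callable,
                    seed: int = 0,
                    foreground_only: bool = True
                    ) -> tuple[pd.DataFrame, dict]:
    """Train on ``split_table['train']`` ids, evaluate on ``['test']`` ids.

    ``samples`` maps sample id -> (cube, labels). Train and test ids must be
    disjoint and non-empty.
    """
    train_ids = list(split_table["train"])
    test_ids = list(split_table["test"])
    if not test_ids or not train_ids:
        raise ValueError("train and test sets must be non-empty")
    if set(train_ids) & set(test_ids):
        raise ValueError("train/test ids overlap: leakage")
    missing = [s for s in train_ids + test_ids if s not in samples]
    if missing:
        raise ValueError(f"unknown sample ids: {missing}")
    segment = segmenter_factory([samples[s] for s in train_ids], seed)
    rows, per_fold = [], []
    for sid in test_ids:
        cube, labels = samples[sid]
        result = segment(cube)
        report = evaluate_segmentation(result, labels,
                                       foreground_only=foreground_only)
        rows.append({"sample_id": sid, **report.as_dict()})
        per_fold.append(report.as_dict())
    return pd.DataFrame(rows), _aggregate(per_fold)
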