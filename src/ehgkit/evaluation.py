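"""Classifier evaluation: confusion matrix, sensitivity/specificity/accuracy,
ROC/AUC, and the three-model comparison report.

Labor is the positive class throughout: sensitivity is the fraction of labor
samples recognised, specificity the fraction of pregnancy samples recognised,

    sensitivity = TP / (TP + FN)
    specificity = TN / (TN + FP)
    accuracy    = (TP + TN) / (TP + TN + FP + FN).

The ROC curve sweeps a threshold over the continuous labor scores (ties
grouped) and the AUC is the trapezoidal area under it.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .autoencoder import SAEHyperParams, SSAEModel, train_ssae
from .baselines import train_elm, train_svm_rbf
from .features import FeatureTable, apply_normalizer, fit_normalizer

__all__ = [
    "EvalReport",
    "confusion",
    "metrics",
    "roc_auc",
    "evaluate_scores",
    "split_per_class",
    "compare_classifiers",
]

_LABEL_TO_INT = {"pregnancy": 0, "labor": 1, 0: 0, 1: 1}


def _as_int_labels(y) -> np.ndarray:
    try:
        return np.array([_LABEL_TO_INT[v] for v in np.asarray(y).tolist()])
    except KeyError as exc:
        raise ValueError(f"unknown class label {exc.args[0]!r}") from exc


def confusion(y_true, y_pred) -> Tuple[int, int, int, int]:
    """(TP, FN, TN, FP) counts with labor (1) as the positive class."""
    t = _as_int_labels(y_true)
    p = _as_int_labels(y_pred)
    if t.size != p.size:
        raise ValueError("y_true and y_pred must have equal length")
    tp = int(np.sum((t == 1) & (p == 1)))
    fn = int(np.sum((t == 1) & (p == 0)))
    tn = int(np.sum((t == 0) & (p == 0)))
    fp = int(np.sum((t == 0) & (p == 1)))
    return tp, fn, tn, fp


def metrics(tp: int, fn: int, tn: int, fp: int) -> Tuple[float, float, float]:
    """(sensitivity, specificity, accuracy) via exact rational arithmetic.

    A zero denominator yields NaN for that metric rather than raising, so
    degenerate test sets are flagged instead of crashing batch evaluation.
    """
    if min(tp, fn, tn, fp) < 0:
        raise ValueError("confusion counts must be non-negative")

    def ratio(num: int, den: int) -> float:
        return float(Fraction(num, den)) if den > 0 else math.nan

    sens = ratio(tp, tp + fn)
    spec = ratio(tn, tn + fp)
    acc = ratio(tp + tn, tp + tn + fp + fn)
    return sens, spec, acc


def roc_auc(y_true, scores) -> Tuple[np.ndarray, float]:
    """ROC points and trapezoidal AUC from continuous labor scores.

    The threshold sweeps the unique score values in descending order, tied
    scores moving together, so the curve runs from (0, 0) to (1, 1).
    """
    t = _as_int_labels(y_true)
    s = np.asarray(scores, dtype=np.float64)
    n_pos = int(np.sum(t == 1))
    n_neg = int(np.sum(t == 0))
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC needs both classes in y_true")
    order = np.argsort(-s, kind="stable")
    t_sorted = t[order]
    s_sorted = s[order]
    # cumulative counts at the end of each tie group
    distinct = np.where(np.diff(s_sorted) != 0)[0]
    boundaries = np.r_[distinct, s_sorted.size - 1]
    tp_cum = np.cumsum(t_sorted == 1)[boundaries]
    fp_cum = np.cumsum(t_sorted == 0)[boundaries]
    tpr = np.r_[0.0, tp_cum / n_pos]
    fpr = np.r_[0.0, fp_cum / n_neg]
    auc = float(np.trapezoid(tpr, fpr))
    points = np.column_stack([fpr, tpr])
    return points, auc


@dataclass
class EvalReport:
    """Counts, rates and ROC summary for one classifier on one test set."""

    tp: int
    fn: int
    tn: int
    fp: int
    sensitivity: float
    specificity: float
    accuracy: float
    auc: float = math.nan
    roc_points: Optional[np.ndarray] = None
    positive_class: str = "labor"

    def as_dict(self) -> Dict:
        return {
            "tp": self.tp,
            "fn": self.fn,
            "tn": self.tn,
            "fp": self.fp,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "accuracy": self.accuracy,
            "auc": self.auc,
            "positive_class": self.positive_class,
        }

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.as_dict(), indent=1))


def evaluate_scores(y_true, y_pred, scores=None) -> EvalReport:
    """Assemble a full report from predictions (and optional ROC scores)."""
    tp, fn, tn, fp = confusion(y_true, y_pred)
    sens, spec, acc = metrics(tp, fn, tn, fp)
    auc = math.nan
    points = None
    if scores is not None:
        points, auc = roc_auc(y_true, scores)
    return EvalReport(
        tp=tp, fn=fn, tn=tn, fp=fp,
        sensitivity=sens, specificity=spec, accuracy=acc,
        auc=auc, roc_points=points,
    )


def split_per_class(
    labels: Sequence[str], n_train: int = 100, n_test: int = 50, seed: int = 0
) -> Tuple[np.ndarray, np.ndarray]:
    """Seeded per-class random split (default 100 train / 50 test per class).

    Returns (train_idx, test_idx) into the label sequence.  Raises when a
    class has fewer than n_train + n_test members.
    """
    y = _as_int_labels(labels)
    rng = np.random.default_rng(seed)
    train_idx: List[int] = []
    test_idx: List[int] = []
    for cls in (0, 1):
        members = np.where(y == cls)[0]
        if members.size < n_train + n_test:
            raise ValueError(
                f"class {cls} has {members.size} samples; "
                f"need {n_train + n_test} for the split"
            )
        perm = rng.permutation(members)
        train_idx.extend(perm[:n_train])
        test_idx.extend(perm[n_train : n_train + n_test])
    return np.array(sorted(train_idx)), np.array(sorted(test_idx))


def compare_classifiers(
    table: FeatureTable,
    n_train: int = 100,
    n_test: int = 50,
    split_seed: int = 0,
    model_seed: int = 0,
    ssae_kwargs: Optional[Dict] = None,
    normalization: str = "train",
) -> Dict[str, EvalReport]:
    """Train SSAE, ELM and RBF-SVM on one shared split and evaluate all three.

    All models see the identical normalised feature matrices (min-max state
    learned on the training split, or on the full table when
    ``normalization="global"``).  Deterministic given the two seeds.
    """
    train_idx, test_idx = split_per_class(table.labels, n_train, n_test, split_seed)
    train = table.subset(train_idx)
    test = table.subset(test_idx)
    norm = fit_normalizer(table if normalization == "global" else train)
    Xtr = apply_normalizer(train, norm).X
    Xte = apply_normalizer(test, norm).X
    ytr = train.y()
    yte = test.y()

    ssae = train_ssae(Xtr, ytr, seed=model_seed, **(ssae_kwargs or {}))
    elm = train_elm(Xtr, ytr, seed=model_seed)
    svm = train_svm_rbf(Xtr, ytr)

    return {
        "SSAE": evaluate_scores(yte, ssae.predict(Xte), ssae.decision_scores(Xte)),
        "ELM": evaluate_scores(yte, elm.predict(Xte), elm.decision_scores(Xte)),
        "SVM": evaluate_scores(yte, svm.predict(Xte), svm.decision_scores(Xte)),
    }


def report_frame(reports: Dict[str, EvalReport]) -> pd.DataFrame:
    """Comparison table: one row per model, the four headline indexes."""
    return pd.DataFrame(
        {
            name: {
                "accuracy": r.accuracy,
                "sensitivity": r.sensitivity,
                "specificity": r.specificity,
                "auc": r.auc,
            }
            for name, r in reports.items()
        }
    ).T
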