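"""Evaluation metrics, ranking analysis, and method-comparison statistics.

The metric suite follows the reporting convention of the multi-class DDI
event-prediction literature: accuracy, F1 (macro by default, micro also
available), and micro-averaged ROC-AUC / AUPR computed over the flattened
instance x class indicator/score matrices.  Method comparison across CV
folds uses a two-sided paired t-test and classical one-way ANOVA at
alpha = 0.05.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import (
    accuracy_score,
    average_precision_score,
    f1_score,
    roc_auc_score,
)

logger = logging.getLogger(__name__)

ALPHA = 0.05

METRIC_COLUMNS = ["ACC", "F1", "AUC", "AUPR"]


def _check_nonempty(y_true: np.ndarray) -> None:
    if len(y_true) == 0:
        raise ValueError("empty input")


def accuracy(y_true: Sequence[int], y_pred: Sequence[int]) -> float:
    """Fraction of exact label matches."""
    y_true = np.asarray(y_true)
    _check_nonempty(y_true)
    return float(accuracy_score(y_true, np.asarray(y_pred)))


def f1_multiclass(
    y_true: Sequence[int],
    y_pred: Sequence[int],
    averaging: str = "macro",
    n_classes: int | None = None,
) -> float:
    """Per-class one-vs-rest F1 aggregated by macro (default) or micro.

    Under macro averaging, classes absent from both truth and prediction
    contribute 0 (logged), matching a fixed-denominator mean over all E
    classes.
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    _check_nonempty(y_true)
    if averaging not in ("macro", "micro"):
        raise ValueError("averaging must be 'macro' or 'micro'")
    if n_classes is not None:
        labels = np.arange(n_classes)
        present = np.union1d(np.unique(y_true), np.unique(y_pred))
        if averaging == "macro" and present.size < n_classes:
            logger.info(
                "%d of %d classes absent from truth and prediction; they contribute 0 to macro F1",
                n_classes - present.size,
                n_classes,
            )
    else:
        labels = np.union1d(np.unique(y_true), np.unique(y_pred))
    return float(f1_score(y_true, y_pred, labels=labels, average=averaging, zero_division=0))


def onehot(y: Sequence[int], n_classes: int) -> np.ndarray:
    y = np.asarray(y, dtype=np.int64)
    out = np.zeros((len(y), n_classes), dtype=np.int64)
    out[np.arange(len(y)), y] = 1
    return out


def _flatten_for_micro(y_true_onehot: np.ndarray, scores: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    y = np.asarray(y_true_onehot).ravel()
    s = np.asarray(scores, dtype=np.float64).ravel()
    if y.shape != s.shape:
        raise ValueError(f"shape mismatch: truth {y_true_onehot.shape} vs scores {scores.shape}")
    if y.min() == y.max():
        raise ValueError("micro-averaged ranking metrics need both positive and negative entries")
    return y, s

def auc_micro(y_true_onehot: np.ndarray, scores: np.ndarray) -> float:
    """ROC AUC over the flattened instance x class matrix."""
    y, s = _flatten_for_micro(y_true_onehot, scores)
    return float(roc_auc_score(y, s))


def aupr_micro(y_true_onehot: np.ndarray, scores: np.ndarray) -> float:
    """Area under precision-recall over the flattened matrix.

    Uses step integration (the average-precision form), not trapezoids.
    """
    y, s = _flatten_for_micro(y_true_onehot, scores)
    return float(average_precision_score(y, s))


def precision_at_k(y_true: Sequence[int], scores: np.ndarray, k: int) -> float:
    """Fraction of the top-k highest-confidence predictions that are correct.

    Records are ranked by their maximum class score, descending; ties break
    by record index for determinism.  A record counts as correct when its
    argmax class equals the true label.  At k = n this equals accuracy.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    y_true = np.asarray(y_true)
    scores = np.asarray(scores, dtype=np.float64)
    _check_nonempty(y_true)
    k = min(k, len(y_true))
    top_score = scores.max(axis=1)
    order = np.lexsort((np.arange(len(y_true)), -top_score))  # score desc, index asc
    chosen = order[:k]
    correct = scores[chosen].argmax(axis=1) == y_true[chosen]
    return float(correct.mean())


def paired_t_test(metric_a: Sequence[float], metric_b: Sequence[float]) -> tuple[float, float]:
    """Two-sided paired t-test over matched per-fold metrics.

    Degenerate cases: all differences zero -> (0, 1); zero-variance nonzero
    differences -> (signed inf, 0) with a warning.
    """
    a = np.asarray(metric_a, dtype=np.float64)
    b = np.asarray(metric_b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    if a.size < 2:
        raise ValueError("need at least 2 paired observations")
    d = a - b
    if np.allclose(d.std(ddof=1), 0.0):
        if np.allclose(d.mean(), 0.0):
            return 0.0, 1.0
        logger.warning("zero-variance nonzero differences; t -> inf, p -> 0")
        return float(np.sign(d.mean()) * np.inf), 0.0
    t, p = stats.ttest_rel(a, b)
    return float(t), float(p)


def anova_oneway(*groups: Sequence[float]) -> tuple[float, float]:
    """Classical one-way ANOVA F statistic and p-value across groups.

    All values identical across all groups leaves F undefined (0/0);
    returns (0, 1) with a warning.
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    arrays = [np.asarray(g, dtype=np.float64) for g in groups]
    if any(a.size < 2 for a in arrays):
        raise ValueError("each group needs at least 2 observations")
    allvals = np.concatenate(arrays)
    if np.allclose(allvals, allvals[0]):
        logger.warning("all observations identical; F undefined, reporting 0")
        return 0.0, 1.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        f, p = stats.f_oneway(*arrays)
    if not np.isfinite(f):
        logger.warning("degenerate ANOVA (zero within-group variance); F undefined, reporting 0")
        return 0.0, 1.0
    return float(f), float(p)


def evaluate_fold(
    y_true: np.ndarray,
    proba: np.ndarray,
    n_classes: int,
    f1_averaging: str = "macro",
) -> dict[str, float]:
    """The standard four-column metric row for one evaluation split."""
    y_pred = proba.argmax(axis=1)
    return {
        "ACC": accuracy(y_true, y_pred),
        "F1": f1_multiclass(y_true, y_pred, averaging=f1_averaging, n_classes=n_classes),
        "AUC": auc_micro(onehot(y_true, n_classes), proba),
        "AUPR": aupr_micro(onehot(y_true, n_classes), proba),
    }


@dataclass
class EvalReport:
    """Per-fold metric rows for one (model, feature set) configuration."""

    model_label: str
    feature_label: str
    rows: list[dict[str, float]] = field(default_factory=list)
    seed: int | None = None
    metric: str = "jaccard"

    def add(self, row: dict[str, float]) -> None:
        self.rows.append(dict(row))

    def frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(self.rows, columns=METRIC_COLUMNS)
        frame.insert(0, "fold", range(len(frame)))
        return frame

    def mean(self) -> dict[str, float]:
        frame = pd.DataFrame(self.rows, columns=METRIC_COLUMNS)
        return {c: float(frame[c].mean()) for c in METRIC_COLUMNS}

    def column(self, name: str) -> np.ndarray:
        return np.array([row[name] for row in self.rows], dtype=np.float64)


def render_table(reports: Sequence[EvalReport], label_header: str = "Model") -> str:
    """Plain-text summary table in the conventional ACC F1 AUC AUPR order."""
    width = max([len(label_header)] + [len(r.model_label) for r in reports]) + 2
    lines = [f"{label_header:<{width}}" + "".join(f"{c:>10}" for c in METRIC_COLUMNS)]
    for report in reports:
        mean = report.mean()
        lines.append(
            f"{report.model_label:<{width}}"
            + "".join(f"{mean[c]:>10.4f}" for c in METRIC_COLUMNS)
        )
    return "\n".join(lines)


def reports_frame(reports: Sequence[EvalReport]) -> pd.DataFrame:
    """Long frame of all per-fold rows, for delimited-text export."""
    frames = []
    for report in reports:
        frame = report.frame()
        frame.insert(0, "model", report.model_label)
        frame.insert(1, "features", report.feature_label)
        frames.append(frame)
    return pd.concat(frames, ignore_index=True)
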