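"""Confusion-matrix metrics, ROC/AUC and the normalized-rank cutoff.

The positive class is *enlargement* (label 1, infarct growth). Rates are
computed exactly from integer counts; AUC follows the Mann-Whitney rank-sum
convention with half credit for ties. Metrics whose denominator is zero are
reported as ``None`` (an explicit undefined marker), never silently 0.
The printed report rounds to 3 decimals (round-half-even); stored values
keep full precision.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, asdict, field

import numpy as np
from scipy.stats import rankdata

__all__ = [
    "ConfusionMatrix",
    "MetricsReport",
    "confusion",
    "metrics",
    "roc_auc",
    "normalized_rank_cutoff",
    "evaluate_model",
]


@dataclass(frozen=True)
class ConfusionMatrix:
    """2x2 counts; positive class = enlargement."""

    tp: int
    fn: int
    fp: int
    tn: int

    def __post_init__(self):
        for name in ("tp", "fn", "fp", "tn"):
            v = getattr(self, name)
            if not (isinstance(v, (int, np.integer)) and v >= 0):
                raise ValueError(f"{name} must be a non-negative integer")
        if self.n == 0:
            raise ValueError("confusion matrix must contain at least one case")

    @property
    def n(self) -> int:
        return self.tp + self.fn + self.fp + self.tn


@dataclass(frozen=True)
class MetricsReport:
    """Rates derived from a confusion matrix; None marks an undefined rate."""

    acc: float
    err: float
    sen: float | None
    spe: float | None
    ppv: float | None
    npv: float | None
    mcc: float | None
    f_score: float | None
    auc: float | None = None

    def rounded(self, ndigits: int = 3) -> dict:
        """Display form: 3-decimal round-half-even, None preserved."""
        out = {}
        for k, v in asdict(self).items():
            out[k] = None if v is None else float(round(v, ndigits))
        return out


def confusion(labels, predictions) -> ConfusionMatrix:
    labels = np.asarray(labels, dtype=int)
    predictions = np.asarray(predictions, dtype=int)
    if labels.size == 0 or labels.shape != predictions.shape:
        raise ValueError("labels and predictions must be equal-length and non-empty")
    if not (np.isin(labels, (0, 1)).all() and np.isin(predictions, (0, 1)).all()):
        raise ValueError("labels and predictions must be binary 0/1")
    return ConfusionMatrix(
        tp=int(((labels == 1) & (predictions == 1)).sum()),
        fn=int(((labels == 1) & (predictions == 0)).sum()),
        fp=int(((labels == 0) & (predictions == 1)).sum()),
        tn=int(((labels == 0) & (predictions == 0)).sum()),
    )


def _ratio(num: int, den: int) -> float | None:
    return None if den == 0 else num / den


def metrics(cm: ConfusionMatrix, auc: float | None = None) -> MetricsReport:
    """Standard 2x2 rates; F-score is F1 on the positive class."""
    tp, fn, fp, tn = cm.tp, cm.fn, cm.fp, cm.tn
    acc = (tp + tn) / cm.n
    sen = _ratio(tp, tp + fn)
    spe = _ratio(tn, tn + fp)
    ppv = _ratio(tp, tp + fp)
    npv = _ratio(tn, tn + fn)
    denom2 = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = None if denom2 == 0 else (tp * tn - fp * fn) / math.sqrt(denom2)
    if ppv is None or sen is None or (ppv + sen) == 0:
        f_score = None
    else:
        f_score = 2 * ppv * sen / (ppv + sen)
    return MetricsReport(acc=acc, err=1.0 - acc, sen=sen, spe=spe, ppv=ppv,
                         npv=npv, mcc=mcc, f_score=f_score, auc=auc)


def roc_auc(scores, labels):
    """Mann-Whitney AUC (ties get half credit) plus ROC curve points.

    Returns ``(auc, fpr, tpr, thresholds)``; the curve enumerates every
    distinct-score operating point.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC needs both classes present")
    ranks = rankdata(scores)  # average ranks on ties
    auc = (ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)

    from sklearn.metrics import roc_curve

    fpr, tpr, thresholds = roc_curve(labels, scores)
    return float(auc), fpr, tpr, thresholds


def normalized_ranks(scores) -> np.ndarray:
    """Scores mapped to (0, 1]: average ranks for ties, divided by n."""
    scores = np.asarray(scores, dtype=float)
    return rankdata(scores) / scores.size


@dataclass(frozen=True)
class CutoffResult:
    level: float
    accuracy: float
    norm_ranks: np.ndarray = field(repr=False)
    levels: np.ndarray = field(repr=False)
    accuracies: np.ndarray = field(repr=False)
    constant_scores: bool = False


def normalized_rank_cutoff(scores, labels) -> CutoffResult:
    """Choose the normalized-rank level that maximizes training accuracy.

    Scores are mapped to normalized ranks; a case is called enlargement when
    its normalized rank is >= the level. Candidate levels are the midpoints
    between consecutive distinct normalized ranks plus the two extremes
    (equivalent to exhaustive thresholding); accuracy ties resolve to the
    lowest level. The returned scatter data (rank vs label, accuracy per
    level) supports the truncation-value plot.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.size < 2 or scores.shape != labels.shape:
        raise ValueError("need >= 2 scores with matching labels")
    nr = normalized_ranks(scores)
    uniq = np.unique(nr)
    if uniq.size == 1:
        warnings.warn("constant scores: no informative cutoff, returning 0.5",
                      stacklevel=2)
        acc = max(labels.mean(), 1 - labels.mean())
        return CutoffResult(level=0.5, accuracy=float(acc), norm_ranks=nr,
                            levels=np.array([0.5]), accuracies=np.array([acc]),
                            constant_scores=True)
    mids = (uniq[:-1] + uniq[1:]) / 2
    levels = np.concatenate([[0.0], mids, [1.0 + 1e-12]])
    accs = np.array([( (nr >= lv).astype(int) == labels).mean() for lv in levels])
    best = int(np.argmax(accs))  # argmax takes the first (lowest) level on ties
    return CutoffResult(level=float(levels[best]), accuracy=float(accs[best]),
                        norm_ranks=nr, levels=levels, accuracies=accs)


def evaluate_model(scores, labels, cutoff: float | None = None):
    """Threshold scores at a normalized-rank level and report all metrics.

    ``cutoff`` is a level in [0, 1]; when None it is chosen on these scores
    by :func:`normalized_rank_cutoff`. Returns ``(MetricsReport,
    ConfusionMatrix)``; the report includes the Mann-Whitney AUC.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if cutoff is None:
        cutoff = normalized_rank_cutoff(scores, labels).level
    preds = (normalized_ranks(scores) >= cutoff).astype(int)
    cm = confusion(labels, preds)
    auc, *_ = roc_auc(scores, labels)
    return metrics(cm, auc=auc), cm
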