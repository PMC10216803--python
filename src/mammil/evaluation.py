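"""Classification metrics, ROC analysis, and cross-validation aggregation.

Accuracy, precision, recall and F1 are computed from the confusion counts,

    accuracy  = (TP + TN) / (TP + TN + FP + FN)
    precision = TP / (TP + FP)
    recall    = TP / (TP + FN)
    F1        = 2 TP / (2 TP + FP + FN)

AUC-ROC is the Mann-Whitney pair statistic (ties get half credit), and the
operating threshold can be optimised by maximising the Youden index
J = sensitivity + specificity - 1 over score midpoints. The prediction rule
is strict: a case is called cancer only when its score *exceeds* the
threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    TN: int
    FP: int
    FN: int

    def __post_init__(self) -> None:
        if min(self.TP, self.TN, self.FP, self.FN) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN


def _check(scores, labels) -> tuple[np.ndarray, np.ndarray]:
    scores = np.asarray(scores, dtype=np.float64).ravel()
    labels = np.asarray(labels, dtype=int).ravel()
    if scores.size == 0:
        raise ValueError("empty score list")
    if scores.shape != labels.shape:
        raise ValueError("scores and labels differ in length")
    if not set(labels.tolist()) <= {0, 1}:
        raise ValueError("labels must be binary {0, 1}")
    return scores, labels


def confusion(scores, labels, threshold: float = 0.5) -> ConfusionCounts:
    """Tally confusion counts with the strict rule ``pred = score > threshold``.

    A score exactly at the threshold is predicted non-cancer.
    """
    scores, labels = _check(scores, labels)
    pred = scores > threshold
    pos = labels == 1
    return ConfusionCounts(
        TP=int(np.sum(pred & pos)),
        TN=int(np.sum(~pred & ~pos)),
        FP=int(np.sum(pred & ~pos)),
        FN=int(np.sum(~pred & pos)),
    )


def metrics_from_counts(c: ConfusionCounts, warn_on_zero_division: bool = True) -> dict[str, float]:
    """Accuracy, precision, recall, F1 from confusion counts.

    A zero denominator yields 0.0 for that metric (with a warning) so fold
    aggregation stays total on degenerate folds.
    """

    def _ratio(num: int, den: int, name: str) -> float:
        if den == 0:
            if warn_on_zero_division:
                warnings.warn(f"{name}: zero denominator, reporting 0.0", stacklevel=3)
            return 0.0
        return num / den

    return {
        "accuracy": _ratio(c.TP + c.TN, c.total, "accuracy"),
        "precision": _ratio(c.TP, c.TP + c.FP, "precision"),
        "recall": _ratio(c.TP, c.TP + c.FN, "recall"),
        "f1": _ratio(2 * c.TP, 2 * c.TP + c.FP + c.FN, "f1"),
    }


def roc_auc(scores, labels) -> float:
    """AUC-ROC as the Mann-Whitney statistic.

    Equals P(score_pos > score_neg) + 0.5 P(score_pos = score_neg) over all
    positive-negative pairs; midranks make this O(n log n) and exact,
    including ties.
    """
    scores, labels = _check(scores, labels)
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC requires both classes present")
    ranks = rankdata(scores)  # midranks
    rank_sum_pos = float(ranks[labels == 1].sum())
    return (rank_sum_pos - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)


def youden_threshold(scores, labels) -> tuple[float, float]:
    """Threshold maximising Youden's J = sensitivity + specificity - 1.

    Candidates are the midpoints between consecutive distinct sorted scores
    plus one sentinel below the minimum and one above the maximum (predict
    all / none). Ties in J resolve to the smallest threshold. Returns
    ``(threshold, J)``.
    """
    scores, labels = _check(scores, labels)
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("threshold optimisation requires both classes present")
    uniq = np.unique(scores)
    candidates = np.concatenate(
        [[uniq[0] - 1.0], (uniq[:-1] + uniq[1:]) / 2.0, [uniq[-1] + 1.0]]
    )
    best_t, best_j = candidates[0], -np.inf
    for t in candidates:
        pred = scores > t
        sens = np.sum(pred & (labels == 1)) / n_pos
        spec = np.sum(~pred & (labels == 0)) / n_neg
        j = sens + spec - 1.0
        if j > best_j + 1e-15:
            best_t, best_j = float(t), float(j)
    return best_t, best_j


@dataclass
class MetricsReport:
    """Per-evaluation metric bundle at a given operating threshold."""

    counts: ConfusionCounts
    accuracy: float
    precision: float
    recall: float
    f1: float
    auc_roc: float
    threshold: float

    @classmethod
    def from_scores(cls, scores, labels, threshold: float = 0.5) -> "MetricsReport":
        c = confusion(scores, labels, threshold)
        m = metrics_from_counts(c, warn_on_zero_division=False)
        return cls(counts=c, auc_roc=roc_auc(scores, labels), threshold=threshold, **m)

    def as_dict(self) -> dict[str, float]:
        return {
            "accuracy": self.accuracy,
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
            "auc_roc": self.auc_roc,
            "threshold": self.threshold,
        }


METRIC_KEYS = ("accuracy", "precision", "recall", "f1", "auc_roc")


def aggregate_cv(per_fold: list[MetricsReport]) -> dict[str, dict[str, float]]:
    """Mean and sample (n-1) standard deviation of each metric across folds.

    Returned as ``{metric: {"mean": .., "std": .., "per_fold": [..]}}``;
    the presentation convention is AUC to 3 decimals and percentage metrics
    to 1 decimal (see :func:`format_cv_table`).
    """
    if len(per_fold) < 2:
        raise ValueError("aggregation needs at least 2 folds")
    out = {}
    for key in METRIC_KEYS:
        vals = np.array([getattr(r, key) for r in per_fold], dtype=np.float64)
        out[key] = {
            "mean": float(vals.mean()),
            "std": float(vals.std(ddof=1)),
            "per_fold": [float(v) for v in vals],
        }
    return out


def format_cv_table(agg: dict[str, dict[str, float]]) -> str:
    """Render the aggregate as ``mean ± std`` rows (AUC 3 d.p., rest in %)."""
    lines = []
    for key in METRIC_KEYS:
        m, s = agg[key]["mean"], agg[key]["std"]
        if key == "auc_roc":
            lines.append(f"AUC-ROC    {m:.3f} ± {s:.3f}")
        else:
            lines.append(f"{key:<9}  {100 * m:.1f} ± {100 * s:.1f} %")
    return "\n".join(lines)
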