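"""Confusion metrics, ROC/PR AUC with bootstrap CIs, and the equalized-odds
disparity objective.

The disparity Z between two groups at a classification threshold is

    Z = |recall_a - recall_b| + |specificity_a - specificity_b|

in percentage points. Under equality of odds, a predictor's true-positive
and false-positive rates are independent of group membership, which is
exactly Z = 0; Z is the objective the threshold-moving mitigation search
minimizes.

All rates are computed on proportions internally and scaled to percentages
only at the reporting boundary. Undefined metrics (zero denominators) are
reported as ``None``, never silently as 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Optional, Sequence

import numpy as np
import sklearn.metrics as skm

from .cohort import GroupSpec

__all__ = [
    "ScoredPredictions",
    "ConfusionCounts",
    "GroupPerformance",
    "MetricUndefinedError",
    "confusion_at_threshold",
    "classification_metrics",
    "roc_auc",
    "pr_auc",
    "bootstrap_ci",
    "disparity",
    "disparity_pvalue",
    "round_half_up",
]


class MetricUndefinedError(ValueError):
    """A requested metric has a zero denominator."""


def round_half_up(x: float, decimals: int = 2) -> float:
    """Round half away from zero, the convention used in reported tables."""
    factor = 10.0**decimals
    return float(np.sign(x) * np.floor(abs(x) * factor + 0.5) / factor)


@dataclass
class ScoredPredictions:
    """Risk scores aligned with outcome labels and optional group labels.

    ``groups`` holds 'a'/'b' analysis-group assignments (empty string =
    excluded from the two-group analysis), as produced by
    :meth:`fairmove.cohort.Cohort.groups`.
    """

    scores: np.ndarray
    labels: np.ndarray
    groups: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.scores.shape != self.labels.shape:
            raise ValueError("scores and labels must have equal length")
        if not np.isin(self.labels, [0, 1]).all():
            raise ValueError("labels must be binary 0/1")
        if np.nanmin(self.scores, initial=0.0) < 0 or np.nanmax(self.scores, initial=0.0) > 1:
            raise ValueError("scores must lie in [0,1]")
        if self.groups is not None:
            self.groups = np.asarray(self.groups, dtype=object)
            if self.groups.shape != self.labels.shape:
                raise ValueError("groups must align with labels")

    def __len__(self) -> int:
        return len(self.labels)

    def for_group(self, g: str) -> "ScoredPredictions":
        if self.groups is None:
            raise ValueError("no group labels attached")
        mask = self.groups == g
        return ScoredPredictions(self.scores[mask], self.labels[mask])

    def analyzed(self) -> "ScoredPredictions":
        """Restrict to records assigned to either analysis group."""
        if self.groups is None:
            return self
        mask = (self.groups == "a") | (self.groups == "b")
        return ScoredPredictions(self.scores[mask], self.labels[mask], self.groups[mask])


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fn: int
    fp: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.fp, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.fp + self.tn


def confusion_at_threshold(pred: ScoredPredictions, threshold: float) -> ConfusionCounts:
    """Classify positive iff ``score * 100 >= threshold`` (threshold on the
    0-100 percent scale; threshold 0 labels every record positive)."""
    if len(pred) == 0:
        raise ValueError("empty predictions")
    if not 0.0 <= threshold <= 100.0:
        raise ValueError(f"threshold must be in [0,100], got {threshold}")
    yhat = pred.scores * 100.0 >= threshold
    y = pred.labels.astype(bool)
    return ConfusionCounts(
        tp=int(np.sum(yhat & y)),
        fn=int(np.sum(~yhat & y)),
        fp=int(np.sum(yhat & ~y)),
        tn=int(np.sum(~yhat & ~y)),
    )


def classification_metrics(c: ConfusionCounts) -> dict[str, Optional[float]]:
    """Recall, specificity, accuracy, and precision as percentages.

    A metric whose denominator is zero is returned as ``None``.
    """

    def rate(num: int, den: int) -> Optional[float]:
        return 100.0 * num / den if den > 0 else None

    return {
        "recall": rate(c.tp, c.tp + c.fn),
        "specificity": rate(c.tn, c.tn + c.fp),
        "accuracy": rate(c.tp + c.tn, c.total),
        "precision": rate(c.tp, c.tp + c.fp),
    }


def roc_auc(pred: ScoredPredictions) -> float:
    """ROC AUC: probability a random positive outscores a random negative
    (ties counted 1/2)."""
    if pred.labels.min() == pred.labels.max():
        raise ValueError("roc_auc requires both classes present")
    return float(skm.roc_auc_score(pred.labels, pred.scores))


def pr_auc(pred: ScoredPredictions) -> float:
    """Area under the precision-recall step curve (average precision)."""
    if pred.labels.min() == pred.labels.max():
        raise ValueError("pr_auc requires both classes present")
    return float(skm.average_precision_score(pred.labels, pred.scores))


def bootstrap_ci(
    metric_fn: Callable[[ScoredPredictions], float],
    pred: ScoredPredictions,
    n_boot: int = 2000,
    level: float = 0.95,
    seed: int = 0,
) -> tuple[float, float]:
    """Percentile bootstrap interval with class-stratified resampling.

    Resamples positives and negatives separately (preserving class counts).
    A resample on which ``metric_fn`` raises is redrawn; the redraw count is
    recorded on the function attribute ``bootstrap_ci.last_redraws``.
    """
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    if not 0.0 < level < 1.0:
        raise ValueError("level must be in (0,1)")
    rng = np.random.default_rng(seed)
    pos = np.flatnonzero(pred.labels == 1)
    neg = np.flatnonzero(pred.labels == 0)
    stats = np.empty(n_boot)
    redraws = 0
    for b in range(n_boot):
        while True:
            idx = np.concatenate(
                [
                    rng.choice(pos, size=len(pos), replace=True) if len(pos) else [],
                    rng.choice(neg, size=len(neg), replace=True) if len(neg) else [],
                ]
            ).astype(int)
            resample = ScoredPredictions(
                pred.scores[idx],
                pred.labels[idx],
                None if pred.groups is None else pred.groups[idx],
            )
            try:
                stats[b] = metric_fn(resample)
                break
            except (ValueError, ZeroDivisionError):
                redraws += 1
                if redraws > 100 * n_boot:
                    raise MetricUndefinedError(
                        "metric undefined on essentially every resample"
                    )
    bootstrap_ci.last_redraws = redraws  # type: ignore[attr-defined]
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(stats, [alpha, 1.0 - alpha])
    return float(lo), float(hi)


def _require(metrics: Mapping[str, Optional[float]], keys: Sequence[str], who: str) -> None:
    for k in keys:
        if metrics.get(k) is None:
            raise MetricUndefinedError(f"{k} undefined for group {who!r}")


def disparity(
    metrics_a: Mapping[str, Optional[float]], metrics_b: Mapping[str, Optional[float]]
) -> float:
    """Equalized-odds disparity Z in percentage points:
    ``|recall_a - recall_b| + |specificity_a - specificity_b|``."""
    _require(metrics_a, ("recall", "specificity"), "a")
    _require(metrics_b, ("recall", "specificity"), "b")
    return abs(metrics_a["recall"] - metrics_b["recall"]) + abs(
        metrics_a["specificity"] - metrics_b["specificity"]
    )


def _group_z(pred: ScoredPredictions, threshold: float) -> float:
    ma = classification_metrics(confusion_at_threshold(pred.for_group("a"), threshold))
    mb = classification_metrics(confusion_at_threshold(pred.for_group("b"), threshold))
    return disparity(ma, mb)


def disparity_pvalue(
    pred: ScoredPredictions,
    spec: GroupSpec,
    threshold: float = 50.0,
    n_perm: int = 2000,
    seed: int = 0,
) -> float:
    """Class-stratified permutation p-value for the observed disparity Z.

    Group labels are permuted within each outcome class (preserving each
    group's class composition margins under the null of no group effect);
    the p-value is the proportion of permutations, including the identity,
    with Z at least the observed value.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    p = pred.analyzed()
    for g in ("a", "b"):
        sub = p.for_group(g)
        if len(sub) == 0 or sub.labels.min() == sub.labels.max():
            raise MetricUndefinedError(
                f"group {g!r} of {spec.attribute!r} must contain both classes"
            )
    observed = _group_z(p, threshold)
    rng = np.random.default_rng(seed)
    groups = np.asarray(p.groups, dtype=object)
    hits = 0
    perm_groups = groups.copy()
    class_idx = [np.flatnonzero(p.labels == c) for c in (0, 1)]
    for _ in range(n_perm):
        for idx in class_idx:
            perm_groups[idx] = groups[idx][rng.permutation(len(idx))]
        z = _group_z(
            ScoredPredictions(p.scores, p.labels, perm_groups.copy()), threshold
        )
        if z >= observed - 1e-12:
            hits += 1
    return (hits + 1) / (n_perm + 1)


@dataclass
class GroupPerformance:
    """Per-group confusion metrics and AUC for one attribute partition."""

    attribute: str
    threshold: float
    per_group: dict[str, dict[str, Optional[float]]] = field(default_factory=dict)
    disparity_z: Optional[float] = None
    auc_gap: Optional[float] = None
    p_value: Optional[float] = None

    def as_rows(self) -> list[dict]:
        """Rows mirroring the published table layout (one per group)."""
        rows = []
        for g, m in self.per_group.items():
            rows.append(
                {
                    "attribute": self.attribute,
                    "group": g,
                    **{k: (None if v is None else round_half_up(v)) for k, v in m.items()},
                    "difference": None
                    if self.disparity_z is None
                    else round_half_up(self.disparity_z),
                    "p_value": self.p_value,
                }
            )
        return rows
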