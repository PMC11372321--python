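"""Equalized-odds bias mitigation by constrained threshold moving.

A score-emitting classifier is post-processed by replacing its default 50%
classification threshold with the grid threshold that minimizes the
two-group disparity

    Z(th) = |recall_a(th) - recall_b(th)| + |specificity_a(th) - specificity_b(th)|

subject to performance floors on the OVERALL test-set recall and accuracy
(defaults 0.70 and 0.50, inclusive comparisons). Thresholds run over the
inclusive grid {0, step, ..., 100} (1001 points at the default step 0.1);
ties in Z are broken toward the lowest threshold. The floors are evaluated
on the whole analyzed test set, not per group, so a group's recall may dip
below the floor at the optimum.

Finding no feasible threshold raises :class:`InfeasibleThresholdError`
carrying the full trace, rather than silently falling back; callers wanting
"best effort under binding constraints" behavior can inspect the trace.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from sklearn.base import BaseEstimator

from .cohort import GroupSpec
from .metrics import (
    ScoredPredictions,
    classification_metrics,
    confusion_at_threshold,
    disparity,
)

__all__ = [
    "SearchConstraints",
    "ThresholdSearchResult",
    "InfeasibleThresholdError",
    "equalized_odds_threshold_search",
    "bias_improvement",
    "EqualizedOddsThreshold",
]


@dataclass(frozen=True)
class SearchConstraints:
    """Performance floors on overall recall and accuracy (proportions)."""

    min_recall: float = 0.70
    min_accuracy: float = 0.50

    def __post_init__(self) -> None:
        for name, v in (("min_recall", self.min_recall), ("min_accuracy", self.min_accuracy)):
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {v}")


@dataclass
class TracePoint:
    threshold: float
    z: float
    overall_recall: float
    overall_accuracy: float
    feasible: bool


@dataclass
class ThresholdSearchResult:
    best_threshold: float
    z_at_best: float
    trace: list[TracePoint]
    constraints: SearchConstraints
    per_group: dict[str, dict[str, Optional[float]]] = field(default_factory=dict)

    def trace_rows(self) -> list[dict]:
        return [
            {
                "threshold": p.threshold,
                "z": p.z,
                "overall_recall": p.overall_recall,
                "overall_accuracy": p.overall_accuracy,
                "feasible": p.feasible,
            }
            for p in self.trace
        ]


class InfeasibleThresholdError(ValueError):
    """No grid threshold satisfied the recall/accuracy floors."""

    def __init__(self, message: str, trace: list[TracePoint]):
        super().__init__(message)
        self.trace = trace


def _counts_by_threshold(scores: np.ndarray, labels: np.ndarray, thresholds: np.ndarray):
    """Vectorized TP/FP counts for every threshold (positive iff
    score*100 >= th). Returns (tp, fp) arrays aligned with thresholds."""
    pct = scores * 100.0
    order = np.argsort(pct, kind="mergesort")
    sorted_pct = pct[order]
    sorted_y = labels[order]
    cum_pos = np.concatenate([[0], np.cumsum(sorted_y)])
    total_pos = cum_pos[-1]
    # records with sorted_pct >= th start at index searchsorted(..., 'left')
    first = np.searchsorted(sorted_pct, thresholds, side="left")
    tp = total_pos - cum_pos[first]
    n_ge = len(pct) - first
    fp = n_ge - tp
    return tp.astype(int), fp.astype(int)


def equalized_odds_threshold_search(
    pred: ScoredPredictions,
    spec: GroupSpec,
    grid_step: float = 0.1,
    constraints: SearchConstraints = SearchConstraints(),
) -> ThresholdSearchResult:
    """Exhaustive constrained search for the disparity-minimizing threshold.

    Evaluates every threshold on the inclusive grid, records the trace, and
    returns the feasible minimizer of Z (lowest threshold on ties).
    """
    if grid_step <= 0:
        raise ValueError("grid_step must be positive")
    p = pred.analyzed()
    if p.groups is None:
        raise ValueError("predictions must carry group labels")
    for g in ("a", "b"):
        sub = p.for_group(g)
        if len(sub) == 0 or sub.labels.min() == sub.labels.max():
            raise ValueError(
                f"group {g!r} of {spec.attribute!r} must contain positives and negatives"
            )

    n_steps = int(round(100.0 / grid_step))
    thresholds = np.round(np.arange(n_steps + 1) * grid_step, 10)
    thresholds = thresholds[thresholds <= 100.0 + 1e-9]

    y = p.labels
    n = len(y)
    n_pos = int(y.sum())
    n_neg = n - n_pos

    tp_all, fp_all = _counts_by_threshold(p.scores, y, thresholds)
    recall_all = tp_all / n_pos
    tn_all = n_neg - fp_all
    accuracy_all = (tp_all + tn_all) / n

    masks = {g: p.groups == g for g in ("a", "b")}
    group_rates = {}
    for g, mask in masks.items():
        yg = y[mask]
        tp_g, fp_g = _counts_by_threshold(p.scores[mask], yg, thresholds)
        pos_g = int(yg.sum())
        neg_g = int(len(yg) - pos_g)
        group_rates[g] = (tp_g / pos_g * 100.0, (neg_g - fp_g) / neg_g * 100.0)

    z = np.abs(group_rates["a"][0] - group_rates["b"][0]) + np.abs(
        group_rates["a"][1] - group_rates["b"][1]
    )
    feasible = (recall_all >= constraints.min_recall) & (
        accuracy_all >= constraints.min_accuracy
    )

    trace = [
        TracePoint(float(t), float(zi), float(r), float(a), bool(f))
        for t, zi, r, a, f in zip(thresholds, z, recall_all, accuracy_all, feasible)
    ]
    if not feasible.any():
        raise InfeasibleThresholdError(
            f"no threshold satisfies recall >= {constraints.min_recall} and "
            f"accuracy >= {constraints.min_accuracy} for {spec.attribute!r}",
            trace,
        )
    z_masked = np.where(feasible, z, np.inf)
    best_idx = int(np.argmin(z_masked))  # argmin takes the first = lowest threshold
    best_th = float(thresholds[best_idx])

    per_group = {}
    for g, label in (("a", spec.label_a), ("b", spec.label_b)):
        m = classification_metrics(confusion_at_threshold(p.for_group(g), best_th))
        per_group[label] = m
    return ThresholdSearchResult(
        best_threshold=best_th,
        z_at_best=float(z[best_idx]),
        trace=trace,
        constraints=constraints,
        per_group=per_group,
    )


def bias_improvement(z_default: float, z_mitigated: float) -> float:
    """Reduction in disparity achieved by mitigation, clamped at zero.

    Reported as percentage points; 0.00 means the constrained optimum did
    not reduce Z below its default-threshold value.
    """
    if z_default < 0 or z_mitigated < 0:
        raise ValueError("disparities must be non-negative")
    return max(z_default - z_mitigated, 0.0)


class EqualizedOddsThreshold(BaseEstimator):
    """Post-processing estimator wrapping the constrained threshold search.

    ``fit`` takes scores, labels and 'a'/'b' group assignments and exposes
    ``best_threshold_``, ``z_``, ``trace_`` and ``per_group_``;
    ``predict`` thresholds new scores at the fitted optimum.
    """

    def __init__(
        self,
        spec: Optional[GroupSpec] = None,
        grid_step: float = 0.1,
        min_recall: float = 0.70,
        min_accuracy: float = 0.50,
    ):
        self.spec = spec
        self.grid_step = grid_step
        self.min_recall = min_recall
        self.min_accuracy = min_accuracy

    def fit(self, scores, labels, groups):
        pred = ScoredPredictions(np.asarray(scores), np.asarray(labels), np.asarray(groups, dtype=object))
        spec = self.spec if self.spec is not None else GroupSpec("attribute", ("a",), ("b",), "a", "b")
        result = equalized_odds_threshold_search(
            pred,
            spec,
            grid_step=self.grid_step,
            constraints=SearchConstraints(self.min_recall, self.min_accuracy),
        )
        self.best_threshold_ = result.best_threshold
        self.z_ = result.z_at_best
        self.trace_ = result.trace
        self.per_group_ = result.per_group
        self.result_ = result
        return self

    def predict(self, scores):
        if not hasattr(self, "best_threshold_"):
            raise ValueError("EqualizedOddsThreshold is not fitted")
        return (np.asarray(scores, dtype=float) * 100.0 >= self.best_threshold_).astype(int)
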