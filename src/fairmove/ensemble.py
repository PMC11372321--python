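"""Fairness-aware weighted majority voting across per-attribute thresholds.

Each sociodemographic attribute contributes one mitigation threshold; an
individual's single risk score is thresholded once per attribute, and the
resulting 0/1 votes are combined into a final probability

    P = w_1 * pc_1 + w_2 * pc_2 + ... + w_n * pc_n

with class 1 assigned when P reaches the decision cut (default 0.5, the
natural weighted-majority rule). The weight of attribute i is its share of
the default-threshold (50%) disparities:

    w_i = Z_i / sum_j Z_j

so attributes exhibiting more recall/specificity imbalance at the default
threshold carry more of the vote. Weights are stored unrounded and sum to
one; two-decimal rounding happens only in reports. Every attribute's
threshold applies to every individual — the vote does not condition on the
individual's own group memberships.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin

from .cohort import Cohort, GroupSpec
from .metrics import (
    ScoredPredictions,
    classification_metrics,
    confusion_at_threshold,
    disparity,
    round_half_up,
)
from .mitigation import SearchConstraints, equalized_odds_threshold_search

__all__ = [
    "WMVModel",
    "compute_wmv_weights",
    "wmv_predict",
    "evaluate_wmv",
    "WeightedMajorityVoteClassifier",
]


def compute_wmv_weights(default_disparities: Mapping[str, float]) -> dict[str, float]:
    """Disparity-proportional weights, normalized to sum to one."""
    if not default_disparities:
        raise ValueError("at least one attribute required")
    values = np.array(list(default_disparities.values()), dtype=float)
    if (values < 0).any():
        raise ValueError("disparities must be non-negative")
    total = values.sum()
    if total <= 0:
        raise ValueError("all disparities are zero; weights undefined")
    return {k: float(v / total) for k, v in zip(default_disparities, values)}


@dataclass
class WMVModel:
    """Per-attribute thresholds and normalized vote weights."""

    attributes: tuple[str, ...]
    thresholds: dict[str, float]
    weights: dict[str, float]
    decision_cut: float = 0.5

    def __post_init__(self) -> None:
        if set(self.attributes) != set(self.thresholds) or set(self.attributes) != set(
            self.weights
        ):
            raise ValueError("attributes, thresholds and weights must share keys")
        w = np.array([self.weights[a] for a in self.attributes])
        if (w < 0).any() or abs(w.sum() - 1.0) > 1e-9:
            raise ValueError("weights must be non-negative and sum to 1")

    def rounded_weights(self) -> dict[str, float]:
        return {a: round_half_up(self.weights[a]) for a in self.attributes}

    def to_json(self) -> str:
        return json.dumps(
            {
                "attributes": list(self.attributes),
                "thresholds": self.thresholds,
                "weights": self.weights,
                "decision_cut": self.decision_cut,
            },
            indent=1,
        )

    @classmethod
    def from_json(cls, text: str) -> "WMVModel":
        d = json.loads(text)
        return cls(
            attributes=tuple(d["attributes"]),
            thresholds=d["thresholds"],
            weights=d["weights"],
            decision_cut=d["decision_cut"],
        )


def wmv_predict(scores: np.ndarray, model: WMVModel) -> tuple[np.ndarray, np.ndarray]:
    """Vote probabilities P and final classes for each individual score."""
    scores = np.asarray(scores, dtype=float)
    if scores.size and (scores.min() < 0 or scores.max() > 1):
        raise ValueError("scores must lie in [0,1]")
    P = np.zeros_like(scores, dtype=float)
    for attr in model.attributes:
        votes = scores * 100.0 >= model.thresholds[attr]
        P = P + model.weights[attr] * votes
    classes = (P >= model.decision_cut).astype(int)
    return P, classes


def evaluate_wmv(pred: ScoredPredictions, model: WMVModel) -> dict[str, Optional[float]]:
    """Recall/specificity/accuracy/precision of the voted classes."""
    _, classes = wmv_predict(pred.scores, model)
    y = pred.labels.astype(bool)
    yhat = classes.astype(bool)
    from .metrics import ConfusionCounts

    c = ConfusionCounts(
        tp=int(np.sum(yhat & y)),
        fn=int(np.sum(~yhat & y)),
        fp=int(np.sum(yhat & ~y)),
        tn=int(np.sum(~yhat & ~y)),
    )
    return classification_metrics(c)


class WeightedMajorityVoteClassifier(BaseEstimator, ClassifierMixin):
    """Estimator fitting per-attribute thresholds and disparity weights.

    ``fit`` runs the constrained equalized-odds threshold search once per
    attribute on held-out scores and derives vote weights from each
    attribute's disparity at the default 50% threshold. User-supplied
    ``weight_overrides`` replace selected weights and are renormalized.
    """

    def __init__(
        self,
        specs: Sequence[GroupSpec],
        grid_step: float = 0.1,
        min_recall: float = 0.70,
        min_accuracy: float = 0.50,
        decision_cut: float = 0.5,
        weight_overrides: Optional[Mapping[str, float]] = None,
    ):
        self.specs = specs
        self.grid_step = grid_step
        self.min_recall = min_recall
        self.min_accuracy = min_accuracy
        self.decision_cut = decision_cut
        self.weight_overrides = weight_overrides

    def fit(self, scores, labels, cohort: Cohort):
        scores = np.asarray(scores, dtype=float)
        labels = np.asarray(labels, dtype=int)
        thresholds: dict[str, float] = {}
        default_z: dict[str, float] = {}
        constraints = SearchConstraints(self.min_recall, self.min_accuracy)
        for spec in self.specs:
            pred = ScoredPredictions(scores, labels, cohort.groups(spec))
            result = equalized_odds_threshold_search(
                pred, spec, grid_step=self.grid_step, constraints=constraints
            )
            thresholds[spec.attribute] = result.best_threshold
            p = pred.analyzed()
            ma = classification_metrics(confusion_at_threshold(p.for_group("a"), 50.0))
            mb = classification_metrics(confusion_at_threshold(p.for_group("b"), 50.0))
            default_z[spec.attribute] = disparity(ma, mb)
        weights = compute_wmv_weights(default_z)
        if self.weight_overrides:
            weights.update(self.weight_overrides)
            total = sum(weights.values())
            if total <= 0:
                raise ValueError("overridden weights sum to zero")
            weights = {k: v / total for k, v in weights.items()}
        self.model_ = WMVModel(
            attributes=tuple(s.attribute for s in self.specs),
            thresholds=thresholds,
            weights=weights,
            decision_cut=self.decision_cut,
        )
        self.default_disparities_ = default_z
        return self

    def predict_proba_votes(self, scores):
        return wmv_predict(scores, self.model_)[0]

    def predict(self, scores):
        return wmv_predict(scores, self.model_)[1]
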