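"""AUC-based bias audits: algorithmic bias on a fixed test set and
sampling bias via training-composition sweeps.

Algorithmic bias is a between-group difference in model discrimination
(per-group ROC AUC) on one fixed test set, reported together with the
group confusion metrics and the equalized-odds disparity Z at a chosen
threshold.

Sampling bias is sensitivity of model performance to the demographic
composition of the training set: models are retrained on samples whose
group-A fraction runs over a grid (default 0 to 1 in 10-point steps) and
evaluated on a fixed, balanced test set built by
:func:`fairmove.cohort.build_fixed_test_set`. An AUC range over the sweep
exceeding the tolerance (default 0.05) flags sampling bias; the paper-scale
fixed test sizes per attribute are sex 2992, marital 2824, working 2648,
race 640, income 1000 per group.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .cohort import Cohort, GroupSpec
from .metrics import (
    GroupPerformance,
    MetricUndefinedError,
    ScoredPredictions,
    classification_metrics,
    confusion_at_threshold,
    disparity,
    disparity_pvalue,
    roc_auc,
)
from .models import ModelConfig, predict_scores, train_model

__all__ = [
    "DEFAULT_FIXED_TEST_SIZE_PER_GROUP",
    "SamplingSweepResult",
    "algorithmic_bias_report",
    "sampling_bias_sweep",
    "flag_sampling_bias",
]

#: Per-group fixed test-set sizes per attribute (half the paper's totals of
#: 5984 / 5648 / 5296 / 1280 / 2000).
DEFAULT_FIXED_TEST_SIZE_PER_GROUP = {
    "sex": 2992,
    "marital": 2824,
    "working": 2648,
    "race": 640,
    "income": 1000,
}


def algorithmic_bias_report(
    pred: ScoredPredictions,
    spec: GroupSpec,
    threshold: float = 50.0,
    n_perm: int = 0,
    seed: int = 0,
) -> GroupPerformance:
    """Per-group recall/specificity/accuracy/AUC at ``threshold``, plus the
    disparity Z and the between-group AUC gap.

    If a group lacks positives, its recall is ``None`` and Z is not
    computed (the AUC gap is likewise omitted when AUC is undefined).
    Set ``n_perm > 0`` to attach a stratified permutation p-value for Z.
    """
    p = pred.analyzed()
    report = GroupPerformance(attribute=spec.attribute, threshold=threshold)
    aucs: dict[str, Optional[float]] = {}
    for g, label in (("a", spec.label_a), ("b", spec.label_b)):
        sub = p.for_group(g)
        if len(sub) == 0:
            raise ValueError(f"group {label!r} is empty")
        m = classification_metrics(confusion_at_threshold(sub, threshold))
        try:
            aucs[g] = 100.0 * roc_auc(sub)
        except ValueError:
            aucs[g] = None
        m["auc"] = aucs[g]
        report.per_group[label] = m
    ma, mb = report.per_group[spec.label_a], report.per_group[spec.label_b]
    try:
        report.disparity_z = disparity(ma, mb)
    except MetricUndefinedError:
        report.disparity_z = None
    if aucs["a"] is not None and aucs["b"] is not None:
        report.auc_gap = abs(aucs["a"] - aucs["b"])
    if n_perm > 0 and report.disparity_z is not None:
        report.p_value = disparity_pvalue(p, spec, threshold, n_perm, seed)
    return report


@dataclass
class SamplingSweepResult:
    """AUC of freshly trained models across training-set compositions."""

    attribute: str
    compositions: np.ndarray  # group-A training fractions, strictly increasing
    aucs: np.ndarray
    fixed_test_size: int
    train_size: int

    def __post_init__(self) -> None:
        self.compositions = np.asarray(self.compositions, dtype=float)
        self.aucs = np.asarray(self.aucs, dtype=float)
        if len(self.compositions) != len(self.aucs):
            raise ValueError("compositions and aucs must align")
        if len(self.compositions) and not np.all(np.diff(self.compositions) > 0):
            raise ValueError("compositions must be strictly increasing")

    @property
    def auc_range(self) -> float:
        return float(self.aucs.max() - self.aucs.min())


def sampling_bias_sweep(
    train_pool: Cohort,
    spec: GroupSpec,
    model_config: ModelConfig,
    fixed_test: Cohort,
    train_size: int,
    compositions: Optional[Sequence[float]] = None,
    seed: int = 0,
) -> SamplingSweepResult:
    """Retrain per composition and measure AUC on the fixed test set.

    For each group-A fraction f, draws ``round(f * train_size)`` group-A
    members and the rest from group B (without replacement, seeded per
    composition), trains a fresh model, and records its ROC AUC on
    ``fixed_test``. Deterministic per (seed, config).
    """
    if compositions is None:
        compositions = np.round(np.arange(0.0, 1.0 + 1e-9, 0.1), 10)
    compositions = np.asarray(compositions, dtype=float)
    groups = train_pool.groups(spec)
    idx_a = np.flatnonzero(groups == "a")
    idx_b = np.flatnonzero(groups == "b")
    aucs = []
    for k, f in enumerate(compositions):
        n_a = int(round(f * train_size))
        n_b = train_size - n_a
        if n_a > len(idx_a) or n_b > len(idx_b):
            raise ValueError(
                f"composition {f} unattainable: needs {n_a} from "
                f"{spec.label_a!r} ({len(idx_a)} available) and {n_b} from "
                f"{spec.label_b!r} ({len(idx_b)} available)"
            )
        rng = np.random.default_rng((seed, k))
        chosen = np.concatenate(
            [
                rng.choice(idx_a, size=n_a, replace=False),
                rng.choice(idx_b, size=n_b, replace=False),
            ]
        ).astype(int)
        sub = train_pool.subset(np.isin(np.arange(len(train_pool)), chosen))
        model = train_model(sub, model_config)
        pred = predict_scores(model, fixed_test)
        aucs.append(roc_auc(pred))
    return SamplingSweepResult(
        attribute=spec.attribute,
        compositions=compositions,
        aucs=np.array(aucs),
        fixed_test_size=len(fixed_test),
        train_size=train_size,
    )


def flag_sampling_bias(result: SamplingSweepResult, tolerance: float = 0.05) -> dict:
    """Flag sampling bias when the sweep's AUC range exceeds ``tolerance``."""
    if len(result.aucs) == 0:
        raise ValueError("empty sweep result")
    return {
        "attribute": result.attribute,
        "flag": bool(result.auc_range > tolerance),
        "auc_range": result.auc_range,
        "tolerance": tolerance,
    }
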