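"""Confusion metrics, AUCs, bootstrap intervals, and the disparity Z."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from fairmove import (
    ConfusionCounts,
    ScoredPredictions,
    bootstrap_ci,
    classification_metrics,
    confusion_at_threshold,
    disparity,
    disparity_pvalue,
    pr_auc,
    roc_auc,
)
from fairmove.cohort import GroupSpec
from fairmove.fixtures import GROUP_TABLE_IDS
from fairmove.metrics import MetricUndefinedError, round_half_up
from conftest import random_predictions
from oracles import classify_loop, concordance_auc

SPEC = GroupSpec("attr", ("a",), ("b",), "a", "b")


class TestConfusion:
    def test_threshold_zero_labels_everything_positive(self):
        pred = ScoredPredictions([0.0, 0.4, 1.0], [1, 0, 1])
        c = confusion_at_threshold(pred, 0.0)
        assert c.fn == 0 and c.tn == 0
        assert c.tp == 2 and c.fp == 1

    def test_simple_split(self):
        pred = ScoredPredictions([0.9, 0.2], [1, 0])
        c = confusion_at_threshold(pred, 50.0)
        assert (c.tp, c.tn, c.fp, c.fn) == (1, 1, 0, 0)

    def test_matches_per_record_loop(self):
        rng = np.random.default_rng(42)
        pred = random_predictions(rng, 50, with_groups=False)
        c = confusion_at_threshold(pred, 37.5)
        assert (c.tp, c.fn, c.fp, c.tn) == classify_loop(pred.scores, pred.labels, 37.5)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            confusion_at_threshold(ScoredPredictions([], []), 50.0)


class TestClassificationMetrics:
    def test_published_sgd_confusion(self):
        m = classification_metrics(ConfusionCounts(tp=9, fn=32, fp=35, tn=6503))
        assert round_half_up(m["recall"]) == 21.95
        assert round_half_up(m["specificity"]) == 99.46
        assert round_half_up(m["accuracy"]) == 98.98
        assert round_half_up(m["precision"]) == 20.45

    def test_published_adam_confusion(self):
        m = classification_metrics(ConfusionCounts(tp=29, fn=12, fp=175, tn=6363))
        assert round_half_up(m["recall"]) == 70.73
        assert round_half_up(m["specificity"]) == 97.32
        assert round_half_up(m["accuracy"]) == 97.16

    def test_degenerate_group_undefined_not_zero(self):
        m = classification_metrics(ConfusionCounts(tp=0, fn=0, fp=3, tn=7))
        assert m["recall"] is None
        assert m["specificity"] is not None


class TestAuc:
    def test_perfect_ranking(self):
        pred = ScoredPredictions([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        assert roc_auc(pred) == 1.0

    def test_all_ties_is_half(self):
        pred = ScoredPredictions([0.5] * 6, [1, 0, 1, 0, 1, 0])
        assert roc_auc(pred) == 0.5

    def test_matches_concordance_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(5):
            pred = random_predictions(rng, 30, with_groups=False)
            assert roc_auc(pred) == pytest.approx(
                concordance_auc(pred.scores, pred.labels), abs=1e-12
            )

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(8)
        pred = random_predictions(rng, 60, with_groups=False)
        transformed = ScoredPredictions(pred.scores**3, pred.labels)
        assert roc_auc(pred) == pytest.approx(roc_auc(transformed), abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc(ScoredPredictions([0.1, 0.9], [1, 1]))
        with pytest.raises(ValueError):
            pr_auc(ScoredPredictions([0.1, 0.9], [0, 0]))


class TestBootstrap:
    def test_constant_metric_gives_point_interval(self):
        pred = ScoredPredictions([1.0, 1.0, 0.0, 0.0], [1, 1, 0, 0])
        lo, hi = bootstrap_ci(roc_auc, pred, n_boot=200, seed=0)
        assert lo == hi == 1.0

    def test_interval_contains_point_estimate(self):
        rng = np.random.default_rng(3)
        pred = random_predictions(rng, 200, with_groups=False)
        point = roc_auc(pred)
        lo, hi = bootstrap_ci(roc_auc, pred, n_boot=2000, seed=1)
        assert lo <= point <= hi

    def test_deterministic_per_seed(self):
        rng = np.random.default_rng(4)
        pred = random_predictions(rng, 100, with_groups=False)
        assert bootstrap_ci(roc_auc, pred, n_boot=200, seed=5) == bootstrap_ci(
            roc_auc, pred, n_boot=200, seed=5
        )

    def test_coverage_of_large_sample_auc(self):
        """Over 200 simulated datasets the 95% interval covers the
        large-sample AUC in 90-99% of runs."""
        rng = np.random.default_rng(10)
        # binormal scores: positives N(1,1), negatives N(0,1) -> AUC = Phi(1/sqrt 2)
        from scipy.stats import norm
        from scipy.special import expit

        truth = norm.cdf(1 / np.sqrt(2))
        covered = 0
        for b in range(200):
            y = (rng.random(150) < 0.4).astype(int)
            raw = rng.normal(y.astype(float), 1.0)
            pred = ScoredPredictions(expit(raw), y)  # monotone map keeps AUC
            lo, hi = bootstrap_ci(roc_auc, pred, n_boot=300, seed=b)
            covered += lo <= truth <= hi
        assert 0.90 * 200 <= covered <= 0.99 * 200

    def test_too_few_resamples_rejected(self):
        pred = ScoredPredictions([0.9, 0.1], [1, 0])
        with pytest.raises(ValueError):
            bootstrap_ci(roc_auc, pred, n_boot=10)


class TestDisparity:
    @pytest.mark.parametrize(
        "a, b, expected",
        [
            ((7.14, 99.60), (29.63, 99.35), 22.74),
            ((79.31, 97.07), (33.33, 97.66), 46.57),
            ((50.0, 80.0), (50.0, 80.0), 0.0),
        ],
    )
    def test_published_difference_cells(self, a, b, expected):
        ma = {"recall": a[0], "specificity": a[1]}
        mb = {"recall": b[0], "specificity": b[1]}
        assert disparity(ma, mb) == pytest.approx(expected, abs=1e-9)

    def test_symmetric_and_nonnegative(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            ma = {"recall": rng.uniform(0, 100), "specificity": rng.uniform(0, 100)}
            mb = {"recall": rng.uniform(0, 100), "specificity": rng.uniform(0, 100)}
            z = disparity(ma, mb)
            assert z >= 0
            assert z == pytest.approx(disparity(mb, ma))

    def test_all_fixture_difference_cells_within_rounding(self, fixture_tables):
        """Every printed Difference cell of the eight group tables equals
        |d recall| + |d specificity| of its rows to within +-0.1."""
        checked = 0
        for tid in GROUP_TABLE_IDS:
            for attr, entry in fixture_tables[tid].items():
                z = disparity(entry["a"], entry["b"])
                assert z == pytest.approx(entry["difference"], abs=0.1), (tid, attr)
                checked += 1
        assert checked == 40

    def test_undefined_metric_names_group(self):
        with pytest.raises(MetricUndefinedError, match="'b'"):
            disparity(
                {"recall": 10.0, "specificity": 90.0},
                {"recall": None, "specificity": 90.0},
            )


class TestDisparityPvalue:
    def test_null_is_rarely_significant(self):
        """Identically distributed groups give p > 0.05 in at least 8/10 seeds."""
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(100 + seed)
            y = (rng.random(2000) < 0.3).astype(int)
            scores = np.clip(rng.normal(0.3 + 0.3 * y, 0.2), 0, 1)
            groups = np.where(rng.random(2000) < 0.5, "a", "b").astype(object)
            pred = ScoredPredictions(scores, y, groups)
            p = disparity_pvalue(pred, SPEC, threshold=50.0, n_perm=300, seed=seed)
            hits += p > 0.05
        assert hits >= 8

    def test_large_injected_gap_is_significant(self):
        """A ~40-point recall gap at n=2000 gives p < 0.001."""
        rng = np.random.default_rng(77)
        y = (rng.random(2000) < 0.3).astype(int)
        groups = np.where(rng.random(2000) < 0.5, "a", "b").astype(object)
        scores = np.clip(rng.normal(0.3 + 0.3 * y, 0.15), 0, 1)
        # suppress scores of positive group-a members: recall gap
        mask = (groups == "a") & (y == 1)
        scores[mask] = np.clip(scores[mask] - 0.35, 0, 1)
        pred = ScoredPredictions(scores, y, groups)
        p = disparity_pvalue(pred, SPEC, threshold=50.0, n_perm=1999, seed=1)
        assert p < 0.001

    def test_zero_permutations_rejected(self):
        rng = np.random.default_rng(5)
        pred = random_predictions(rng, 40)
        with pytest.raises(ValueError):
            disparity_pvalue(pred, SPEC, n_perm=0)


@settings(max_examples=30, deadline=None, derandomize=True)
@given(st.integers(0, 10_000))
def test_scores_validated_to_unit_interval(seed):
    rng = np.random.default_rng(seed)
    with pytest.raises(ValueError):
        ScoredPredictions(rng.random(5) + 1.0, [0, 1, 0, 1, 0])
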