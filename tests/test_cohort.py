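"""Cohort generation, splitting, fixed test sets, and CSV round-trips."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import binom

from fairmove import (
    SyntheticConfig,
    build_fixed_test_set,
    generate_synthetic_cohort,
    read_cohort_csv,
    stratified_split,
    write_cohort_csv,
)
from fairmove.cohort import (
    ATTRIBUTE_LEVELS,
    CohortError,
    CohortParseError,
    DEFAULT_GROUP_SPECS,
    PREDICTOR_COLUMNS,
    group_spec_for,
    load_schema,
)
from oracles import concordance_auc


class TestGenerator:
    def test_positive_count_matches_survey_scale(self):
        """Full-size cohort yields a positive count inside the central 99%
        binomial interval around the survey's 207 cases."""
        cohort = generate_synthetic_cohort(SyntheticConfig(seed=1))
        assert len(cohort) == 32893
        lo, hi = binom.ppf([0.005, 0.995], 32893, 0.0063)
        assert lo <= cohort.n_positive <= hi

    def test_zero_bias_gives_equal_group_rates(self):
        """Without bias coefficients, per-group outcome rates differ only
        within sampling tolerance (pooled over 20 seeds)."""
        diffs = []
        for seed in range(20):
            c = generate_synthetic_cohort(
                SyntheticConfig(n=4000, prevalence=0.05, seed=seed)
            )
            g = c.groups(group_spec_for("sex"))
            y = c.outcome
            diffs.append(y[g == "a"].mean() - y[g == "b"].mean())
        # mean difference ~ N(0, sigma/sqrt(20)); 3 SE bound
        se = np.sqrt(0.05 * 0.95 * (1 / 1840 + 1 / 2160) / 20)
        assert abs(np.mean(diffs)) < 3 * se

    def test_signal_bias_creates_group_auc_gap(self):
        """A +1 log-gain signal shift on race yields a trained-model AUC gap
        above 0.05, verified by the pairwise-concordance oracle."""
        from fairmove import ModelConfig, predict_scores, train_model

        cfg = SyntheticConfig(
            n=10000, prevalence=0.05, seed=2, bias_coefficients={"race": {"signal": 1.0}}
        )
        cohort = generate_synthetic_cohort(cfg)
        train, _ = stratified_split(cohort, 0.3, seed=2)
        model = train_model(train, ModelConfig(family="logistic", seed=0))
        pred = predict_scores(model, cohort)
        g = cohort.groups(group_spec_for("race"))
        aucs = {}
        for grp in ("a", "b"):
            m = g == grp
            # oracle is O(n^2); subsample negatives deterministically
            idx = np.flatnonzero(m)
            y = pred.labels[idx]
            keep = np.concatenate(
                [idx[y == 1][:80], idx[y == 0][: 60 * 80 // 8]]
            )
            aucs[grp] = concordance_auc(pred.scores[keep], pred.labels[keep])
        assert abs(aucs["a"] - aucs["b"]) > 0.05

    def test_signal_bias_preserves_group_prevalence(self):
        base = SyntheticConfig(n=20000, prevalence=0.05, seed=6)
        biased = SyntheticConfig(
            n=20000, prevalence=0.05, seed=6, bias_coefficients={"sex": {"signal": 1.0}}
        )
        spec = group_spec_for("sex")
        for cfg in (base, biased):
            c = generate_synthetic_cohort(cfg)
            g = c.groups(spec)
            rate_a = c.outcome[g == "a"].mean()
            rate_b = c.outcome[g == "b"].mean()
            assert abs(rate_a - rate_b) < 0.015

    def test_deterministic_per_seed(self):
        a = generate_synthetic_cohort(SyntheticConfig(n=500, prevalence=0.1, seed=3))
        b = generate_synthetic_cohort(SyntheticConfig(n=500, prevalence=0.1, seed=3))
        pd.testing.assert_frame_equal(a.frame, b.frame)

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"n": 0},
            {"prevalence": 0.0},
            {"attribute_marginals": {"sex": {"male": 0.7, "female": 0.7}}},
            {"attribute_marginals": {"sex": {"male": -0.1, "female": 1.1}}},
            {"bias_coefficients": {"nonexistent": {"outcome": 1.0}}},
        ],
    )
    def test_invalid_config_rejected(self, kwargs):
        with pytest.raises(CohortError):
            SyntheticConfig(**kwargs)

    def test_schema_has_44_documented_predictors(self):
        schema = load_schema()
        assert set(schema) == set(PREDICTOR_COLUMNS)
        onehot = [m for m in schema.values() if m["kind"] == "onehot"]
        levels = {(m["attribute"], m["level"]) for m in onehot}
        expected = {(a, l) for a, ls in ATTRIBUTE_LEVELS.items() for l in ls}
        assert levels == expected


class TestStratifiedSplit:
    def test_survey_scale_split_counts(self):
        """An 80:20 split of 32,893 with 207 positives puts exactly 41
        positives and 6538 negatives in the test set."""
        cfg = SyntheticConfig(n=600, prevalence=0.1, seed=0)
        cohort = generate_synthetic_cohort(cfg)
        # force the exact survey counts by relabelling deterministically
        frame = generate_synthetic_cohort(SyntheticConfig(seed=1)).frame.copy()
        frame["outcome"] = 0
        frame.loc[: 207 - 1, "outcome"] = 1
        from fairmove.cohort import Cohort

        survey = Cohort(frame)
        train, test = stratified_split(survey, 0.2, seed=0)
        assert test.n_positive == 41
        assert len(test) - test.n_positive == 6538
        assert len(train) + len(test) == 32893

    def test_small_symmetric_split(self):
        from fairmove.cohort import Cohort

        frame = generate_synthetic_cohort(SyntheticConfig(n=4, prevalence=0.5, seed=0)).frame.copy()
        frame["outcome"] = [0, 1, 0, 1]
        cohort = Cohort(frame)
        train, test = stratified_split(cohort, 0.5, seed=1)
        assert test.n_positive == 1 and train.n_positive == 1
        assert len(test) == 2 and len(train) == 2

    def test_partition_exact_and_deterministic(self):
        cohort = generate_synthetic_cohort(SyntheticConfig(n=1000, prevalence=0.2, seed=2))
        t1 = stratified_split(cohort, 0.25, seed=7)
        t2 = stratified_split(cohort, 0.25, seed=7)
        assert set(t1[1].ids) == set(t2[1].ids)
        assert set(t1[0].ids) | set(t1[1].ids) == set(cohort.ids)
        assert not (set(t1[0].ids) & set(t1[1].ids))
        # class counts preserved within one individual
        n_pos = cohort.n_positive
        assert abs(t1[1].n_positive - round(0.25 * n_pos)) <= 1

    def test_single_class_rejected(self):
        from fairmove.cohort import Cohort

        frame = generate_synthetic_cohort(SyntheticConfig(n=10, prevalence=0.3, seed=0)).frame.copy()
        frame["outcome"] = 0
        with pytest.raises(CohortError):
            stratified_split(Cohort(frame), 0.2, seed=0)


class TestFixedTestSet:
    def test_exact_group_sizes(self):
        cohort = generate_synthetic_cohort(SyntheticConfig(n=4000, prevalence=0.1, seed=5))
        spec = group_spec_for("sex")
        fixed = build_fixed_test_set(cohort, spec, 500, seed=1)
        g = fixed.groups(spec)
        assert (g == "a").sum() == 500 and (g == "b").sum() == 500
        assert len(fixed) == 1000

    def test_zero_size_gives_empty(self):
        cohort = generate_synthetic_cohort(SyntheticConfig(n=200, prevalence=0.1, seed=5))
        fixed = build_fixed_test_set(cohort, group_spec_for("sex"), 0, seed=1)
        assert len(fixed) == 0

    def test_oversized_request_names_group(self):
        cohort = generate_synthetic_cohort(SyntheticConfig(n=200, prevalence=0.1, seed=5))
        with pytest.raises(CohortError, match="race"):
            build_fixed_test_set(cohort, group_spec_for("race"), 150, seed=1)


class TestCsvRoundTrip:
    def test_round_trip_identity(self, tmp_path):
        cohort = generate_synthetic_cohort(SyntheticConfig(n=10, prevalence=0.3, seed=8))
        path = tmp_path / "cohort.csv"
        write_cohort_csv(cohort, path)
        back = read_cohort_csv(path)
        pd.testing.assert_frame_equal(cohort.frame, back.frame)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000), n=st.integers(1, 40))
    def test_round_trip_property(self, tmp_path_factory, seed, n):
        cohort = generate_synthetic_cohort(SyntheticConfig(n=n, prevalence=0.3, seed=seed))
        path = tmp_path_factory.mktemp("rt") / "c.csv"
        write_cohort_csv(cohort, path)
        pd.testing.assert_frame_equal(cohort.frame, read_cohort_csv(path).frame)

    def test_bad_outcome_cites_row(self, tmp_path):
        cohort = generate_synthetic_cohort(SyntheticConfig(n=5, prevalence=0.3, seed=8))
        path = tmp_path / "bad.csv"
        frame = cohort.frame.copy()
        frame.loc[2, "outcome"] = 2
        frame.to_csv(path, index=False)
        with pytest.raises(CohortParseError, match="row 4"):
            read_cohort_csv(path)

    def test_missing_column_rejected(self, tmp_path):
        cohort = generate_synthetic_cohort(SyntheticConfig(n=5, prevalence=0.3, seed=8))
        path = tmp_path / "bad.csv"
        cohort.frame.drop(columns=["p07"]).to_csv(path, index=False)
        with pytest.raises(CohortParseError, match="p07"):
            read_cohort_csv(path)

    def test_duplicate_id_cites_row(self, tmp_path):
        cohort = generate_synthetic_cohort(SyntheticConfig(n=5, prevalence=0.3, seed=8))
        frame = cohort.frame.copy()
        frame.loc[3, "id"] = frame.loc[0, "id"]
        path = tmp_path / "dup.csv"
        frame.to_csv(path, index=False)
        with pytest.raises(CohortParseError, match="row 5"):
            read_cohort_csv(path)


def test_group_specs_are_disjoint():
    for spec in DEFAULT_GROUP_SPECS:
        assert not (set(spec.values_a) & set(spec.values_b))
        assert set(spec.values_a) | set(spec.values_b) <= set(ATTRIBUTE_LEVELS[spec.attribute])
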