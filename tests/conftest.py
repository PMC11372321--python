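import numpy as np
import pytest

from fairmove import (
    ModelConfig,
    SyntheticConfig,
    generate_synthetic_cohort,
    load_fixture_tables,
    predict_scores,
    stratified_split,
    train_model,
)
from fairmove.cohort import group_spec_for
from fairmove.metrics import ScoredPredictions


@pytest.fixture(scope="session")
def fixture_tables():
    return load_fixture_tables()


@pytest.fixture(scope="session")
def small_cohort():
    """A 600-record moderately predictable cohort used across model tests."""
    return generate_synthetic_cohort(SyntheticConfig(n=600, prevalence=0.25, seed=11))


@pytest.fixture(scope="session")
def separable_cohort():
    """Linearly separable labels: outcome = at least two of three
    substance-use indicators, a deterministic halfspace of the features."""
    from fairmove.cohort import Cohort

    frame = generate_synthetic_cohort(
        SyntheticConfig(n=200, prevalence=0.3, seed=5)
    ).frame.copy()
    frame["outcome"] = (
        frame["p22"] + frame["p24"] + frame["p26"] >= 2
    ).astype(int)
    return Cohort(frame)


@pytest.fixture(scope="session")
def sex_biased_scored():
    """Test-set predictions from a cohort with label bias on sex."""
    cfg = SyntheticConfig(
        n=5000, prevalence=0.1, seed=4, bias_coefficients={"sex": {"outcome": 1.0}}
    )
    cohort = generate_synthetic_cohort(cfg)
    train, test = stratified_split(cohort, 0.3, seed=4)
    model = train_model(train, ModelConfig(family="logistic", seed=4))
    pred = predict_scores(model, test)
    spec = group_spec_for("sex")
    pred.groups = test.groups(spec)
    return pred, spec, test


def random_predictions(rng, n, with_groups=True) -> ScoredPredictions:
    scores = rng.random(n)
    labels = (rng.random(n) < 0.4).astype(int)
    if labels.sum() in (0, n):  # ensure both classes
        labels[0], labels[1] = 0, 1
    groups = None
    if with_groups:
        groups = np.where(rng.random(n) < 0.5, "a", "b").astype(object)
        # ensure each group holds both classes
        idx = rng.permutation(n)
        groups[idx[0]], labels[idx[0]] = "a", 1
        groups[idx[1]], labels[idx[1]] = "a", 0
        groups[idx[2]], labels[idx[2]] = "b", 1
        groups[idx[3]], labels[idx[3]] = "b", 0
    return ScoredPredictions(scores, labels, groups)
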