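"""Cohort schema, CSV I/O, splitting, and the synthetic survey-like generator.

A cohort is one row per individual: a binary outcome (here: opioid use
disorder), a continuous BMI, 44 binary one-hot predictors ``p01..p44``
(opioid-type use, heroin, treatment history, comorbidities, substance use,
and one-hot sociodemographic levels), and five named sociodemographic
attribute columns (sex, marital status, working condition, race, income).

The synthetic generator draws outcomes from a logistic model over the
predictors and supports injecting group-conditional bias at the label and
signal level, so that algorithmic- and sampling-bias audits performed
downstream operate on bias that arose the way it does in real pipelines:
through the data, not through doctored scores.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

__all__ = [
    "ATTRIBUTE_COLUMNS",
    "PREDICTOR_COLUMNS",
    "COHORT_COLUMNS",
    "DEFAULT_ATTRIBUTE_MARGINALS",
    "DEFAULT_GROUP_SPECS",
    "Cohort",
    "GroupSpec",
    "SyntheticConfig",
    "CohortError",
    "CohortParseError",
    "generate_synthetic_cohort",
    "stratified_split",
    "build_fixed_test_set",
    "read_cohort_csv",
    "write_cohort_csv",
    "load_schema",
]


class CohortError(ValueError):
    """Invalid cohort construction or configuration."""


class CohortParseError(CohortError):
    """CSV did not conform to the documented cohort dialect."""


ATTRIBUTE_COLUMNS = ("sex", "marital", "working", "race", "income")
PREDICTOR_COLUMNS = tuple(f"p{i:02d}" for i in range(1, 45))
COHORT_COLUMNS = ("id", "outcome", "bmi") + PREDICTOR_COLUMNS + ATTRIBUTE_COLUMNS

#: Category labels per attribute; "unknown" marks skipped/no-answer survey
#: responses, which are retained in the cohort but excluded from that
#: attribute's two-group analyses.
ATTRIBUTE_LEVELS: Mapping[str, tuple[str, ...]] = {
    "sex": ("male", "female"),
    "marital": ("married", "widowed", "divorced", "never", "unknown"),
    "working": ("full", "part", "unknown"),
    "race": ("white", "black", "other"),
    "income": ("low", "other"),
}

#: Default population composition of the generator (proportions per level),
#: matching a large US substance-use survey cohort.
DEFAULT_ATTRIBUTE_MARGINALS: Mapping[str, Mapping[str, float]] = {
    "sex": {"male": 0.46, "female": 0.54},
    "marital": {
        "married": 0.3693,
        "widowed": 0.0201,
        "divorced": 0.0794,
        "never": 0.4394,
        "unknown": 0.0918,
    },
    "working": {"full": 0.4077, "part": 0.1412, "unknown": 0.4511},
    "race": {"white": 0.6494, "black": 0.0920, "other": 0.2586},
    "income": {"low": 0.1495, "other": 0.8505},
}


def load_schema() -> dict:
    """Return the packaged 44-predictor schema.

    Maps each ``pNN`` column to a descriptive name, its marginal prevalence
    in the synthetic population, and the log-odds coefficient the generator
    assigns to it.
    """
    text = resources.files("fairmove.data").joinpath("schema.json").read_text()
    return json.loads(text)


@dataclass(frozen=True)
class GroupSpec:
    """A two-group partition of one sociodemographic attribute.

    ``values_a``/``values_b`` list the category labels forming each analysis
    group; categories in neither list (e.g. the "unknown" sentinel, or the
    "other" race group) are excluded from that attribute's analyses.
    """

    attribute: str
    values_a: tuple[str, ...]
    values_b: tuple[str, ...]
    label_a: str
    label_b: str

    def __post_init__(self) -> None:
        if set(self.values_a) & set(self.values_b):
            raise CohortError(
                f"groups for {self.attribute!r} overlap: "
                f"{set(self.values_a) & set(self.values_b)}"
            )

    def assign(self, categories: pd.Series) -> np.ndarray:
        """Map category labels to 'a'/'b'/'' (excluded) per record."""
        out = np.full(len(categories), "", dtype=object)
        out[categories.isin(self.values_a).to_numpy()] = "a"
        out[categories.isin(self.values_b).to_numpy()] = "b"
        return out


#: The five analysis partitions: male/female, never-married/ever-married,
#: working >=35h per week/working fewer hours, White/Black race, and yearly
#: income below US $20,000/other income.
DEFAULT_GROUP_SPECS: tuple[GroupSpec, ...] = (
    GroupSpec("sex", ("male",), ("female",), "Male", "Female"),
    GroupSpec(
        "marital",
        ("never",),
        ("married", "widowed", "divorced"),
        "Never been married",
        "Other groups of marital status",
    ),
    GroupSpec(
        "working",
        ("full",),
        ("part",),
        "Working >=35 hours",
        "Other groups of working condition",
    ),
    GroupSpec("race", ("white",), ("black",), "White", "Black"),
    GroupSpec(
        "income", ("low",), ("other",), "An income of <US $20,000", "Other groups of income"
    ),
)


def group_spec_for(attribute: str) -> GroupSpec:
    for spec in DEFAULT_GROUP_SPECS:
        if spec.attribute == attribute:
            return spec
    raise CohortError(f"no default group spec for attribute {attribute!r}")


@dataclass
class Cohort:
    """An ordered collection of labelled individuals.

    Thin wrapper over a :class:`pandas.DataFrame` with the fixed column
    layout ``id, outcome, bmi, p01..p44, sex, marital, working, race,
    income``.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in COHORT_COLUMNS if c not in self.frame.columns]
        if missing:
            raise CohortError(f"cohort frame missing columns: {missing}")
        self.frame = self.frame.loc[:, list(COHORT_COLUMNS)].reset_index(drop=True)
        ids = self.frame["id"].astype(str)
        if ids.duplicated().any():
            dup = ids[ids.duplicated()].iloc[0]
            raise CohortError(f"duplicate id {dup!r}")
        outcome = self.frame["outcome"]
        if not outcome.isin([0, 1]).all():
            bad = outcome[~outcome.isin([0, 1])].iloc[0]
            raise CohortError(f"outcome values must be 0/1, found {bad!r}")
        for attr, levels in ATTRIBUTE_LEVELS.items():
            col = self.frame[attr]
            if not col.isin(levels).all():
                bad = col[~col.isin(levels)].iloc[0]
                raise CohortError(f"unknown {attr} category {bad!r}")

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def ids(self) -> np.ndarray:
        return self.frame["id"].to_numpy()

    @property
    def outcome(self) -> np.ndarray:
        return self.frame["outcome"].to_numpy(dtype=int)

    @property
    def n_positive(self) -> int:
        return int(self.outcome.sum())

    def feature_matrix(self) -> np.ndarray:
        """Model inputs: BMI followed by the 44 binary predictors."""
        cols = ["bmi", *PREDICTOR_COLUMNS]
        return self.frame[cols].to_numpy(dtype=float)

    def feature_names(self) -> tuple[str, ...]:
        return ("bmi", *PREDICTOR_COLUMNS)

    def groups(self, spec: GroupSpec) -> np.ndarray:
        """Per-record 'a'/'b'/'' assignment under ``spec``."""
        return spec.assign(self.frame[spec.attribute])

    def subset(self, mask: np.ndarray) -> "Cohort":
        return Cohort(self.frame.loc[np.asarray(mask)].reset_index(drop=True))


@dataclass(frozen=True)
class SyntheticConfig:
    """Conditions for the synthetic survey-like cohort generator.

    ``bias_coefficients`` maps an attribute name to shifts applied to
    members of that attribute's first analysis group (``values_a`` of the
    default spec): ``outcome`` is an additive log-odds shift on the
    outcome (label bias: group prevalence differs at identical
    covariates); ``signal`` is an additive shift on the log-gain of the
    predictor-driven signal (signal bias: the group's outcomes are more —
    or, negative shift, less — strongly determined by its observed
    predictors, which downstream audits recover as AUC structure).
    """

    n: int = 32893
    prevalence: float = 0.0063
    attribute_marginals: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: DEFAULT_ATTRIBUTE_MARGINALS
    )
    bias_coefficients: Mapping[str, Mapping[str, float]] = field(default_factory=dict)
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise CohortError(f"n must be >= 1, got {self.n}")
        if not 0.0 < self.prevalence < 1.0:
            raise CohortError(f"prevalence must be in (0,1), got {self.prevalence}")
        if self.noise_sd < 0:
            raise CohortError("noise_sd must be non-negative")
        for attr, marg in self.attribute_marginals.items():
            if attr not in ATTRIBUTE_LEVELS:
                raise CohortError(f"unknown attribute {attr!r}")
            probs = np.array(list(marg.values()), dtype=float)
            if (probs < 0).any() or (probs > 1).any() or abs(probs.sum() - 1.0) > 1e-6:
                raise CohortError(
                    f"marginals for {attr!r} must lie in [0,1] and sum to 1"
                )
            unknown = set(marg) - set(ATTRIBUTE_LEVELS[attr])
            if unknown:
                raise CohortError(f"unknown {attr} levels {sorted(unknown)}")
        for attr, shifts in self.bias_coefficients.items():
            if attr not in ATTRIBUTE_LEVELS:
                raise CohortError(f"bias coefficient for unknown attribute {attr!r}")
            bad = set(shifts) - {"outcome", "signal"}
            if bad:
                raise CohortError(f"bias coefficients must be outcome/signal, got {bad}")


def generate_synthetic_cohort(config: SyntheticConfig) -> Cohort:
    """Draw a synthetic cohort under ``config``.

    Outcomes follow a logistic model: a fixed clinical coefficient vector
    (packaged schema), a small BMI effect, Gaussian latent noise, and the
    configured per-group bias shifts. The intercept is calibrated by root
    finding so the expected outcome rate equals ``config.prevalence``.
    Deterministic for a fixed seed.
    """
    schema = load_schema()
    rng = np.random.default_rng(config.seed)
    n = config.n

    # Sociodemographic attributes first; one-hot predictor columns derive
    # from them so the predictor block stays consistent with the attribute
    # columns.
    attrs: dict[str, np.ndarray] = {}
    for attr, levels in ATTRIBUTE_LEVELS.items():
        marg = config.attribute_marginals.get(attr, DEFAULT_ATTRIBUTE_MARGINALS[attr])
        lv = list(marg.keys())
        probs = np.array([marg[k] for k in lv], dtype=float)
        attrs[attr] = rng.choice(np.array(lv, dtype=object), size=n, p=probs)

    columns: dict[str, np.ndarray] = {}
    beta = np.zeros(len(PREDICTOR_COLUMNS))
    for j, col in enumerate(PREDICTOR_COLUMNS):
        meta = schema[col]
        beta[j] = meta["coefficient"]
        if meta["kind"] == "clinical":
            columns[col] = (rng.random(n) < meta["prevalence"]).astype(int)
        else:
            attr, level = meta["attribute"], meta["level"]
            columns[col] = (attrs[attr] == level).astype(int)

    bmi = np.clip(rng.normal(25.59, 8.82, size=n), 12.0, 70.0)
    bmi_coef = -0.01  # slightly lower BMI among cases

    X = np.column_stack([columns[c] for c in PREDICTOR_COLUMNS])
    signal = X @ beta + bmi_coef * (bmi - 25.59)

    # Signal bias: a shift s on the log-gain of the predictor-driven signal
    # within the biased group (gain exp(s), multiplicative across biased
    # attributes). Gain != 1 changes how strongly the group's outcomes are
    # determined by its observed predictors, so trained models discriminate
    # differently across groups — recoverable as an AUC gap — and models
    # trained on one group transfer poorly to the other — recoverable by
    # the training-composition sweep. Outcome bias adds a plain log-odds
    # shift (group prevalence differs at identical covariates).
    log_gain = np.zeros(n)
    outcome_shift = np.zeros(n)
    for attr, shifts in config.bias_coefficients.items():
        spec = group_spec_for(attr)
        in_a = np.isin(attrs[attr], spec.values_a)
        outcome_shift += shifts.get("outcome", 0.0) * in_a
        log_gain += shifts.get("signal", 0.0) * in_a

    noise = rng.normal(0.0, config.noise_sd, size=n) if config.noise_sd > 0 else 0.0
    base = signal + outcome_shift + noise
    linpred = np.exp(log_gain) * signal + outcome_shift + noise

    # Calibrate the overall intercept on the gain-free log-odds so
    # E[outcome] matches the target prevalence, then re-center each
    # gain-stratum to its gain-free prevalence: signal bias changes how
    # strongly outcomes track the predictors within a group, not how many
    # outcomes the group has (prevalence differences are the outcome
    # shift's job).
    def calibrate(lp: np.ndarray, target: float) -> float:
        return brentq(lambda c: float(expit(lp + c).mean() - target), -60.0, 60.0)

    intercept = calibrate(base, config.prevalence)
    prob = expit(linpred + intercept)
    for gain_value in np.unique(log_gain):
        if gain_value == 0.0:
            continue
        stratum = log_gain == gain_value
        target = float(expit(base[stratum] + intercept).mean())
        adjust = calibrate(linpred[stratum], target)
        prob[stratum] = expit(linpred[stratum] + adjust)
    outcome = (rng.random(n) < prob).astype(int)

    frame = pd.DataFrame(
        {
            "id": [f"ind{i:06d}" for i in range(n)],
            "outcome": outcome,
            "bmi": np.round(bmi, 2),
            **columns,
            **{attr: pd.Series(vals, dtype=object) for attr, vals in attrs.items()},
        }
    )
    return Cohort(frame)


def stratified_split(
    cohort: Cohort, test_fraction: float, seed: int
) -> tuple[Cohort, Cohort]:
    """Stratified train/test partition preserving class proportions.

    The test set receives ``round(test_fraction * n)`` records in total, of
    which ``round(test_fraction * n_positive)`` are outcome-positive; the
    split is exact (no overlap, union is the cohort) and deterministic per
    seed.
    """
    if not 0.0 < test_fraction < 1.0:
        raise CohortError(f"test_fraction must be in (0,1), got {test_fraction}")
    y = cohort.outcome
    n_pos, n_neg = int(y.sum()), int((1 - y).sum())
    if n_pos == 0 or n_neg == 0:
        raise CohortError("both outcome classes must be present to stratify")

    n_test = int(round(test_fraction * len(cohort)))
    n_test_pos = min(max(int(round(test_fraction * n_pos)), 0), n_pos)
    n_test_neg = min(n_test - n_test_pos, n_neg)

    rng = np.random.default_rng(seed)
    pos_idx = np.flatnonzero(y == 1)
    neg_idx = np.flatnonzero(y == 0)
    test_idx = np.concatenate(
        [
            rng.choice(pos_idx, size=n_test_pos, replace=False),
            rng.choice(neg_idx, size=n_test_neg, replace=False),
        ]
    )
    mask = np.zeros(len(cohort), dtype=bool)
    mask[test_idx] = True
    return cohort.subset(~mask), cohort.subset(mask)


def build_fixed_test_set(
    cohort: Cohort, spec: GroupSpec, size_per_group: int, seed: int
) -> Cohort:
    """Fixed-composition test set: exactly ``size_per_group`` members of each
    analysis group of ``spec``, sampled without replacement."""
    if size_per_group < 0:
        raise CohortError("size_per_group must be non-negative")
    groups = cohort.groups(spec)
    rng = np.random.default_rng(seed)
    chosen: list[np.ndarray] = []
    for g, label in (("a", spec.label_a), ("b", spec.label_b)):
        idx = np.flatnonzero(groups == g)
        if len(idx) < size_per_group:
            raise CohortError(
                f"group {label!r} of attribute {spec.attribute!r} has only "
                f"{len(idx)} members, need {size_per_group}"
            )
        chosen.append(rng.choice(idx, size=size_per_group, replace=False))
    mask = np.zeros(len(cohort), dtype=bool)
    if chosen:
        mask[np.concatenate(chosen)] = True
    return cohort.subset(mask)


def write_cohort_csv(cohort: Cohort, path) -> None:
    """Write the documented comma-separated dialect (UTF-8, header row)."""
    cohort.frame.to_csv(path, index=False)


def read_cohort_csv(path) -> Cohort:
    """Read a cohort CSV, validating the documented dialect.

    Raises :class:`CohortParseError` naming the offending row (1-based file
    line, header = line 1) on a missing column, a non-binary outcome, or a
    duplicate id.
    """
    frame = pd.read_csv(path, dtype={"id": str})
    missing = [c for c in COHORT_COLUMNS if c not in frame.columns]
    if missing:
        raise CohortParseError(f"{path}: missing required columns {missing}")
    bad = ~frame["outcome"].isin([0, 1])
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0]) + 2
        raise CohortParseError(
            f"{path}: non-binary outcome value "
            f"{frame['outcome'][bad].iloc[0]!r} at row {row}"
        )
    dup = frame["id"].duplicated()
    if dup.any():
        row = int(np.flatnonzero(dup.to_numpy())[0]) + 2
        raise CohortParseError(
            f"{path}: duplicate id {frame['id'][dup].iloc[0]!r} at row {row}"
        )
    for col in PREDICTOR_COLUMNS:
        nb = ~frame[col].isin([0, 1])
        if nb.any():
            row = int(np.flatnonzero(nb.to_numpy())[0]) + 2
            raise CohortParseError(
                f"{path}: non-binary predictor {col} at row {row}"
            )
    try:
        return Cohort(frame)
    except CohortError as exc:  # attribute-level validation
        raise CohortParseError(f"{path}: {exc}") from exc
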