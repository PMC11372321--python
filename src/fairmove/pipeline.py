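"""End-to-end orchestration: detect -> mitigate -> vote -> match -> re-detect.

``run_pipeline`` ties the modules into one reproducible run: build or load
a cohort, stratified-split it, train the configured risk model, audit each
sociodemographic attribute at the default threshold, search per-attribute
mitigation thresholds, assemble the weighted majority vote, run 1-N
matching balance diagnostics, and (optionally) the sampling-bias sweep.
All results land as CSV/JSON files in the output directory together with a
manifest echoing the full configuration and seed, which suffices to
reproduce the run.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .bias import (
    DEFAULT_FIXED_TEST_SIZE_PER_GROUP,
    algorithmic_bias_report,
    flag_sampling_bias,
    sampling_bias_sweep,
)
from .cohort import (
    ATTRIBUTE_LEVELS,
    Cohort,
    DEFAULT_GROUP_SPECS,
    SyntheticConfig,
    build_fixed_test_set,
    generate_synthetic_cohort,
    read_cohort_csv,
    stratified_split,
    write_cohort_csv,
)
from .ensemble import WeightedMajorityVoteClassifier, evaluate_wmv
from .matching import DEFAULT_MATCHING_COVARIATES, match_one_to_n
from .metrics import round_half_up
from .mitigation import InfeasibleThresholdError
from .models import ModelConfig, predict_scores, train_model

logger = logging.getLogger("fairmove")

__all__ = ["RunConfig", "PipelineError", "run_pipeline"]


class PipelineError(RuntimeError):
    """A pipeline stage failed; partial outputs are preserved on disk."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """Single-file configuration for a pipeline run."""

    cohort_csv: Optional[str] = None  # when None, generate synthetically
    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    model: ModelConfig = field(default_factory=lambda: ModelConfig(family="logistic"))
    attributes: tuple[str, ...] = tuple(s.attribute for s in DEFAULT_GROUP_SPECS)
    test_fraction: float = 0.2
    min_recall: float = 0.70
    min_accuracy: float = 0.50
    grid_step: float = 0.1
    run_sweep: bool = False
    sweep_train_size: int = 2000
    sweep_test_size_per_group: Optional[Mapping[str, int]] = None
    match_n: Optional[int] = None
    matching_covariates: tuple[str, ...] = DEFAULT_MATCHING_COVARIATES
    out_dir: str = "fairmove_out"
    seed: int = 0

    def __post_init__(self) -> None:
        unknown = set(self.attributes) - set(ATTRIBUTE_LEVELS)
        if unknown:
            raise ValueError(f"unknown attributes in config: {sorted(unknown)}")
        if not (0.0 <= self.min_recall <= 1.0 and 0.0 <= self.min_accuracy <= 1.0):
            raise ValueError("constraint floors must lie in [0,1]")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "synthetic" in raw:
            raw["synthetic"] = SyntheticConfig(**raw["synthetic"])
        if "model" in raw:
            m = dict(raw["model"])
            if "hidden_sizes" in m:
                m["hidden_sizes"] = tuple(m["hidden_sizes"])
            raw["model"] = ModelConfig(**m)
        if "attributes" in raw:
            raw["attributes"] = tuple(raw["attributes"])
        if "matching_covariates" in raw:
            raw["matching_covariates"] = tuple(raw["matching_covariates"])
        return cls(**raw)

    def echo(self) -> dict:
        d = dataclasses.asdict(self)
        return d


def _specs_for(attributes: Sequence[str]):
    by_name = {s.attribute: s for s in DEFAULT_GROUP_SPECS}
    return [by_name[a] for a in attributes]


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full workflow; returns the manifest dictionary."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "config": config.echo(), "files": []}

    def emit(name: str, frame: pd.DataFrame) -> None:
        frame.to_csv(out / name, index=False)
        manifest["files"].append(name)

    stage = "load"
    try:
        if config.cohort_csv:
            cohort = read_cohort_csv(config.cohort_csv)
        else:
            cohort = generate_synthetic_cohort(config.synthetic)
            write_cohort_csv(cohort, out / "cohort.csv")
            manifest["files"].append("cohort.csv")
        logger.info("stage=%s seed=%d n=%d positives=%d", stage, config.seed, len(cohort), cohort.n_positive)

        stage = "split"
        train, test = stratified_split(cohort, config.test_fraction, seed=config.seed)

        stage = "train"
        model = train_model(train, config.model)
        test_pred = predict_scores(model, test)

        specs = _specs_for(config.attributes)

        stage = "detect"
        detect_rows = []
        for spec in specs:
            pred = dataclasses.replace(test_pred)
            pred.groups = test.groups(spec)
            report = algorithmic_bias_report(pred, spec, threshold=50.0)
            detect_rows.extend(report.as_rows())
        emit("detection.csv", pd.DataFrame(detect_rows))

        stage = "mitigate"
        wmv = WeightedMajorityVoteClassifier(
            specs,
            grid_step=config.grid_step,
            min_recall=config.min_recall,
            min_accuracy=config.min_accuracy,
        )
        wmv.fit(test_pred.scores, test_pred.labels, test)
        mit_rows = []
        for spec in specs:
            th = wmv.model_.thresholds[spec.attribute]
            pred = dataclasses.replace(test_pred)
            pred.groups = test.groups(spec)
            report = algorithmic_bias_report(pred, spec, threshold=th)
            for row in report.as_rows():
                row["optimal_threshold"] = th
                row["default_z"] = round_half_up(wmv.default_disparities_[spec.attribute])
                mit_rows.append(row)
        emit("mitigation.csv", pd.DataFrame(mit_rows))

        stage = "wmv"
        (out / "wmv_model.json").write_text(wmv.model_.to_json())
        manifest["files"].append("wmv_model.json")
        wmv_metrics = evaluate_wmv(test_pred, wmv.model_)
        emit("wmv_metrics.csv", pd.DataFrame([wmv_metrics]))

        stage = "match"
        match = match_one_to_n(
            cohort,
            covariates=config.matching_covariates,
            n=config.match_n,
            seed=config.seed,
        )
        before = match.balance_before.rename(
            columns={"smd": "smd_before", "variance_ratio": "vr_before"}
        )
        after = match.balance_after.rename(
            columns={"smd": "smd_after", "variance_ratio": "vr_after"}
        )
        balance = before.join(after)
        balance.insert(0, "covariate", balance.index)
        emit("matching_balance.csv", balance.reset_index(drop=True))
        manifest["match_n"] = match.n

        if config.run_sweep:
            stage = "sweep"
            sweep_rows = []
            flags = []
            sizes = dict(DEFAULT_FIXED_TEST_SIZE_PER_GROUP)
            if config.sweep_test_size_per_group:
                sizes.update(config.sweep_test_size_per_group)
            for spec in specs:
                fixed = build_fixed_test_set(
                    test, spec, sizes[spec.attribute], seed=config.seed
                )
                result = sampling_bias_sweep(
                    train,
                    spec,
                    config.model,
                    fixed_test=fixed,
                    train_size=config.sweep_train_size,
                    seed=config.seed,
                )
                for f, a in zip(result.compositions, result.aucs):
                    sweep_rows.append(
                        {"attribute": spec.attribute, "composition": f, "auc": a}
                    )
                flags.append(flag_sampling_bias(result))
            emit("sampling_sweep.csv", pd.DataFrame(sweep_rows))
            emit("sampling_flags.csv", pd.DataFrame(flags))
    except InfeasibleThresholdError as exc:
        raise PipelineError(stage, exc) from exc
    except Exception as exc:  # noqa: BLE001 - annotate with stage, keep partials
        raise PipelineError(stage, exc) from exc

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=1, default=str))
    return manifest
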