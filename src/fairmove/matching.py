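"""1-N case-control matching on socioeconomic covariates with balance
diagnostics.

Each outcome-positive case is matched to its n nearest controls by distance
on the propensity logit (propensity = logistic model of the outcome on the
matching covariates). Matching is with replacement by default — at a
control:case ratio near n, matching without replacement is impossible —
with no caliper; both are configurable. When n is unspecified it defaults
to ``round(n_controls / n_cases)``, the pool ratio.

Balance diagnostics per covariate (categorical covariates expand to one
indicator per level):

    SMD            = (mean_case - mean_control) / sqrt((var_case + var_control) / 2)
    variance ratio = var_case / var_control

Continuous covariates use the n-1 sample variance; binary indicators use
p(1-p). |SMD| < 0.1 and a variance ratio near 1 are the conventional
"balanced" calls.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import logit
from sklearn.base import BaseEstimator
from sklearn.linear_model import LogisticRegression

from .cohort import ATTRIBUTE_COLUMNS, ATTRIBUTE_LEVELS, Cohort

__all__ = [
    "DEFAULT_MATCHING_COVARIATES",
    "MatchResult",
    "propensity_scores",
    "match_one_to_n",
    "balance_diagnostics",
    "PropensityMatcher",
]

DEFAULT_MATCHING_COVARIATES = ("bmi",) + ATTRIBUTE_COLUMNS


def _design_matrix(frame: pd.DataFrame, covariates: Sequence[str]) -> pd.DataFrame:
    """Numeric design matrix: continuous columns as-is, categorical
    attribute columns expanded to level indicators."""
    if not covariates:
        raise ValueError("empty covariate list")
    cols: dict[str, np.ndarray] = {}
    for cov in covariates:
        if cov not in frame.columns:
            raise ValueError(f"unknown covariate {cov!r}")
        if cov in ATTRIBUTE_LEVELS:
            for level in ATTRIBUTE_LEVELS[cov]:
                cols[f"{cov}[{level}]"] = (frame[cov] == level).to_numpy(dtype=float)
        else:
            cols[cov] = frame[cov].to_numpy(dtype=float)
    return pd.DataFrame(cols, index=frame.index)


def propensity_scores(
    cohort: Cohort, covariates: Sequence[str] = DEFAULT_MATCHING_COVARIATES
) -> np.ndarray:
    """Case-probability per individual from a logistic model of the
    outcome on the matching covariates, aligned to cohort order."""
    y = cohort.outcome
    if y.min() == y.max():
        raise ValueError("both outcome classes required to fit a propensity model")
    X = _design_matrix(cohort.frame, covariates).to_numpy()
    # column scaling for optimizer conditioning; probabilities are invariant
    scale = X.std(axis=0)
    scale[scale == 0] = 1.0
    model = LogisticRegression(max_iter=5000, C=1e6)  # effectively unpenalized
    model.fit(X / scale, y)
    p = model.predict_proba(X / scale)[:, 1]
    if p.min() <= 1e-12 or p.max() >= 1 - 1e-12:
        raise ValueError("degenerate propensity fit (perfect separation)")
    return p


@dataclass
class MatchResult:
    case_ids: list[str]
    control_ids: dict[str, list[str]]  # per case, n matched control ids
    n: int
    balance_before: pd.DataFrame
    balance_after: pd.DataFrame

    def matched_control_index(self) -> list[str]:
        out: list[str] = []
        for cid in self.case_ids:
            out.extend(self.control_ids[cid])
        return out

    def match_map_rows(self) -> list[dict]:
        rows = []
        for cid in self.case_ids:
            for rank, ctrl in enumerate(self.control_ids[cid], start=1):
                rows.append({"case_id": cid, "control_id": ctrl, "rank": rank})
        return rows


def balance_diagnostics(
    cases: pd.DataFrame, controls: pd.DataFrame, covariates: Sequence[str]
) -> pd.DataFrame:
    """Per-covariate SMD and variance ratio between cases and controls.

    Returns a frame indexed by expanded covariate name with columns
    ``smd`` and ``variance_ratio``; a zero control variance leaves the
    ratio as NaN (flagged, not fabricated).
    """
    if len(cases) < 2 or len(controls) < 2:
        raise ValueError("need at least 2 records per side")
    Xc = _design_matrix(cases, covariates)
    Xk = _design_matrix(controls, covariates)

    rows = {}
    for col in Xc.columns:
        a, b = Xc[col].to_numpy(), Xk[col].to_numpy()
        binary = set(np.unique(np.concatenate([a, b]))) <= {0.0, 1.0}
        if binary:
            pa, pb = a.mean(), b.mean()
            va, vb = pa * (1 - pa), pb * (1 - pb)
            diff = pa - pb
        else:
            va, vb = a.var(ddof=1), b.var(ddof=1)
            diff = a.mean() - b.mean()
        pooled = np.sqrt((va + vb) / 2.0)
        smd = diff / pooled if pooled > 0 else 0.0
        ratio = va / vb if vb > 0 else np.nan
        rows[col] = {"smd": smd, "variance_ratio": ratio}
    return pd.DataFrame.from_dict(rows, orient="index")


def match_one_to_n(
    cohort: Cohort,
    covariates: Sequence[str] = DEFAULT_MATCHING_COVARIATES,
    n: Optional[int] = None,
    seed: int = 0,
    replacement: bool = True,
    caliper: Optional[float] = None,
) -> MatchResult:
    """Nearest-neighbor 1-N matching on the propensity logit.

    For each case, the n closest controls (distance on the logit scale,
    optional caliper); deterministic per seed (ties and case order are
    seed-shuffled). Without replacement, controls are consumed greedily.
    """
    y = cohort.outcome
    case_idx = np.flatnonzero(y == 1)
    ctrl_idx = np.flatnonzero(y == 0)
    if len(case_idx) == 0 or len(ctrl_idx) == 0:
        raise ValueError("need both cases and controls")
    if n is None:
        n = int(round(len(ctrl_idx) / len(case_idx)))
    if n < 1:
        raise ValueError("n must be >= 1")
    if not replacement and len(ctrl_idx) < n * len(case_idx):
        raise ValueError(
            f"matching without replacement needs {n * len(case_idx)} controls, "
            f"only {len(ctrl_idx)} available (shortfall "
            f"{n * len(case_idx) - len(ctrl_idx)})"
        )

    ps = propensity_scores(cohort, covariates)
    lp = logit(np.clip(ps, 1e-12, 1 - 1e-12))
    ids = cohort.ids

    rng = np.random.default_rng(seed)
    case_order = rng.permutation(len(case_idx))
    available = np.ones(len(ctrl_idx), dtype=bool)
    control_ids: dict[str, list[str]] = {}
    jitter = rng.random(len(ctrl_idx))  # seed-deterministic tie-break

    for ci in case_idx[case_order]:
        dist = np.abs(lp[ctrl_idx] - lp[ci])
        order = np.lexsort((jitter, dist))
        picked: list[int] = []
        for j in order:
            if not replacement and not available[j]:
                continue
            if caliper is not None and dist[j] > caliper:
                break
            picked.append(j)
            if len(picked) == n:
                break
        if len(picked) < n:
            raise ValueError(
                f"case {ids[ci]!r}: only {len(picked)} controls within "
                f"constraints, need {n}"
            )
        if not replacement:
            available[np.asarray(picked)] = False
        control_ids[ids[ci]] = [ids[ctrl_idx[j]] for j in picked]

    case_frame = cohort.frame.iloc[case_idx]
    pool_frame = cohort.frame.iloc[ctrl_idx]
    balance_before = balance_diagnostics(case_frame, pool_frame, covariates)

    matched_rows = []
    frame_by_id = cohort.frame.set_index(cohort.frame["id"].astype(str))
    for cid in ids[case_idx]:
        matched_rows.append(frame_by_id.loc[control_ids[cid]])
    matched_frame = pd.concat(matched_rows, axis=0)
    balance_after = balance_diagnostics(case_frame, matched_frame, covariates)

    return MatchResult(
        case_ids=[str(i) for i in ids[case_idx]],
        control_ids=control_ids,
        n=n,
        balance_before=balance_before,
        balance_after=balance_after,
    )


class PropensityMatcher(BaseEstimator):
    """Estimator-style wrapper: ``fit`` runs the matching, exposing
    ``result_``, ``balance_before_`` and ``balance_after_``."""

    def __init__(
        self,
        covariates: Sequence[str] = DEFAULT_MATCHING_COVARIATES,
        n: Optional[int] = None,
        seed: int = 0,
        replacement: bool = True,
        caliper: Optional[float] = None,
    ):
        self.covariates = covariates
        self.n = n
        self.seed = seed
        self.replacement = replacement
        self.caliper = caliper

    def fit(self, cohort: Cohort, y=None):
        self.result_ = match_one_to_n(
            cohort,
            covariates=self.covariates,
            n=self.n,
            seed=self.seed,
            replacement=self.replacement,
            caliper=self.caliper,
        )
        self.balance_before_ = self.result_.balance_before
        self.balance_after_ = self.result_.balance_after
        return self
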