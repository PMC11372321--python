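"""Reference trainers emitting probability scores for cohort records.

Five model families: a feed-forward neural network trained with minibatch
SGD or Adam (two hidden layers of 1000 rectified-linear units, sigmoid
output, weighted binary cross-entropy with balanced class weighting, batch
size 64, 20 epochs, learning rate 0.001), logistic regression, a linear
SVM, and an RBF SVM with C=1 and the "scale" gamma convention

    gamma = 1 / (n_features * feature_variance).

The neural network is implemented directly on numpy: balanced class
weighting enters the loss as per-sample weights n/(2*n_class), so each
class contributes equally regardless of imbalance. Training is fully
deterministic per (seed, config): weight initialization and the per-epoch
minibatch shuffle both derive from the run seed.

BMI (the only continuous input) is z-scored inside the model pipeline
before SVM and NN training for kernel and gradient conditioning; the 44
binary predictors pass through untouched.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import joblib
import numpy as np
from scipy.special import expit
from sklearn.base import BaseEstimator, ClassifierMixin, TransformerMixin
from sklearn.calibration import CalibratedClassifierCV
from sklearn.linear_model import LogisticRegression
from sklearn.pipeline import Pipeline
from sklearn.svm import SVC
from sklearn.utils.validation import check_is_fitted

from .cohort import Cohort
from .metrics import ScoredPredictions

__all__ = [
    "MODEL_FAMILIES",
    "ModelConfig",
    "ScoreModel",
    "MLPBinaryClassifier",
    "rbf_gamma",
    "build_estimator",
    "train_model",
    "predict_scores",
    "save_model",
    "load_model",
]

MODEL_FAMILIES = ("nn_sgd", "nn_adam", "logistic", "svm_linear", "svm_rbf")


def rbf_gamma(n_features: int, feature_variance: float) -> float:
    """Default RBF kernel width: ``1 / (n_features * feature_variance)``."""
    if n_features < 1:
        raise ValueError("n_features must be >= 1")
    if feature_variance <= 0:
        raise ValueError("feature_variance must be positive (degenerate kernel)")
    return 1.0 / (n_features * feature_variance)


@dataclass(frozen=True)
class ModelConfig:
    family: str = "nn_adam"
    hidden_sizes: tuple[int, ...] = (1000, 1000)
    epochs: int = 20
    batch_size: int = 64
    learning_rate: float = 0.001
    C: float = 1.0
    class_weighting: str = "balanced"  # or "none"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.family not in MODEL_FAMILIES:
            raise ValueError(f"unknown model family {self.family!r}")
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be positive")
        if any(h < 1 for h in self.hidden_sizes):
            raise ValueError("hidden sizes must be positive")
        if self.learning_rate <= 0 or self.C <= 0:
            raise ValueError("learning_rate and C must be positive")
        if self.class_weighting not in ("balanced", "none"):
            raise ValueError("class_weighting must be 'balanced' or 'none'")


class BMIStandardizer(BaseEstimator, TransformerMixin):
    """Z-score the first feature column (BMI); pass binary columns through."""

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        self.mean_ = float(X[:, 0].mean())
        self.scale_ = float(X[:, 0].std()) or 1.0
        return self

    def transform(self, X):
        check_is_fitted(self, "mean_")
        X = np.asarray(X, dtype=float).copy()
        X[:, 0] = (X[:, 0] - self.mean_) / self.scale_
        return X


class MLPBinaryClassifier(BaseEstimator, ClassifierMixin):
    """Two-hidden-layer feed-forward network for binary outcomes.

    Rectified-linear hidden units, a single sigmoid output, and weighted
    binary cross-entropy loss. ``solver`` selects plain minibatch SGD or
    Adam. ``class_weight='balanced'`` weights each sample by
    ``n / (2 * n_class)``.
    """

    def __init__(
        self,
        hidden_sizes: tuple[int, ...] = (1000, 1000),
        solver: str = "adam",
        learning_rate: float = 0.001,
        epochs: int = 20,
        batch_size: int = 64,
        class_weight: Optional[str] = "balanced",
        random_state: int = 0,
    ):
        self.hidden_sizes = hidden_sizes
        self.solver = solver
        self.learning_rate = learning_rate
        self.epochs = epochs
        self.batch_size = batch_size
        self.class_weight = class_weight
        self.random_state = random_state

    def _init_params(self, n_in: int, rng: np.random.Generator):
        sizes = [n_in, *self.hidden_sizes, 1]
        weights, biases = [], []
        for fan_in, fan_out in zip(sizes[:-1], sizes[1:]):
            # He initialization, suited to rectified-linear units
            weights.append(rng.normal(0.0, np.sqrt(2.0 / fan_in), (fan_in, fan_out)))
            biases.append(np.zeros(fan_out))
        return weights, biases

    def _forward(self, X, weights, biases):
        acts = [X]
        a = X
        for W, b in zip(weights[:-1], biases[:-1]):
            a = np.maximum(a @ W + b, 0.0)
            acts.append(a)
        logit = a @ weights[-1] + biases[-1]
        return acts, logit

    def fit(self, X, y):
        if self.solver not in ("sgd", "adam"):
            raise ValueError(f"solver must be 'sgd' or 'adam', got {self.solver!r}")
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        classes = np.unique(y)
        if not np.isin(classes, [0.0, 1.0]).all() or len(classes) < 2:
            raise ValueError("training labels must contain both classes 0 and 1")
        n, n_in = X.shape
        if self.class_weight == "balanced":
            n_pos = float(y.sum())
            sw = np.where(y == 1, n / (2.0 * n_pos), n / (2.0 * (n - n_pos)))
        else:
            sw = np.ones(n)

        rng = np.random.default_rng(self.random_state)
        weights, biases = self._init_params(n_in, rng)
        if self.solver == "adam":
            mW = [np.zeros_like(W) for W in weights]
            vW = [np.zeros_like(W) for W in weights]
            mb = [np.zeros_like(b) for b in biases]
            vb = [np.zeros_like(b) for b in biases]
            b1, b2, eps = 0.9, 0.999, 1e-8
            t = 0

        for _ in range(self.epochs):
            order = rng.permutation(n)
            for start in range(0, n, self.batch_size):
                idx = order[start : start + self.batch_size]
                Xb, yb, wb = X[idx], y[idx], sw[idx]
                acts, logit = self._forward(Xb, weights, biases)
                p = expit(logit.ravel())
                # gradient of weighted BCE wrt the output logit
                delta = (wb * (p - yb))[:, None] / len(idx)
                gW, gb = [None] * len(weights), [None] * len(biases)
                for layer in range(len(weights) - 1, -1, -1):
                    gW[layer] = acts[layer].T @ delta
                    gb[layer] = delta.sum(axis=0)
                    if layer > 0:
                        delta = (delta @ weights[layer].T) * (acts[layer] > 0)
                if self.solver == "sgd":
                    for L in range(len(weights)):
                        weights[L] -= self.learning_rate * gW[L]
                        biases[L] -= self.learning_rate * gb[L]
                else:
                    t += 1
                    for L in range(len(weights)):
                        mW[L] = b1 * mW[L] + (1 - b1) * gW[L]
                        vW[L] = b2 * vW[L] + (1 - b2) * gW[L] ** 2
                        mb[L] = b1 * mb[L] + (1 - b1) * gb[L]
                        vb[L] = b2 * vb[L] + (1 - b2) * gb[L] ** 2
                        mhW = mW[L] / (1 - b1**t)
                        vhW = vW[L] / (1 - b2**t)
                        mhb = mb[L] / (1 - b1**t)
                        vhb = vb[L] / (1 - b2**t)
                        weights[L] -= self.learning_rate * mhW / (np.sqrt(vhW) + eps)
                        biases[L] -= self.learning_rate * mhb / (np.sqrt(vhb) + eps)

        self.weights_ = weights
        self.biases_ = biases
        self.classes_ = np.array([0, 1])
        self.n_features_in_ = n_in
        return self

    def decision_function(self, X):
        check_is_fitted(self, "weights_")
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"expected {self.n_features_in_} features, got {X.shape[1] if X.ndim == 2 else X.ndim}"
            )
        _, logit = self._forward(X, self.weights_, self.biases_)
        return logit.ravel()

    def predict_proba(self, X):
        p = expit(self.decision_function(X))
        return np.column_stack([1.0 - p, p])

    def predict(self, X):
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(int)


def build_estimator(config: ModelConfig, n_features: Optional[int] = None):
    """Assemble the sklearn estimator (BMI scaling included) for a family."""
    cw = "balanced" if config.class_weighting == "balanced" else None
    if config.family in ("nn_sgd", "nn_adam"):
        core = MLPBinaryClassifier(
            hidden_sizes=tuple(config.hidden_sizes),
            solver="sgd" if config.family == "nn_sgd" else "adam",
            learning_rate=config.learning_rate,
            epochs=config.epochs,
            batch_size=config.batch_size,
            class_weight=cw,
            random_state=config.seed,
        )
    elif config.family == "logistic":
        core = LogisticRegression(
            C=config.C, class_weight=cw, max_iter=2000, random_state=config.seed
        )
    elif config.family == "svm_linear":
        core = CalibratedClassifierCV(
            SVC(kernel="linear", C=config.C, class_weight=cw, random_state=config.seed),
            method="sigmoid",  # Platt scaling on training folds
            cv=3,
            ensemble=False,
        )
    elif config.family == "svm_rbf":
        # gamma='scale' realizes 1/(n_features * var) on the training matrix,
        # the same convention rbf_gamma() computes explicitly.
        core = CalibratedClassifierCV(
            SVC(
                kernel="rbf",
                C=config.C,
                gamma="scale",
                class_weight=cw,
                random_state=config.seed,
            ),
            method="sigmoid",
            cv=3,
            ensemble=False,
        )
    else:  # pragma: no cover - guarded by ModelConfig
        raise ValueError(config.family)
    return Pipeline([("scale", BMIStandardizer()), ("model", core)])


def _fingerprint(feature_names: Sequence[str]) -> str:
    payload = json.dumps(list(feature_names)).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


@dataclass
class ScoreModel:
    """A fitted score-emitting model bound to a feature schema."""

    family: str
    estimator: Pipeline
    feature_names: tuple[str, ...]
    config: ModelConfig

    @property
    def schema_fingerprint(self) -> str:
        return _fingerprint(self.feature_names)


def train_model(train: Cohort, config: ModelConfig) -> ScoreModel:
    """Fit the configured family on a cohort's feature matrix."""
    y = train.outcome
    if len(np.unique(y)) < 2:
        raise ValueError("training cohort must contain both outcome classes")
    est = build_estimator(config)
    est.fit(train.feature_matrix(), y)
    return ScoreModel(
        family=config.family,
        estimator=est,
        feature_names=train.feature_names(),
        config=config,
    )


def predict_scores(model: ScoreModel, cohort: Cohort) -> ScoredPredictions:
    """Score a cohort; scores align with record order and lie in [0,1]."""
    if cohort.feature_names() != model.feature_names:
        raise ValueError(
            f"cohort schema {_fingerprint(cohort.feature_names())} does not match "
            f"model schema {model.schema_fingerprint}"
        )
    if len(cohort) == 0:
        return ScoredPredictions(np.empty(0), np.empty(0, dtype=int))
    scores = model.estimator.predict_proba(cohort.feature_matrix())[:, 1]
    return ScoredPredictions(np.clip(scores, 0.0, 1.0), cohort.outcome)


def save_model(model: ScoreModel, path) -> None:
    """Persist as a directory bundle: config echo + fingerprint in JSON,
    fitted parameters in a joblib file."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    meta = {
        "family": model.family,
        "feature_names": list(model.feature_names),
        "schema_fingerprint": model.schema_fingerprint,
        "config": asdict(model.config),
    }
    (path / "model.json").write_text(json.dumps(meta, indent=1))
    joblib.dump(model.estimator, path / "model.joblib")


def load_model(path) -> ScoreModel:
    path = Path(path)
    meta = json.loads((path / "model.json").read_text())
    cfg = dict(meta["config"])
    cfg["hidden_sizes"] = tuple(cfg["hidden_sizes"])
    config = ModelConfig(**cfg)
    estimator = joblib.load(path / "model.joblib")
    return ScoreModel(
        family=meta["family"],
        estimator=estimator,
        feature_names=tuple(meta["feature_names"]),
        config=config,
    )
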