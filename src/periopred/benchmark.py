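"""Patient-grouped benchmarking: splits, rebalancing, model zoo, tuning.

All resampling is grouped at patient level so that every site of a patient
falls on exactly one side of any split — the leakage guard that site-level
clinical data requires. Class imbalance is handled inside training folds
only (upsampling, downsampling or SMOTE), as is categorical target
encoding; both are re-fitted per inner fold during tuning.

The tuned estimator is exposed sklearn-style: :class:`BenchmarkClassifier`
implements ``fit(X, y, groups)`` / ``predict`` / ``predict_proba`` with
fitted attributes ``best_params_``, ``best_score_`` and ``trace_``;
:func:`tune_and_train` is a thin functional wrapper.

Hyperparameter search is seeded random search by default, with a light
Gaussian-process expected-improvement alternative (``search="bayesian"``).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.compose import ColumnTransformer
from sklearn.ensemble import RandomForestClassifier
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import Matern
from sklearn.linear_model import LogisticRegression
from sklearn.neighbors import NearestNeighbors
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import OneHotEncoder, StandardScaler, TargetEncoder
from xgboost import XGBClassifier

from .evaluation import binary_metrics, multiclass_metrics
from .labeling import TaskDataset

__all__ = [
    "BenchmarkConfig",
    "SplitPlan",
    "grouped_split",
    "grouped_cv_folds",
    "rebalance_training",
    "smote_resample",
    "PriorDummyClassifier",
    "BenchmarkClassifier",
    "tune_and_train",
    "dummy_baseline",
    "predict_proba",
    "benchmark_grid",
]

LEARNERS = ("dummy", "logistic", "random_forest", "gradient_boosting",
            "multilayer_perceptron")
CRITERIA = ("f1", "f1_macro", "brier", "multiclass_brier")
REBALANCE = ("none", "upsample", "downsample", "smote")


# --------------------------------------------------------------------------
# Grouped resampling
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class SplitPlan:
    train_patients: tuple
    test_patients: tuple
    folds: dict = field(default_factory=dict)  # patient -> fold index

    def __post_init__(self) -> None:
        if set(self.train_patients) & set(self.test_patients):
            raise ValueError("train and test patients overlap")


def grouped_split(task: TaskDataset, test_fraction: float = 0.2,
                  seed: int = 0) -> SplitPlan:
    """Randomly partition patients (never sites) into train and test."""
    patients = np.array(sorted(set(task.groups)), dtype=object)
    if len(patients) < 2:
        raise ValueError("need at least two patients to split")
    if not 0.0 < test_fraction < 1.0:
        raise ValueError("test_fraction must be in (0,1)")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(patients))
    n_test = max(1, int(round(test_fraction * len(patients))))
    n_test = min(n_test, len(patients) - 1)
    test = patients[order[:n_test]]
    train = patients[order[n_test:]]
    return SplitPlan(tuple(train.tolist()), tuple(test.tolist()))


def grouped_cv_folds(train_patients: Sequence, k: int = 10,
                     seed: int = 0) -> dict:
    """Assign each training patient to one of k folds (sizes differ <= 1)."""
    patients = np.array(sorted(set(train_patients)), dtype=object)
    if k < 2:
        raise ValueError("need at least two folds")
    if len(patients) < k:
        raise ValueError(f"{len(patients)} patients cannot fill {k} folds")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(patients))
    return {patients[i]: int(i_pos % k) for i_pos, i in enumerate(order)}


# --------------------------------------------------------------------------
# Rebalancing
# --------------------------------------------------------------------------

def smote_resample(X: np.ndarray, y: np.ndarray, seed: int = 0,
                   k_neighbors: int = 5) -> tuple[np.ndarray, np.ndarray]:
    """Synthetic minority oversampling on an encoded numeric matrix.

    New minority samples are linear interpolations between a minority point
    and one of its k nearest minority neighbours, generated until every
    class matches the majority count. Classes too small for the requested
    neighbour count fall back to plain upsampling with a warning.
    """
    rng = np.random.default_rng(seed)
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    n_max = counts.max()
    parts_X, parts_y = [X], [y]
    for c, n_c in zip(classes, counts):
        deficit = int(n_max - n_c)
        if deficit == 0:
            continue
        Xc = X[y == c]
        if n_c <= k_neighbors:
            warnings.warn(
                f"class {c!r} has {n_c} samples <= k={k_neighbors} neighbours; "
                "falling back to upsampling", stacklevel=2)
            idx = rng.integers(0, n_c, size=deficit)
            synth = Xc[idx]
        else:
            nn = NearestNeighbors(n_neighbors=k_neighbors + 1).fit(Xc)
            _, neigh = nn.kneighbors(Xc)
            base = rng.integers(0, n_c, size=deficit)
            pick = neigh[base, rng.integers(1, k_neighbors + 1, size=deficit)]
            lam = rng.random(deficit)[:, None]
            synth = Xc[base] + lam * (Xc[pick] - Xc[base])
        parts_X.append(synth)
        parts_y.append(np.full(deficit, c, dtype=y.dtype))
    return np.vstack(parts_X), np.concatenate(parts_y)


def rebalance_training(X: np.ndarray, y: np.ndarray, strategy: str = "none",
                       seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Equalize class counts on TRAINING data only.

    ``upsample`` resamples every class with replacement up to the majority
    count; ``downsample`` without replacement down to the minority count;
    ``smote`` interpolates synthetic minority samples; ``none`` is the
    identity.
    """
    if strategy not in REBALANCE:
        raise ValueError(f"unknown strategy {strategy!r}")
    X = np.asarray(X)
    y = np.asarray(y)
    if strategy == "none":
        return X, y
    if strategy == "smote":
        return smote_resample(X, y, seed=seed)
    rng = np.random.default_rng(seed)
    classes, counts = np.unique(y, return_counts=True)
    target = counts.max() if strategy == "upsample" else counts.min()
    idx_parts = []
    for c, n_c in zip(classes, counts):
        idx_c = np.flatnonzero(y == c)
        if strategy == "upsample":
            extra = rng.choice(idx_c, size=int(target - n_c), replace=True)
            idx_parts.append(np.concatenate([idx_c, extra]))
        else:
            idx_parts.append(rng.choice(idx_c, size=int(target), replace=False))
    idx = np.concatenate(idx_parts)
    return X[idx], y[idx]


# --------------------------------------------------------------------------
# Baseline + model zoo
# --------------------------------------------------------------------------

class PriorDummyClassifier(BaseEstimator, ClassifierMixin):
    """Feature-free baseline: prior probabilities, majority hard label.

    Predicts the training class-prevalence vector as probabilities for
    every input and the majority class as the hard label; prevalence ties
    resolve to the lowest class index.
    """

    def fit(self, X, y):
        y = np.asarray(y)
        if len(y) == 0:
            raise ValueError("need at least one training row")
        self.classes_, counts = np.unique(y, return_counts=True)
        self.prior_ = counts / counts.sum()
        self.majority_ = self.classes_[int(np.argmax(counts))]
        return self

    def predict_proba(self, X):
        n = len(X)
        return np.tile(self.prior_, (n, 1))

    def predict(self, X):
        return np.full(len(X), self.majority_)


def dummy_baseline(train_labels) -> PriorDummyClassifier:
    """Fit the prior-probability dummy on training labels alone."""
    return PriorDummyClassifier().fit(np.zeros((len(train_labels), 1)), train_labels)


def _loguniform(lo, hi):
    return ("log", float(lo), float(hi))


# search spaces: name -> ("log", lo, hi) | ("int", lo, hi) | ("cat", [..])
_SEARCH_SPACES: dict[str, dict] = {
    "logistic": {
        "C": _loguniform(1e-3, 1e2),
    },
    "random_forest": {
        "n_estimators": ("int", 100, 400),
        "max_depth": ("int", 3, 16),
        "min_samples_leaf": ("int", 1, 10),
        "max_features": ("cat", ["sqrt", "log2", 0.5]),
    },
    "gradient_boosting": {
        "n_estimators": ("int", 50, 300),
        "max_depth": ("int", 2, 8),
        "learning_rate": _loguniform(0.01, 0.3),
        "subsample": ("cat", [0.6, 0.8, 1.0]),
        "colsample_bytree": ("cat", [0.6, 0.8, 1.0]),
    },
    "multilayer_perceptron": {
        "hidden_layer_sizes": ("cat", [(32,), (64,), (64, 32), (128, 64)]),
        "alpha": _loguniform(1e-5, 1e-2),
        "learning_rate_init": _loguniform(1e-4, 1e-2),
    },
}


class _LabelEncodedXGB(BaseEstimator, ClassifierMixin):
    """XGBoost needs 0..K-1 labels; this shim maps arbitrary class labels."""

    def __init__(self, **params):
        self.params = params

    def fit(self, X, y):
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        codes = np.searchsorted(self.classes_, y)
        self._xgb = XGBClassifier(**self.params)
        self._xgb.fit(X, codes)
        return self

    def predict_proba(self, X):
        return self._xgb.predict_proba(X)

    def predict(self, X):
        return self.classes_[self._xgb.predict(X)]


def _make_learner(learner: str, params: dict, n_classes: int, seed: int):
    if learner == "dummy":
        return PriorDummyClassifier()
    if learner == "logistic":
        # saga with log loss (binary) / multinomial loss (multiclass)
        return LogisticRegression(solver="saga", max_iter=500,
                                  random_state=seed, **params)
    if learner == "random_forest":
        return RandomForestClassifier(random_state=seed, n_jobs=1, **params)
    if learner == "gradient_boosting":
        return _LabelEncodedXGB(
            objective="binary:logistic" if n_classes == 2 else "multi:softprob",
            eval_metric="logloss" if n_classes == 2 else "mlogloss",
            random_state=seed, n_jobs=1, verbosity=0, **params)
    if learner == "multilayer_perceptron":
        return MLPClassifier(max_iter=300, random_state=seed, **params)
    raise ValueError(f"unknown learner {learner!r}")


def _make_encoder(task: TaskDataset, encoding: str, seed: int,
                  scale: bool) -> Pipeline:
    if encoding == "one_hot":
        cat = OneHotEncoder(handle_unknown="ignore", sparse_output=False)
    elif encoding == "target":
        from sklearn.model_selection import KFold
        cat = TargetEncoder(
            target_type="binary" if task.is_binary else "multiclass",
            cv=KFold(n_splits=5, shuffle=True, random_state=seed % 2**31))
    else:
        raise ValueError(f"unknown encoding {encoding!r}")
    ct = ColumnTransformer(
        [("cat", cat, list(task.categorical_cols)),
         ("num", "passthrough", list(task.numeric_cols))],
        remainder="drop")
    steps = [("encode", ct)]
    if scale:
        steps.append(("scale", StandardScaler()))
    return Pipeline(steps)


# --------------------------------------------------------------------------
# Tuning
# --------------------------------------------------------------------------

@dataclass
class BenchmarkConfig:
    """One cell of the benchmark grid."""

    learner: str = "logistic"
    tuning_criterion: str = "f1"
    search: str = "random"
    inner_eval: str = "holdout"  # "holdout" | "cv10"
    rebalance: str = "none"
    encoding: str = "one_hot"
    seed: int = 0
    search_budget: int = 10
    brier_convention: str = "sum"

    def validate(self, n_classes: int) -> None:
        if self.learner not in LEARNERS:
            raise ValueError(f"unknown learner {self.learner!r}")
        if self.tuning_criterion not in CRITERIA:
            raise ValueError(f"unknown criterion {self.tuning_criterion!r}")
        if self.rebalance not in REBALANCE:
            raise ValueError(f"unknown rebalance {self.rebalance!r}")
        if self.search not in ("random", "bayesian"):
            raise ValueError(f"unknown search {self.search!r}")
        if self.inner_eval not in ("holdout", "cv10"):
            raise ValueError(f"unknown inner_eval {self.inner_eval!r}")
        binary = n_classes == 2
        if binary and self.tuning_criterion in ("f1_macro", "multiclass_brier"):
            raise ValueError(f"{self.tuning_criterion} requires the 3-class task")
        if not binary and self.tuning_criterion in ("f1", "brier"):
            raise ValueError(f"{self.tuning_criterion} requires a binary task")


def _sample_params(space: dict, rng: np.random.Generator) -> dict:
    out = {}
    for name, spec in space.items():
        kind = spec[0]
        if kind == "log":
            out[name] = float(np.exp(rng.uniform(np.log(spec[1]), np.log(spec[2]))))
        elif kind == "int":
            out[name] = int(rng.integers(spec[1], spec[2] + 1))
        else:
            out[name] = spec[1][int(rng.integers(len(spec[1])))]
    return out


def _params_to_vector(space: dict, params: dict) -> np.ndarray:
    vec = []
    for name, spec in space.items():
        kind = spec[0]
        if kind == "log":
            vec.append((np.log(params[name]) - np.log(spec[1]))
                       / (np.log(spec[2]) - np.log(spec[1])))
        elif kind == "int":
            vec.append((params[name] - spec[1]) / max(spec[2] - spec[1], 1))
        else:
            vec.append(spec[1].index(params[name]) / max(len(spec[1]) - 1, 1))
    return np.asarray(vec, dtype=float)


class BenchmarkClassifier(BaseEstimator, ClassifierMixin):
    """Tuned task classifier with grouped inner evaluation.

    ``fit(X, y, groups)`` tunes hyperparameters on the configured inner
    resampling (grouped holdout or grouped 10-fold CV), with rebalancing
    and categorical encoding fitted inside each inner training fold, then
    refits the winning configuration on all training data.

    Attributes
    ----------
    best_params_ : dict
    best_score_ : float
        Inner score of the winner (higher is better; Brier criteria are
        negated internally).
    trace_ : list of dict
        Every trial with its parameters and inner score.
    """

    def __init__(self, task_meta: TaskDataset | None = None,
                 config: BenchmarkConfig | None = None):
        self.task_meta = task_meta
        self.config = config

    # -- scoring ------------------------------------------------------------
    def _score(self, model, enc, X_val, y_val) -> float:
        proba = model.predict_proba(enc.transform(X_val))
        pred = model.classes_[np.argmax(proba, axis=1)]
        crit = self.config.tuning_criterion
        if crit == "f1":
            pos = np.flatnonzero(model.classes_ == 1)
            p1 = proba[:, pos[0]] if len(pos) else np.zeros(len(X_val))
            return binary_metrics(y_val, pred, p1)["f1"]
        if crit == "brier":
            pos = np.flatnonzero(model.classes_ == 1)
            p1 = proba[:, pos[0]] if len(pos) else np.zeros(len(X_val))
            return -binary_metrics(y_val, pred, p1)["brier"]
        full = np.zeros((len(X_val), len(self.classes_)))
        for j, c in enumerate(self.classes_):
            k = np.flatnonzero(model.classes_ == c)
            if len(k):
                full[:, j] = proba[:, k[0]]
        m = multiclass_metrics(y_val, pred, full, classes=self.classes_,
                               brier_convention=self.config.brier_convention)
        return m["f1_macro"] if crit == "f1_macro" else -m["brier"]

    def _fit_candidate(self, params: dict, X, y, groups, inner_plans,
                       seed: int) -> float:
        cfg = self.config
        scores = []
        for train_p, val_p in inner_plans:
            tr = np.isin(groups, list(train_p))
            va = np.isin(groups, list(val_p))
            enc = _make_encoder(self.task_meta, cfg.encoding, seed,
                                scale=cfg.learner in ("logistic",
                                                      "multilayer_perceptron"))
            Xtr = enc.fit_transform(X[tr], y[tr])
            Xtr, ytr = rebalance_training(Xtr, y[tr], cfg.rebalance, seed=seed)
            model = _make_learner(cfg.learner, params, len(self.classes_), seed)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model.fit(Xtr, ytr)
            scores.append(self._score(model, enc, X[va], y[va]))
        return float(np.mean(scores))

    # -- fit ----------------------------------------------------------------
    def fit(self, X: pd.DataFrame, y, groups):
        cfg = self.config or BenchmarkConfig()
        self.config = cfg
        y = np.asarray(y)
        groups = np.asarray(groups)
        self.classes_ = np.unique(y)
        cfg.validate(len(self.classes_))
        rng = np.random.default_rng(cfg.seed)

        space = _SEARCH_SPACES.get(cfg.learner, {})
        patients = sorted(set(groups))
        if cfg.inner_eval == "holdout":
            inner = grouped_split_patients(patients, 0.2, seed=cfg.seed + 1)
            inner_plans = [inner]
        else:
            folds = grouped_cv_folds(patients, k=10, seed=cfg.seed + 1)
            inner_plans = []
            for f in range(10):
                val = tuple(p for p, v in folds.items() if v == f)
                trn = tuple(p for p, v in folds.items() if v != f)
                inner_plans.append((trn, val))

        self.trace_ = []
        if cfg.learner == "dummy" or not space or cfg.search_budget == 0:
            if cfg.search_budget == 0 and cfg.learner != "dummy":
                warnings.warn("search budget 0: using default hyperparameters",
                              stacklevel=2)
            self.best_params_ = {}
            self.best_score_ = np.nan
        elif cfg.search == "random":
            best, best_score = None, -np.inf
            for t in range(cfg.search_budget):
                params = _sample_params(space, rng)
                score = self._fit_candidate(params, X, y, groups, inner_plans,
                                            seed=cfg.seed + 100 + t)
                self.trace_.append({"trial": t, "params": params, "score": score})
                if score > best_score:
                    best, best_score = params, score
            self.best_params_, self.best_score_ = best, best_score
        else:
            self.best_params_, self.best_score_ = self._bayesian_search(
                space, X, y, groups, inner_plans, rng)

        enc = _make_encoder(self.task_meta, cfg.encoding, cfg.seed,
                            scale=cfg.learner in ("logistic",
                                                  "multilayer_perceptron"))
        Xenc = enc.fit_transform(X, y)
        Xres, yres = rebalance_training(Xenc, y, cfg.rebalance, seed=cfg.seed)
        model = _make_learner(cfg.learner, self.best_params_ or {},
                              len(self.classes_), cfg.seed)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model.fit(Xres, yres)
        self.encoder_ = enc
        self.model_ = model
        self.feature_names_in_ = np.asarray(X.columns, dtype=object)
        return self

    def _bayesian_search(self, space, X, y, groups, inner_plans, rng):
        """Sequential GP expected-improvement over the unit-cube-encoded
        hyperparameter space; categorical dims are snapped to grid."""
        budget = self.config.search_budget
        n_init = min(4, budget)
        tried, vecs, scores = [], [], []
        for t in range(budget):
            if t < n_init:
                params = _sample_params(space, rng)
            else:
                gp = GaussianProcessRegressor(
                    kernel=Matern(nu=2.5), normalize_y=True, alpha=1e-6,
                    random_state=int(rng.integers(2**31)))
                gp.fit(np.vstack(vecs), np.asarray(scores))
                cands = [_sample_params(space, rng) for _ in range(128)]
                cvecs = np.vstack([_params_to_vector(space, c) for c in cands])
                mu, sd = gp.predict(cvecs, return_std=True)
                best = max(scores)
                z = (mu - best) / np.maximum(sd, 1e-9)
                ei = (mu - best) * stats.norm.cdf(z) + sd * stats.norm.pdf(z)
                params = cands[int(np.argmax(ei))]
            score = self._fit_candidate(params, X, y, groups, inner_plans,
                                        seed=self.config.seed + 100 + t)
            tried.append(params)
            vecs.append(_params_to_vector(space, params))
            scores.append(score)
            self.trace_.append({"trial": t, "params": params, "score": score})
        k = int(np.argmax(scores))
        return tried[k], float(scores[k])

    # -- predict ------------------------------------------------------------
    def _check_schema(self, X: pd.DataFrame) -> None:
        missing = [c for c in self.feature_names_in_ if c not in X.columns]
        extra = [c for c in X.columns if c not in self.feature_names_in_]
        if missing or extra:
            raise ValueError(f"schema mismatch: missing={missing} extra={extra}")

    def predict_proba(self, X: pd.DataFrame) -> np.ndarray:
        self._check_schema(X)
        proba = self.model_.predict_proba(self.encoder_.transform(X))
        if proba.shape[1] != len(self.classes_):
            full = np.zeros((len(X), len(self.classes_)))
            for j, c in enumerate(self.classes_):
                k = np.flatnonzero(self.model_.classes_ == c)
                if len(k):
                    full[:, j] = proba[:, k[0]]
            proba = full
        return proba

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        return self.classes_[np.argmax(self.predict_proba(X), axis=1)]


def grouped_split_patients(patients: Sequence, test_fraction: float,
                           seed: int) -> tuple[tuple, tuple]:
    """Patient-level partition used for inner holdout evaluation."""
    patients = np.array(sorted(set(patients)), dtype=object)
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(patients))
    n_test = max(1, int(round(test_fraction * len(patients))))
    n_test = min(n_test, len(patients) - 1)
    return (tuple(patients[order[n_test:]].tolist()),
            tuple(patients[order[:n_test]].tolist()))


def tune_and_train(task: TaskDataset, config: BenchmarkConfig,
                   train_patients: Sequence | None = None) -> BenchmarkClassifier:
    """Tune and fit one benchmark configuration on (a subset of) the task."""
    mask = (np.isin(task.groups, list(train_patients))
            if train_patients is not None else np.ones(len(task), dtype=bool))
    clf = BenchmarkClassifier(task_meta=task, config=config)
    return clf.fit(task.features[mask], task.labels[mask], task.groups[mask])


def predict_proba(model, rows: pd.DataFrame) -> np.ndarray:
    """Probability rows for fitted models; rows must match training schema."""
    return model.predict_proba(rows)


def benchmark_grid(
    learners: Sequence[str] = ("dummy", "logistic", "random_forest",
                               "gradient_boosting", "multilayer_perceptron"),
    criteria: Sequence[str] = ("f1", "brier"),
    rebalance: Sequence[str] = REBALANCE,
    encodings: Sequence[str] = ("one_hot", "target"),
    **common,
) -> list[BenchmarkConfig]:
    """Enumerate the learner x criterion x rebalance x encoding grid."""
    grid = [
        BenchmarkConfig(learner=l, tuning_criterion=c, rebalance=r,
                        encoding=e, **common)
        for l in learners for c in criteria for r in rebalance for e in encodings
    ]
    return grid


def run_benchmark(task: TaskDataset, configs: Sequence[BenchmarkConfig],
                  test_fraction: float = 0.2, seed: int = 0) -> pd.DataFrame:
    """Fit every configuration on a shared grouped split; score on test."""
    plan = grouped_split(task, test_fraction=test_fraction, seed=seed)
    test_mask = np.isin(task.groups, list(plan.test_patients))
    rows = []
    for cfg in configs:
        clf = tune_and_train(task, cfg, train_patients=plan.train_patients)
        proba = clf.predict_proba(task.features[test_mask])
        pred = clf.predict(task.features[test_mask])
        y = task.labels[test_mask]
        if task.is_binary:
            j = int(np.flatnonzero(clf.classes_ == 1)[0])
            m = binary_metrics(y, pred, proba[:, j])
        else:
            m = multiclass_metrics(y, pred, proba, classes=clf.classes_,
                                   brier_convention=cfg.brier_convention)
            m.pop("brier_convention")
            m["class_f1"] = str(m["class_f1"])
        rows.append({**asdict(cfg), **m})
    return pd.DataFrame(rows)
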