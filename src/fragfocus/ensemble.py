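"""Six-member precision-tuned classifier ensemble with vote-threshold consensus.

The ensemble combines logistic regression, k-nearest neighbors, an RBF
support-vector classifier, a random forest, gradient-boosted trees
(XGBoost), and a feed-forward network.  Each member is tuned by a seeded
random search (default 300 trials) scored by mean cross-validated precision
(default 10 folds) subject to a recall floor, refit on the full training
split, and combined at predict time by counting positive votes: a compound
is a consensus positive when at least ``vote_threshold`` members (default
all six) call it active.  Unanimous voting makes the consensus positive set
the intersection of the member positive sets, so the ensemble's false
positive count can never exceed any single member's.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import joblib
import numpy as np
import pandas as pd
from scipy.stats import loguniform
from sklearn.base import clone
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import (
    average_precision_score,
    precision_recall_curve,
    roc_auc_score,
    roc_curve,
)
from sklearn.model_selection import ParameterSampler, StratifiedKFold, train_test_split
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from xgboost import XGBClassifier

MEMBER_ALGORITHMS = (
    "logistic_linear",
    "k_nearest_neighbor",
    "kernel_svm",
    "random_forest",
    "gradient_boosted_trees",
    "feedforward_net",
)

TUNING_OBJECTIVES = ("precision", "average_precision", "roc_auc")


@dataclass(frozen=True)
class MemberSpec:
    """One member: algorithm name, hyperparameter search space, preprocessing."""

    algorithm: str
    hyperparameter_space: dict
    preprocessing: str = "none"

    def __post_init__(self) -> None:
        if self.algorithm not in MEMBER_ALGORITHMS:
            raise ValueError(f"unknown algorithm {self.algorithm!r}")
        if self.preprocessing not in ("none", "standardize"):
            raise ValueError(f"unknown preprocessing {self.preprocessing!r}")


@dataclass(frozen=True)
class TuningConfig:
    """Random-search budget, CV folds, objective, and seed for member tuning.

    The precision objective is subject to ``recall_floor``: trials whose
    mean CV recall falls below it are rejected, which avoids the degenerate
    predict-almost-nothing optimum of a pure precision score.
    """

    n_trials: int = 300
    cv_folds: int = 10
    objective: str = "precision"
    seed: int = 0
    recall_floor: float = 0.25

    def __post_init__(self) -> None:
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")
        if self.objective not in TUNING_OBJECTIVES:
            raise ValueError(f"unknown objective {self.objective!r}")


def default_member_specs() -> list[MemberSpec]:
    """The six member specs with their default search spaces."""
    return [
        MemberSpec(
            "logistic_linear",
            {"C": loguniform(1e-3, 1e3)},
            preprocessing="standardize",
        ),
        MemberSpec(
            "k_nearest_neighbor",
            {"n_neighbors": list(range(3, 32)), "weights": ["uniform", "distance"]},
        ),
        MemberSpec(
            "kernel_svm",
            {"C": loguniform(1e-2, 1e3), "gamma": ["scale", "auto", 1e-4, 1e-3, 1e-2, 1e-1]},
            preprocessing="standardize",
        ),
        MemberSpec(
            "random_forest",
            {
                "n_estimators": [100, 200, 300],
                "max_depth": [None, 8, 16, 32],
                "max_features": ["sqrt", 0.1, 0.3],
            },
        ),
        MemberSpec(
            "gradient_boosted_trees",
            {
                "n_estimators": [100, 200, 300],
                "max_depth": [3, 4, 6, 8],
                "learning_rate": loguniform(1e-2, 0.3),
                "subsample": [0.7, 0.85, 1.0],
                "colsample_bytree": [0.5, 0.75, 1.0],
            },
        ),
        MemberSpec(
            "feedforward_net",
            {
                "hidden_layer_sizes": [(32,), (64,), (64, 32)],
                "alpha": loguniform(1e-5, 1e-1),
                "learning_rate_init": loguniform(1e-4, 1e-2),
            },
            preprocessing="standardize",
        ),
    ]


def _build_member(spec: MemberSpec, params: dict, seed: int, y: np.ndarray):
    """Instantiate one member with *params*; wraps a scaler when the spec asks."""
    alg = spec.algorithm
    if alg == "logistic_linear":
        est = LogisticRegression(max_iter=2000, class_weight="balanced", random_state=seed, **params)
    elif alg == "k_nearest_neighbor":
        # cosine distance suits sparse fingerprint blocks far better than
        # euclidean on standardized bits
        est = KNeighborsClassifier(metric="cosine", **params)
    elif alg == "kernel_svm":
        est = SVC(kernel="rbf", probability=True, class_weight="balanced", random_state=seed, **params)
    elif alg == "random_forest":
        est = RandomForestClassifier(class_weight="balanced", random_state=seed, n_jobs=1, **params)
    elif alg == "gradient_boosted_trees":
        pos = max(int((y == 1).sum()), 1)
        neg = int((y == 0).sum())
        est = XGBClassifier(
            eval_metric="logloss",
            scale_pos_weight=max(neg / pos, 1.0),
            random_state=seed,
            n_jobs=1,
            verbosity=0,
            **params,
        )
    elif alg == "feedforward_net":
        est = MLPClassifier(max_iter=300, tol=1e-3, random_state=seed, **params)
    else:  # pragma: no cover - guarded by MemberSpec
        raise ValueError(alg)
    if spec.preprocessing == "standardize":
        return Pipeline([("scale", StandardScaler()), ("clf", est)])
    return est


def _proba(est, X: np.ndarray) -> np.ndarray:
    return est.predict_proba(X)[:, 1]


def _confusion(y_true: np.ndarray, y_pred: np.ndarray) -> tuple[int, int, int, int]:
    tp = int(np.sum((y_true == 1) & (y_pred == 1)))
    fp = int(np.sum((y_true == 0) & (y_pred == 1)))
    tn = int(np.sum((y_true == 0) & (y_pred == 0)))
    fn = int(np.sum((y_true == 1) & (y_pred == 0)))
    return tp, fp, tn, fn


@dataclass(frozen=True)
class EvaluationMetrics:
    """Confusion counts with the derived rates used to judge members and ensemble."""

    tp: int
    fp: int
    tn: int
    fn: int
    precision: float
    recall: float
    accuracy: float
    roc_auc: float
    average_precision: float
    fpr: float

    @classmethod
    def from_counts(
        cls, tp: int, fp: int, tn: int, fn: int, roc_auc: float = float("nan"), ap: float = float("nan")
    ) -> "EvaluationMetrics":
        n = tp + fp + tn + fn
        return cls(
            tp=tp,
            fp=fp,
            tn=tn,
            fn=fn,
            precision=tp / (tp + fp) if tp + fp > 0 else float("nan"),
            recall=tp / (tp + fn) if tp + fn > 0 else float("nan"),
            accuracy=(tp + tn) / n if n > 0 else float("nan"),
            roc_auc=roc_auc,
            average_precision=ap,
            fpr=fp / (fp + tn) if fp + tn > 0 else float("nan"),
        )


def labels_to_y(labels: Sequence[str]) -> np.ndarray:
    """Map active/inactive labels to 1/0."""
    out = []
    for lab in labels:
        if lab == "active":
            out.append(1)
        elif lab == "inactive":
            out.append(0)
        else:
            raise ValueError(f"unlabeled or unknown label {lab!r}")
    return np.asarray(out, dtype=int)


def _as_array(X) -> np.ndarray:
    return X.to_numpy(dtype=np.float64) if isinstance(X, pd.DataFrame) else np.asarray(X, dtype=np.float64)


def split_train_test(
    X: pd.DataFrame | np.ndarray,
    y: Sequence[int] | Sequence[str],
    fraction: float = 0.9,
    seed: int = 0,
) -> tuple:
    """Stratified train/test split, default 90/10, reproducible for a seed."""
    y = labels_to_y(y) if len(y) and isinstance(y[0], str) else np.asarray(y, dtype=int)
    if len(y) < 10:
        raise ValueError("need at least 10 rows to split")
    if len(np.unique(y)) < 2:
        raise ValueError("cannot split a single-class dataset")
    X_train, X_test, y_train, y_test = train_test_split(
        X, y, train_size=fraction, random_state=seed, stratify=y, shuffle=True
    )
    return X_train, X_test, y_train, y_test


def tune_and_fit_member(
    spec: MemberSpec,
    X: pd.DataFrame | np.ndarray,
    y: Sequence[int],
    cfg: TuningConfig = TuningConfig(),
):
    """Random-search the spec's space, select the best trial, refit on all data.

    Returns ``(fitted member, best params, trial log)``; the log records
    every trial's parameters, mean CV objective, and mean CV recall.  For
    the precision objective, trials below the recall floor score ``-inf``.
    """
    if not spec.hyperparameter_space:
        raise ValueError("empty hyperparameter search space")
    Xa = _as_array(X)
    ya = np.asarray(y, dtype=int)
    sampler = ParameterSampler(spec.hyperparameter_space, n_iter=cfg.n_trials, random_state=cfg.seed)
    skf = StratifiedKFold(n_splits=cfg.cv_folds, shuffle=True, random_state=cfg.seed)
    splits = list(skf.split(Xa, ya))

    log = []
    best_key, best_params = (-np.inf, -np.inf), None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for trial, params in enumerate(sampler):
            fold_obj, fold_rec = [], []
            for tr_idx, va_idx in splits:
                est = _build_member(spec, params, cfg.seed, ya[tr_idx])
                est.fit(Xa[tr_idx], ya[tr_idx])
                scores = _proba(est, Xa[va_idx])
                pred = (scores >= 0.5).astype(int)
                tp, fp, tn, fn = _confusion(ya[va_idx], pred)
                if cfg.objective == "precision":
                    fold_obj.append(tp / (tp + fp) if tp + fp > 0 else 0.0)
                elif cfg.objective == "average_precision":
                    fold_obj.append(average_precision_score(ya[va_idx], scores))
                else:
                    fold_obj.append(roc_auc_score(ya[va_idx], scores))
                fold_rec.append(tp / (tp + fn) if tp + fn > 0 else 0.0)
            mean_obj = float(np.mean(fold_obj))
            mean_rec = float(np.mean(fold_rec))
            score = mean_obj
            if cfg.objective == "precision" and mean_rec < cfg.recall_floor:
                score = -np.inf
            log.append({"trial": trial, "params": params, "objective": mean_obj, "recall": mean_rec})
            # ties on the objective (common on separable data) break by recall
            if (score, mean_rec) > best_key:
                best_key, best_params = (score, mean_rec), params
        if best_params is None:
            # every trial failed the recall floor; fall back to the best raw objective
            best_params = max(log, key=lambda e: e["objective"])["params"]
        member = _build_member(spec, best_params, cfg.seed, ya)
        member.fit(Xa, ya)
    return member, best_params, log


@dataclass
class EnsembleModel:
    """Six fitted members, a vote threshold, the feature schema, and provenance."""

    members: dict
    best_params: dict
    vote_threshold: int = 6
    feature_schema: list[str] = field(default_factory=list)
    manifest: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 1 <= self.vote_threshold <= len(self.members):
            raise ValueError("vote_threshold out of range")

    def _check_schema(self, X) -> np.ndarray:
        if isinstance(X, pd.DataFrame) and self.feature_schema:
            cols = list(X.columns)
            if cols != self.feature_schema:
                for i, (got, want) in enumerate(zip(cols, self.feature_schema)):
                    if got != want:
                        raise ValueError(f"feature schema mismatch at column {i}: got {got!r}, expected {want!r}")
                raise ValueError(
                    f"feature schema mismatch: got {len(cols)} columns, expected {len(self.feature_schema)}"
                )
        elif not isinstance(X, pd.DataFrame) and self.feature_schema:
            if np.asarray(X).shape[1] != len(self.feature_schema):
                raise ValueError(
                    f"feature schema mismatch: got {np.asarray(X).shape[1]} columns, "
                    f"expected {len(self.feature_schema)}"
                )
        return _as_array(X)

    def member_probabilities(self, X) -> pd.DataFrame:
        Xa = self._check_schema(X)
        return pd.DataFrame({alg: _proba(est, Xa) for alg, est in self.members.items()})

    def predict_votes(self, X) -> np.ndarray:
        """Per-row count of members whose positive-class probability is >= 0.5."""
        probs = self.member_probabilities(X)
        return (probs.to_numpy() >= 0.5).sum(axis=1).astype(int)

    def predict(self, X, threshold: Optional[int] = None) -> np.ndarray:
        t = self.vote_threshold if threshold is None else threshold
        return consensus_classify(self.predict_votes(X), t).astype(int)


def consensus_classify(votes: np.ndarray | int, threshold: int) -> np.ndarray | bool:
    """True where the vote count reaches the threshold."""
    if not 1 <= threshold <= 6:
        raise ValueError("threshold must be in [1, 6]")
    if np.isscalar(votes):
        return bool(votes >= threshold)
    return np.asarray(votes) >= threshold


def train_ensemble(
    X: pd.DataFrame | np.ndarray,
    y: Sequence[int] | Sequence[str],
    specs: Optional[list[MemberSpec]] = None,
    tuning: TuningConfig = TuningConfig(),
    vote_threshold: int = 6,
) -> EnsembleModel:
    """Tune and fit all six members on the training split and assemble the ensemble."""
    specs = specs if specs is not None else default_member_specs()
    algs = [s.algorithm for s in specs]
    if sorted(algs) != sorted(set(algs)):
        raise ValueError("duplicate member algorithms in ensemble spec")
    y = labels_to_y(y) if len(y) and isinstance(y[0], str) else np.asarray(y, dtype=int)
    members, best_params, logs = {}, {}, {}
    for i, spec in enumerate(specs):
        member_cfg = TuningConfig(
            n_trials=tuning.n_trials,
            cv_folds=tuning.cv_folds,
            objective=tuning.objective,
            seed=tuning.seed + i,
            recall_floor=tuning.recall_floor,
        )
        member, params, log = tune_and_fit_member(spec, X, y, member_cfg)
        members[spec.algorithm] = member
        best_params[spec.algorithm] = params
        logs[spec.algorithm] = log
    schema = list(X.columns) if isinstance(X, pd.DataFrame) else []
    manifest = {"tuning": tuning, "trial_logs": logs}
    return EnsembleModel(members, best_params, vote_threshold, schema, manifest)


def evaluate(model, X, y_true: Sequence[int] | Sequence[str]) -> tuple[EvaluationMetrics, dict]:
    """Metrics plus threshold-ordered ROC and precision-recall curve points.

    *model* may be an :class:`EnsembleModel` (scored by vote counts,
    decided by its vote threshold) or a single fitted member (scored by
    positive-class probability, decided at 0.5).  With single-class
    ``y_true`` the AUC metrics are reported as NaN.
    """
    y_true = labels_to_y(y_true) if len(y_true) and isinstance(y_true[0], str) else np.asarray(y_true, dtype=int)
    if isinstance(model, EnsembleModel):
        votes = model.predict_votes(X)
        scores = votes / len(model.members)
        y_pred = (votes >= model.vote_threshold).astype(int)
    else:
        scores = _proba(model, _as_array(X))
        y_pred = (scores >= 0.5).astype(int)
    tp, fp, tn, fn = _confusion(y_true, y_pred)
    curves: dict = {}
    if len(np.unique(y_true)) == 2:
        auc = float(roc_auc_score(y_true, scores))
        ap = float(average_precision_score(y_true, scores))
        fpr_c, tpr_c, roc_t = roc_curve(y_true, scores)
        prec_c, rec_c, pr_t = precision_recall_curve(y_true, scores)
        curves = {
            "roc": {"fpr": fpr_c.tolist(), "tpr": tpr_c.tolist(), "thresholds": roc_t.tolist()},
            "pr": {"precision": prec_c.tolist(), "recall": rec_c.tolist(), "thresholds": pr_t.tolist()},
        }
    else:
        auc = float("nan")
        ap = float("nan")
    return EvaluationMetrics.from_counts(tp, fp, tn, fn, auc, ap), curves


def negative_pool_fpr(
    model: EnsembleModel, negatives, thresholds: Sequence[int] = (1, 2, 3, 4, 5, 6)
) -> dict[int, float]:
    """False positive rate on an assumed-inactive pool, per vote threshold.

    The pool is treated as all-negative, so the FPR at threshold *t* is the
    fraction of rows with at least *t* positive votes; the table is
    non-increasing in *t*.
    """
    n = len(negatives)
    if n == 0:
        raise ValueError("empty negative pool")
    votes = model.predict_votes(negatives)
    return {int(t): float(np.mean(votes >= t)) for t in thresholds}


def save_model(model: EnsembleModel, path: str | Path) -> None:
    """Persist the fitted ensemble (members, hyperparameters, schema, manifest)."""
    joblib.dump(
        {
            "members": model.members,
            "best_params": model.best_params,
            "vote_threshold": model.vote_threshold,
            "feature_schema": model.feature_schema,
            "manifest": model.manifest,
        },
        path,
    )


def load_model(path: str | Path) -> EnsembleModel:
    d = joblib.load(path)
    return EnsembleModel(d["members"], d["best_params"], d["vote_threshold"], d["feature_schema"], d["manifest"])
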