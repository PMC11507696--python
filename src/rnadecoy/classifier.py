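"""Boosted decoy classification and ROC evaluation.

An adaptive-boosting ensemble of depth-1 decision trees (stumps) maps the
six per-sequence features to a decoy probability. Two boosting variants are
exposed: ``discrete-vote`` (each stump casts a weighted class vote; delegated
to scikit-learn's AdaBoostClassifier) and ``probability-weighted`` (stumps
contribute real-valued half-log-odds; implemented here over scikit-learn
stumps). Model selection uses grouped cross-validated grid search scored by
area under the ROC curve, so sequences from one group never straddle a fold
boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import joblib
import numpy as np
from scipy.special import expit
from sklearn.ensemble import AdaBoostClassifier
from sklearn.metrics import roc_curve as _sk_roc_curve
from sklearn.model_selection import GroupKFold
from sklearn.tree import DecisionTreeClassifier

from .core import LABEL_DECOY
from .features import FEATURE_NAMES, feature_table

__all__ = [
    "BoostModel",
    "RocCurve",
    "DEFAULT_THRESHOLD",
    "DESK_PARAM_GRID",
    "train",
    "grid_search",
    "classify_group",
    "roc",
]

#: Example operating threshold on the decoy probability; corresponds to a 5%
#: homolog-misclassification rate for one particular trained model and should
#: be re-derived from the ROC for any retrained model.
DEFAULT_THRESHOLD = 0.4971

MODEL_FORMAT_VERSION = 1

#: Desk-scale hyperparameter grid (logarithmic subsample of the full
#: 20..20000 / 0.5..20 ranges).
DESK_PARAM_GRID = {
    "n_estimators": [20, 100, 500, 2000],
    "learning_rate": [0.5, 1.0, 5.0, 20.0],
    "variant": ["discrete-vote", "probability-weighted"],
}

_PROBA_EPS = 1e-9


def labels_to_binary(labels: Sequence[str]) -> np.ndarray:
    """1 for decoys (any label starting with 'decoy'), 0 for homologs."""
    return np.array([1 if str(l).startswith(LABEL_DECOY) else 0 for l in labels])


class _RealBoost:
    """Probability-weighted (real) AdaBoost for two classes.

    Each round fits a stump on the current weights; its class-1 probability
    p(x) contributes learning_rate * 0.5 * log(p / (1-p)) to the decision
    function, and weights are updated multiplicatively with the same
    quantity. The decoy probability is the logistic of the mean stump
    contribution.
    """

    def __init__(self, n_estimators: int, learning_rate: float, seed: int = 0):
        self.n_estimators = n_estimators
        self.learning_rate = learning_rate
        self.seed = seed
        self.stumps_: list[DecisionTreeClassifier] = []

    def fit(self, X: np.ndarray, y: np.ndarray) -> "_RealBoost":
        n = X.shape[0]
        w = np.full(n, 1.0 / n)
        ysign = np.where(y == 1, 1.0, -1.0)
        self.stumps_ = []
        for t in range(self.n_estimators):
            stump = DecisionTreeClassifier(max_depth=1,
                                           random_state=self.seed + t)
            stump.fit(X, y, sample_weight=w)
            p = stump.predict_proba(X)
            if p.shape[1] == 1:  # degenerate: stump saw one class
                break
            p1 = np.clip(p[:, 1], _PROBA_EPS, 1 - _PROBA_EPS)
            h = 0.5 * np.log(p1 / (1.0 - p1))
            self.stumps_.append(stump)
            w = w * np.exp(-self.learning_rate * ysign * h)
            total = w.sum()
            if total <= 0 or not np.isfinite(total):
                break
            w /= total
        return self

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        df = np.zeros(X.shape[0])
        for stump in self.stumps_:
            p1 = np.clip(stump.predict_proba(X)[:, 1], _PROBA_EPS, 1 - _PROBA_EPS)
            df += self.learning_rate * 0.5 * np.log(p1 / (1.0 - p1))
        return df

    def predict_proba1(self, X: np.ndarray) -> np.ndarray:
        return expit(self.decision_function(X) / max(len(self.stumps_), 1))


@dataclass
class BoostModel:
    """A trained boosted decoy classifier."""

    variant: str = "probability-weighted"
    n_estimators: int = 500
    learning_rate: float = 1.0
    seed: int = 0
    _backend: object = field(default=None, repr=False)
    feature_names: tuple = FEATURE_NAMES

    def fit(self, X: np.ndarray, y: np.ndarray) -> "BoostModel":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if len(np.unique(y)) < 2:
            raise ValueError("training data must contain both classes")
        if self.variant == "discrete-vote":
            backend = AdaBoostClassifier(
                estimator=DecisionTreeClassifier(max_depth=1),
                n_estimators=self.n_estimators,
                learning_rate=self.learning_rate,
                random_state=self.seed)
            backend.fit(X, y)
        elif self.variant == "probability-weighted":
            backend = _RealBoost(self.n_estimators, self.learning_rate,
                                 self.seed).fit(X, y)
        else:
            raise ValueError(f"unknown boosting variant {self.variant!r}")
        self._backend = backend
        return self

    def predict_probability(self, X: np.ndarray) -> np.ndarray:
        """Decoy probability in [0, 1] for each feature row."""
        if self._backend is None:
            raise ValueError("model is not fitted")
        X = np.asarray(X, dtype=float)
        if isinstance(self._backend, AdaBoostClassifier):
            idx = list(self._backend.classes_).index(1)
            return self._backend.predict_proba(X)[:, idx]
        return self._backend.predict_proba1(X)

    def save(self, path) -> None:
        joblib.dump({"format_version": MODEL_FORMAT_VERSION, "model": self}, path)

    @classmethod
    def load(cls, path) -> "BoostModel":
        payload = joblib.load(path)
        if payload.get("format_version") != MODEL_FORMAT_VERSION:
            raise ValueError("unsupported model file version")
        return payload["model"]


def train(features: np.ndarray, labels: Sequence, n_estimators: int = 500,
          learning_rate: float = 1.0, variant: str = "probability-weighted",
          seed: int = 0) -> BoostModel:
    """Train a boosted classifier on per-sequence feature vectors.

    ``labels`` may be binary (1 = decoy) or label strings.
    """
    y = np.asarray(labels)
    if y.dtype.kind in "OUS":
        y = labels_to_binary(labels)
    model = BoostModel(variant=variant, n_estimators=n_estimators,
                       learning_rate=learning_rate, seed=seed)
    return model.fit(np.asarray(features, dtype=float), y)


def grid_search(X: np.ndarray, y: Sequence, group_ids: Sequence,
                param_grid: Optional[dict] = None, folds: int = 3,
                seed: int = 0) -> tuple[dict, list[dict]]:
    """Grouped cross-validated grid search maximizing ROC AUC.

    All sequences of a group stay in one fold. Returns (best_params,
    cv_table); ties break toward the first configuration in sorted order.
    """
    from sklearn.metrics import roc_auc_score

    if param_grid is None:
        param_grid = DESK_PARAM_GRID
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if y.dtype.kind in "OUS":
        y = labels_to_binary(y)
    groups = np.asarray(group_ids)
    n_groups = len(np.unique(groups))
    if folds > n_groups:
        raise ValueError("more folds than groups")
    splitter = GroupKFold(n_splits=folds)
    splits = list(splitter.split(X, y, groups))
    configs = [
        {"n_estimators": n, "learning_rate": lr, "variant": v}
        for n in param_grid.get("n_estimators", [500])
        for lr in param_grid.get("learning_rate", [1.0])
        for v in param_grid.get("variant", ["probability-weighted"])
    ]
    if not configs:
        raise ValueError("empty parameter grid")
    table = []
    for cfg in configs:
        aucs = []
        for tr, va in splits:
            if len(np.unique(y[tr])) < 2 or len(np.unique(y[va])) < 2:
                continue
            m = BoostModel(seed=seed, **cfg).fit(X[tr], y[tr])
            aucs.append(roc_auc_score(y[va], m.predict_probability(X[va])))
        table.append({**cfg, "mean_auc": float(np.mean(aucs)) if aucs else float("nan")})
    best = max(table, key=lambda row: (row["mean_auc"],))
    best_params = {k: best[k] for k in ("n_estimators", "learning_rate", "variant")}
    return best_params, table


def classify_group(model: BoostModel, result,
                   threshold: float = DEFAULT_THRESHOLD):
    """Per-sequence decoy probabilities and verdicts for one group.

    Returns a DataFrame with the six features, the decoy probability, and a
    verdict ('decoy' iff probability >= threshold), in input order.
    """
    table = feature_table(result)
    X = table[list(FEATURE_NAMES)].to_numpy()
    prob = model.predict_probability(X)
    table["decoy_probability"] = prob
    table["verdict"] = np.where(prob >= threshold, "decoy", "homolog")
    return table


@dataclass
class RocCurve:
    """ROC points ordered by descending threshold, with trapezoidal AUC."""

    points: np.ndarray  # (n, 2) of (1 - specificity, sensitivity)
    auc: float
    thresholds: np.ndarray

    def sensitivity_at(self, fpr: float = 0.05) -> float:
        """Sensitivity at a given false-positive rate, linearly interpolated."""
        return float(np.interp(fpr, self.points[:, 0], self.points[:, 1]))


def roc(scores: Sequence[float], labels: Sequence) -> RocCurve:
    """ROC curve over all unique score thresholds.

    ``labels`` may be binary (1 = decoy, the positive class) or strings.
    """
    y = np.asarray(labels)
    if y.dtype.kind in "OUS":
        y = labels_to_binary(labels)
    if len(np.unique(y)) < 2:
        raise ValueError("ROC needs both classes present")
    fpr, tpr, thr = _sk_roc_curve(y, np.asarray(scores, dtype=float),
                                  drop_intermediate=False)
    auc = float(np.trapezoid(tpr, fpr))
    return RocCurve(points=np.column_stack([fpr, tpr]), auc=auc, thresholds=thr)
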