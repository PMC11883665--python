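"""Binary placement classifier over map-model score vectors.

A placed slice is accepted or rejected by a logistic-regression decision
function fitted with stochastic gradient descent (scikit-learn
``SGDClassifier`` with log loss).  The default hyperparameters are the
selected values of a randomized accuracy-scored search: alpha 0.001, l2
penalty, inverse-scaling learning rate with eta0 100 and power_t 0.9,
validation fraction 0.2, epsilon 0.1.  Training sets are balanced by
undersampling the majority class and split at map granularity, so the
classifier is always evaluated against maps it has not seen — multiple
placements are scored per map, and splitting rows at random would leak
map identity across the split.

Features are standardized with train-set statistics that are stored in the
model and reused verbatim at prediction time (a numerical necessity for
SGD at this learning rate).  The map's nominal resolution is carried in
every score vector but excluded from the feature set by default, which was
found to improve generalisation.  Models persist as plain JSON.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
from sklearn.linear_model import SGDClassifier
from sklearn.metrics import (accuracy_score, confusion_matrix, f1_score,
                             precision_score, recall_score, roc_auc_score)

from .density import ScoreVector

logger = logging.getLogger(__name__)

__all__ = [
    "TrainingRow",
    "TrainingSet",
    "Hyperparameters",
    "ClassifierModel",
    "EvaluationReport",
    "balance_undersample",
    "grouped_split",
    "train",
    "predict_proba",
    "classify",
    "evaluate",
    "ablation",
    "random_search",
]

_SKLEARN_LOSS = {"log": "log_loss"}


@dataclass
class TrainingRow:
    scores: ScoreVector
    label: int           # 1 = correct placement, 0 = incorrect
    group: str           # map id

    def __post_init__(self) -> None:
        if self.label not in (0, 1):
            raise ValueError(f"label must be 0 or 1, got {self.label}")


@dataclass
class TrainingSet:
    rows: list[TrainingRow]

    def __len__(self) -> int:
        return len(self.rows)

    def labels(self) -> np.ndarray:
        return np.array([r.label for r in self.rows], dtype=int)

    def groups(self) -> np.ndarray:
        return np.array([r.group for r in self.rows])

    def matrix(self, use_resolution: bool = False) -> np.ndarray:
        return np.array([r.scores.as_array(use_resolution) for r in self.rows])


@dataclass
class Hyperparameters:
    """SGD hyperparameters; defaults are the selected search values."""

    alpha: float = 0.001
    penalty: str = "l2"
    learning_rate: str = "invscaling"
    eta0: float = 100.0
    loss: str = "log"
    power_t: float = 0.9
    validation_fraction: float = 0.2
    epsilon: float = 0.1

    #: the printed randomized-search space
    SEARCH_SPACE = {
        "alpha": [0.0001, 0.001, 0.01, 0.1, 1, 10, 100],
        "penalty": ["l2", "l1", "elasticnet", None],
        "learning_rate": ["optimal", "invscaling", "adaptive"],
        "eta0": [0.01, 0.1, 1, 10, 100],
        "loss": ["hinge", "log", "modified_huber", "squared_hinge",
                 "perceptron"],
        "power_t": [0.1, 0.2, 0.5, 0.55, 0.9],
        "validation_fraction": [0.1, 0.2, 0.3],
        "epsilon": [0.1, 0.2, 0.3],
    }

    def to_sklearn(self, seed: int | None = None) -> SGDClassifier:
        return SGDClassifier(
            loss=_SKLEARN_LOSS.get(self.loss, self.loss),
            penalty=self.penalty, alpha=self.alpha,
            learning_rate=self.learning_rate, eta0=self.eta0,
            power_t=self.power_t,
            validation_fraction=self.validation_fraction,
            epsilon=self.epsilon, random_state=seed, max_iter=1000,
            tol=1e-3)


@dataclass
class ClassifierModel:
    """A trained, standardized logistic placement gate."""

    feature_names: list[str]
    means: np.ndarray
    sds: np.ndarray
    weights: np.ndarray
    intercept: float
    hyperparameters: Hyperparameters
    cutoff: float = 0.5
    use_resolution: bool = False

    def __post_init__(self) -> None:
        self.means = np.asarray(self.means, dtype=float)
        self.sds = np.asarray(self.sds, dtype=float)
        self.weights = np.asarray(self.weights, dtype=float)
        if len(self.weights) != len(self.feature_names):
            raise ValueError("weight length does not match feature count")
        if not 0.0 < self.cutoff < 1.0:
            raise ValueError(f"cutoff must lie in (0, 1), got {self.cutoff}")

    def decision(self, features: np.ndarray) -> np.ndarray:
        z = (np.atleast_2d(features) - self.means) / self.sds
        return z @ self.weights + self.intercept

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "feature_names": self.feature_names,
            "means": self.means.tolist(),
            "sds": self.sds.tolist(),
            "weights": self.weights.tolist(),
            "intercept": self.intercept,
            "hyperparameters": asdict(self.hyperparameters),
            "cutoff": self.cutoff,
            "use_resolution": self.use_resolution,
        }
        text = json.dumps(payload, indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "ClassifierModel":
        text = Path(source).read_text() if Path(str(source)).is_file() else str(source)
        d = json.loads(text)
        return cls(d["feature_names"], np.array(d["means"]),
                   np.array(d["sds"]), np.array(d["weights"]),
                   d["intercept"], Hyperparameters(**d["hyperparameters"]),
                   d["cutoff"], d["use_resolution"])


@dataclass
class EvaluationReport:
    roc_auc: float | None
    f1: float
    recall: float
    precision: float
    accuracy: float
    confusion: np.ndarray  # 2x2, rows = true, cols = predicted

    def to_dict(self) -> dict:
        return {"roc_auc": self.roc_auc, "f1": self.f1, "recall": self.recall,
                "precision": self.precision, "accuracy": self.accuracy,
                "confusion": np.asarray(self.confusion).tolist()}


def balance_undersample(ts: TrainingSet, seed: int = 0) -> TrainingSet:
    """Randomly subsample the majority class to the minority count."""
    labels = ts.labels()
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present to balance")
    if n_pos == n_neg:
        return TrainingSet(list(ts.rows))
    rng = np.random.default_rng(seed)
    minority = 1 if n_pos < n_neg else 0
    keep_idx = np.where(labels == minority)[0].tolist()
    maj_idx = np.where(labels != minority)[0]
    keep_idx += rng.choice(maj_idx, size=min(n_pos, n_neg),
                           replace=False).tolist()
    keep_idx.sort()
    return TrainingSet([ts.rows[i] for i in keep_idx])


def grouped_split(ts: TrainingSet, test_fraction: float = 0.3,
                  seed: int = 0) -> tuple[TrainingSet, TrainingSet]:
    """Train/test split at map (group) granularity; groups never straddle."""
    groups = sorted(set(ts.groups()))
    if len(groups) < 2:
        raise ValueError("grouped split needs at least 2 groups")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(groups)
    n_test = min(len(groups) - 1, max(1, round(test_fraction * len(groups))))
    test_groups = set(perm[:n_test])
    train_rows = [r for r in ts.rows if r.group not in test_groups]
    test_rows = [r for r in ts.rows if r.group in test_groups]
    return TrainingSet(train_rows), TrainingSet(test_rows)


def train(ts: TrainingSet, hp: Hyperparameters | None = None,
          use_resolution: bool = False, seed: int = 0,
          cutoff: float = 0.5) -> ClassifierModel:
    """Fit the standardized SGD logistic gate on a (balanced) training set.

    Rows with non-finite features are rejected with a log message; a
    zero-variance feature is a hard error naming the feature.
    """
    hp = hp or Hyperparameters()
    names = ScoreVector.feature_names(use_resolution)
    X = ts.matrix(use_resolution)
    y = ts.labels()
    finite = np.isfinite(X).all(axis=1)
    if not finite.all():
        logger.warning("rejecting %d rows with non-finite features",
                       int((~finite).sum()))
        X, y = X[finite], y[finite]
    if len(np.unique(y)) < 2:
        raise ValueError("training set must contain both classes")
    means = X.mean(axis=0)
    sds = X.std(axis=0)
    dead = [n for n, s in zip(names, sds) if s == 0]
    if dead:
        raise ValueError(f"zero-variance feature(s): {dead}")
    Z = (X - means) / sds
    clf = hp.to_sklearn(seed).fit(Z, y)
    # sklearn orders classes [0, 1]; decision > 0 means class 1
    return ClassifierModel(names, means, sds, clf.coef_.ravel(),
                           float(clf.intercept_[0]), hp, cutoff,
                           use_resolution)


def predict_proba(model: ClassifierModel, s: ScoreVector) -> float:
    """Probability that a placement is correct (logistic of the decision)."""
    if model.hyperparameters.loss not in ("log", "log_loss"):
        raise ValueError(
            f"loss {model.hyperparameters.loss!r} yields no probabilities; "
            "train with log loss")
    x = s.as_array(model.use_resolution)
    if not np.all(np.isfinite(x)):
        raise ValueError("score vector contains non-finite features")
    z = float(model.decision(x)[0])
    return float(1.0 / (1.0 + np.exp(-z)))


def classify(model: ClassifierModel, s: ScoreVector) -> tuple[str, float]:
    """'pass' iff probability is strictly greater than the cutoff."""
    p = predict_proba(model, s)
    return ("pass" if p > model.cutoff else "fail"), p


def _metrics(y_true: np.ndarray, y_pred: np.ndarray,
             y_score: np.ndarray) -> EvaluationReport:
    if len(np.unique(y_true)) < 2:
        auc = None
        logger.warning("single-class test set: ROC AUC undefined")
    else:
        auc = float(roc_auc_score(y_true, y_score))
    return EvaluationReport(
        roc_auc=auc,
        f1=float(f1_score(y_true, y_pred, zero_division=0)),
        recall=float(recall_score(y_true, y_pred, zero_division=0)),
        precision=float(precision_score(y_true, y_pred, zero_division=0)),
        accuracy=float(accuracy_score(y_true, y_pred)),
        confusion=confusion_matrix(y_true, y_pred, labels=[0, 1]))


def evaluate(model: ClassifierModel, test: TrainingSet,
             resolution_split: float | None = None
             ) -> EvaluationReport | dict[str, EvaluationReport]:
    """Metrics + confusion matrix on a held-out set.

    With ``resolution_split`` (e.g. 4 A), separate reports are returned for
    the high-resolution (<= split) and low-resolution (> split) subsets.
    """
    if len(test) == 0:
        raise ValueError("empty test set")
    if resolution_split is not None:
        high = TrainingSet([r for r in test.rows
                            if r.scores.resolution <= resolution_split])
        low = TrainingSet([r for r in test.rows
                           if r.scores.resolution > resolution_split])
        return {f"<={resolution_split}A": evaluate(model, high) if high.rows else None,
                f">{resolution_split}A": evaluate(model, low) if low.rows else None}
    y_true = test.labels()
    probs = np.array([predict_proba(model, r.scores) for r in test.rows])
    y_pred = (probs > model.cutoff).astype(int)
    return _metrics(y_true, y_pred, probs)


def ablation(ts: TrainingSet, hp: Hyperparameters | None = None,
             seed: int = 0, test_fraction: float = 0.3,
             use_resolution: bool = False) -> dict[str, EvaluationReport]:
    """Single-feature, drop-one-feature, and all-feature reports.

    Every variant is trained and tested under the identical grouped split,
    so differences reflect the feature sets alone.
    """
    names = ScoreVector.feature_names(use_resolution)
    if len(names) < 2:
        raise ValueError("ablation needs at least 2 features")
    tr, te = grouped_split(ts, test_fraction, seed)
    reports: dict[str, EvaluationReport] = {}
    X_tr, y_tr = tr.matrix(use_resolution), tr.labels()
    X_te, y_te = te.matrix(use_resolution), te.labels()
    hp = hp or Hyperparameters()

    def _fit_eval(cols: list[int]) -> EvaluationReport:
        Xs, Xt = X_tr[:, cols], X_te[:, cols]
        means, sds = Xs.mean(axis=0), Xs.std(axis=0)
        sds[sds == 0] = 1.0
        clf = hp.to_sklearn(seed).fit((Xs - means) / sds, y_tr)
        z = ((Xt - means) / sds) @ clf.coef_.ravel() + float(clf.intercept_[0])
        probs = 1.0 / (1.0 + np.exp(-z))
        return _metrics(y_te, (probs > 0.5).astype(int), probs)

    all_cols = list(range(len(names)))
    reports["all"] = _fit_eval(all_cols)
    for i, name in enumerate(names):
        reports[f"only_{name}"] = _fit_eval([i])
        reports[f"drop_{name}"] = _fit_eval([c for c in all_cols if c != i])
    return reports


def random_search(ts: TrainingSet, n_iter: int = 20, seed: int = 0,
                  test_fraction: float = 0.3) -> tuple[Hyperparameters, float]:
    """Seeded random search over the printed space, scored by accuracy."""
    rng = np.random.default_rng(seed)
    tr, te = grouped_split(ts, test_fraction, seed)
    best_hp, best_acc = Hyperparameters(), -1.0
    for _ in range(n_iter):
        draw = {k: v[rng.integers(len(v))]
                for k, v in Hyperparameters.SEARCH_SPACE.items()}
        if draw["loss"] != "log":
            draw["loss"] = "log"  # probabilities are required downstream
        hp = Hyperparameters(**draw)
        try:
            model = train(tr, hp, seed=seed)
            acc = evaluate(model, te).accuracy
        except (ValueError, ArithmeticError):
            continue
        if acc > best_acc:
            best_hp, best_acc = hp, acc
    return best_hp, best_acc
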