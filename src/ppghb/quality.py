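"""Cost-sensitive boosted signal-quality classification (AdaCost).

AdaCost is AdaBoost with a per-sample cost-adjustment of the weight update:
misclassifying an expensive sample inflates its weight more, and classifying
it correctly deflates its weight less, than for a cheap sample.  With the
cost-adjustment function

    β(i) = 0.5 + 0.5·c_i   if sample i is misclassified
    β(i) = 0.5 − 0.5·c_i   if sample i is classified correctly

the weight update is D_{t+1}(i) ∝ D_t(i)·exp(−α_t·y_i·h_t(x_i)·β(i)) and the
learner weight comes from the cost-weighted margin r = Σ_i D(i)·y_i·h(x_i)·β(i)
as α = ½·ln((1+r)/(1−r)).  With all costs zero, β ≡ 0.5 for both outcomes and
the dynamics reduce to AdaBoost's up to the constant margin scale.

Here quality labels are +1 (satisfactory) and −1 (poor); a poor signal passed
on as satisfactory corrupts the downstream regression, so poor-class samples
carry the higher cost (default 0.8 versus 0.2).

Weak learners are depth-limited decision trees (weighted-Gini splits).  The
fitted trees are flattened into plain arrays so the ensemble serializes to a
versioned JSON document and predicts without any fitted estimator state.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn.tree import DecisionTreeClassifier

from .errors import FitError

__all__ = [
    "QualitySample",
    "TreeLearner",
    "QualityModel",
    "DEFAULT_COSTS",
    "make_samples",
    "adacost_fit",
    "adacost_predict",
    "classification_report",
]

SATISFACTORY = 1
POOR = -1

#: Default misclassification costs per true class: letting a poor signal
#: through is the expensive mistake.
DEFAULT_COSTS = {POOR: 0.8, SATISFACTORY: 0.2}


@dataclass(frozen=True)
class QualitySample:
    """One annotated record: quality features, label ±1, cost in [0, 1]."""

    features: np.ndarray
    label: int
    cost: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "features", np.asarray(self.features, dtype=float))
        if self.label not in (SATISFACTORY, POOR):
            raise ValueError("label must be +1 (satisfactory) or -1 (poor)")
        if not 0.0 <= self.cost <= 1.0:
            raise ValueError("cost must lie in [0, 1]")
        if not np.all(np.isfinite(self.features)):
            raise ValueError("features must be finite")


def make_samples(features: np.ndarray, labels: Sequence[int],
                 costs: dict[int, float] | None = None) -> list[QualitySample]:
    """Bundle a feature matrix and labels into samples with per-class costs."""
    costs = DEFAULT_COSTS if costs is None else costs
    features = np.atleast_2d(np.asarray(features, dtype=float))
    return [QualitySample(features[i], int(labels[i]), costs[int(labels[i])])
            for i in range(features.shape[0])]


@dataclass(frozen=True)
class TreeLearner:
    """A decision tree flattened to arrays; leaves hold ±1 votes."""

    children_left: np.ndarray
    children_right: np.ndarray
    feature: np.ndarray
    threshold: np.ndarray
    leaf_value: np.ndarray

    @classmethod
    def from_sklearn(cls, tree: DecisionTreeClassifier) -> "TreeLearner":
        t = tree.tree_
        # per-node vote: sign of the weighted class balance, classes_ gives order
        votes = np.zeros(t.node_count)
        for node in range(t.node_count):
            counts = t.value[node][0]
            votes[node] = tree.classes_[int(np.argmax(counts))]
        return cls(
            children_left=t.children_left.copy(),
            children_right=t.children_right.copy(),
            feature=t.feature.copy(),
            threshold=t.threshold.copy(),
            leaf_value=votes,
        )

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        out = np.empty(X.shape[0])
        for i, row in enumerate(X):
            node = 0
            while self.children_left[node] != -1:
                if row[self.feature[node]] <= self.threshold[node]:
                    node = self.children_left[node]
                else:
                    node = self.children_right[node]
            out[i] = self.leaf_value[node]
        return out

    def to_dict(self) -> dict:
        return {k: getattr(self, k).tolist() for k in
                ("children_left", "children_right", "feature", "threshold", "leaf_value")}

    @classmethod
    def from_dict(cls, d: dict) -> "TreeLearner":
        return cls(**{k: np.asarray(d[k]) for k in
                      ("children_left", "children_right", "feature", "threshold",
                       "leaf_value")})


@dataclass
class QualityModel:
    """Boosted ensemble: weak trees, their weights and the cost map.

    ``fit_trace``, when present, holds one dict per boosting round with the
    pre-update sample weights, the cost-weighted margin and the learner
    weight — useful for auditing the weight dynamics; it is not serialized.
    """

    weak_learners: list[TreeLearner]
    alphas: np.ndarray
    cost_map: dict[int, float] = field(default_factory=lambda: dict(DEFAULT_COSTS))
    fit_trace: list[dict] | None = None

    def __post_init__(self) -> None:
        self.alphas = np.asarray(self.alphas, dtype=float)
        if len(self.weak_learners) < 1:
            raise ValueError("model needs at least one weak learner")
        if not np.all(np.isfinite(self.alphas)):
            raise ValueError("alphas must be finite")

    def to_json(self, path: str | Path | None = None) -> str:
        doc = {
            "format": "ppghb-quality-model",
            "version": 1,
            "alphas": self.alphas.tolist(),
            "cost_map": {str(k): v for k, v in self.cost_map.items()},
            "weak_learners": [t.to_dict() for t in self.weak_learners],
        }
        text = json.dumps(doc, indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "QualityModel":
        text = Path(source).read_text() if isinstance(source, Path) or \
            (isinstance(source, str) and "\n" not in source and Path(source).exists()) \
            else str(source)
        doc = json.loads(text)
        if doc.get("format") != "ppghb-quality-model":
            raise ValueError("not a quality-model document")
        return cls(
            weak_learners=[TreeLearner.from_dict(d) for d in doc["weak_learners"]],
            alphas=np.asarray(doc["alphas"], dtype=float),
            cost_map={int(k): float(v) for k, v in doc["cost_map"].items()},
        )


def adacost_fit(samples: Sequence[QualitySample], n_rounds: int = 20,
                seed: int = 0, max_depth: int = 2,
                collect_trace: bool = False) -> QualityModel:
    """Fit the cost-sensitive boosted ensemble.

    Boosting stops early when a round's weak learner is degenerate (weighted
    error ≥ 0.5, i.e. non-positive cost-weighted margin).  Deterministic
    given the seed.  With ``collect_trace`` the per-round weight dynamics are
    kept on the returned model.
    """
    if n_rounds < 1:
        raise ValueError("n_rounds must be >= 1")
    X = np.vstack([s.features for s in samples])
    y = np.array([s.label for s in samples], dtype=float)
    c = np.array([s.cost for s in samples], dtype=float)
    if np.unique(y).size < 2:
        raise FitError("both quality classes must be present in the training set")

    n = X.shape[0]
    D = np.full(n, 1.0 / n)
    learners: list[TreeLearner] = []
    alphas: list[float] = []
    trace: list[dict] = []
    for t in range(n_rounds):
        stump = DecisionTreeClassifier(max_depth=max_depth, random_state=seed)
        stump.fit(X, y, sample_weight=D)
        learner = TreeLearner.from_sklearn(stump)
        h = learner.predict(X)
        correct = h == y
        if float(D[~correct].sum()) >= 0.5:
            break  # degenerate weak learner: keep what we have
        beta = np.where(correct, 0.5 - 0.5 * c, 0.5 + 0.5 * c)
        u = y * h * beta
        r = float(np.clip(D @ u, -1.0 + 1e-12, 1.0 - 1e-12))
        if r <= 0:
            break
        alpha = 0.5 * np.log((1.0 + r) / (1.0 - r))
        learners.append(learner)
        alphas.append(alpha)
        D = D * np.exp(-alpha * u)
        D = D / D.sum()
        if collect_trace:
            trace.append({"round": t, "margin": r, "alpha": float(alpha),
                          "weights_after": D.copy(), "beta": beta.copy(),
                          "predictions": h.copy()})

    if not learners:
        raise FitError("no usable weak learner was found")
    cost_map = {POOR: float(c[y == POOR].max(initial=0.0)),
                SATISFACTORY: float(c[y == SATISFACTORY].max(initial=0.0))}
    return QualityModel(weak_learners=learners, alphas=np.array(alphas),
                        cost_map=cost_map,
                        fit_trace=trace if collect_trace else None)


def adacost_predict(model: QualityModel, features: np.ndarray
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Ensemble vote: labels (sign of the weighted sum) and raw margins."""
    X = np.atleast_2d(np.asarray(features, dtype=float))
    margins = np.zeros(X.shape[0])
    for alpha, learner in zip(model.alphas, model.weak_learners):
        margins += alpha * learner.predict(X)
    labels = np.where(margins >= 0, SATISFACTORY, POOR)
    return labels, margins


def classification_report(y_true: Sequence[int], y_pred: Sequence[int],
                          positive: int = POOR) -> tuple[float, float, float]:
    """(recall, precision, F1) with the poor-quality class as the positive class.

    A degenerate denominator (no predicted/true positives) is reported as 0
    with a warning rather than raising.
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.size == 0:
        raise ValueError("empty input")
    if y_true.shape != y_pred.shape:
        raise ValueError("length mismatch")
    tp = int(np.sum((y_true == positive) & (y_pred == positive)))
    fn = int(np.sum((y_true == positive) & (y_pred != positive)))
    fp = int(np.sum((y_true != positive) & (y_pred == positive)))
    if tp + fn == 0:
        warnings.warn("no positive examples: recall undefined, reported as 0")
        recall = 0.0
    else:
        recall = tp / (tp + fn)
    if tp + fp == 0:
        warnings.warn("no positive predictions: precision undefined, reported as 0")
        precision = 0.0
    else:
        precision = tp / (tp + fp)
    f1 = 0.0 if recall + precision == 0 else 2 * precision * recall / (precision + recall)
    return recall, precision, f1
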