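"""Feature-based activity classifiers and Gini-impurity feature importance.

The central objects follow the model/results convention: an
:class:`ActivityClassifier` is built from a labeled feature matrix and a
:class:`ClassifierSpec`; its :meth:`~ActivityClassifier.fit` returns an
:class:`ActivityClassifierResults` carrying the fitted estimator, the
training-fold z-scoring parameters, predictions, the per-feature Gini
importance for tree ensembles, and a ``summary()`` table.

Eight classifier families are supported: the two tree ensembles — random
forest (bagging: each of 100 trees fit on a bootstrap resample with a random
feature subset per split, majority vote) and AdaBoost (100 depth-limited
trees fit sequentially on reweighted data, weighted vote) — plus six
comparators: decision tree, k-NN (k=3), LDA, QDA, linear-kernel SVM and a
single-hidden-layer MLP.

Feature importance for an ensemble is the reach-weighted Gini-impurity
decrease: per internal node, p_parent*Gini(parent) - p_left*Gini(left) -
p_right*Gini(right), attributed to the split feature; per-tree totals are
divided by that tree's node count and averaged over trees. This denominator
differs from scikit-learn's ``feature_importances_`` (which normalizes each
tree's importances to sum to one), so scores are computed here directly from
the fitted tree structures.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.discriminant_analysis import (
    LinearDiscriminantAnalysis,
    QuadraticDiscriminantAnalysis,
)
from sklearn.ensemble import AdaBoostClassifier, RandomForestClassifier
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .featurize import FEATURE_COLUMNS, LabeledFeatureMatrix

logger = logging.getLogger(__name__)

CLASSIFIER_FAMILIES = (
    "random_forest",
    "adaboost",
    "decision_tree",
    "knn",
    "lda",
    "qda",
    "svm_linear",
    "mlp",
)

TREE_ENSEMBLES = ("random_forest", "adaboost")


class ModelError(ValueError):
    """Raised for invalid modeling configuration or inputs."""


@dataclass
class ClassifierSpec:
    """Configuration of one classifier family.

    Defaults follow the study setup where stated (100 trees for both
    ensembles, k=3 for k-NN, linear SVM kernel, single-hidden-layer MLP) and
    canonical values elsewhere (AdaBoost base-tree depth 3, MLP hidden size
    64, SVM C=1).
    """

    family: str = "random_forest"
    n_trees: int = 100
    k: int = 3
    mlp_hidden: int = 64
    adaboost_depth: int = 3
    svm_c: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.family not in CLASSIFIER_FAMILIES:
            raise ModelError(
                f"unknown family {self.family!r}; expected one of {CLASSIFIER_FAMILIES}"
            )
        if self.n_trees < 1:
            raise ModelError("n_trees must be >= 1")
        if self.k < 1:
            raise ModelError("k must be >= 1")


def _build_estimator(spec: ClassifierSpec, n_features: int):
    if spec.family == "random_forest":
        return RandomForestClassifier(
            n_estimators=spec.n_trees,
            max_features=min(n_features, math.ceil(math.sqrt(n_features))),
            random_state=spec.seed,
            n_jobs=1,
        )
    if spec.family == "adaboost":
        return AdaBoostClassifier(
            estimator=DecisionTreeClassifier(
                max_depth=spec.adaboost_depth, random_state=spec.seed
            ),
            n_estimators=spec.n_trees,
            random_state=spec.seed,
        )
    if spec.family == "decision_tree":
        return DecisionTreeClassifier(random_state=spec.seed)
    if spec.family == "knn":
        return KNeighborsClassifier(n_neighbors=spec.k)
    if spec.family == "lda":
        return LinearDiscriminantAnalysis()
    if spec.family == "qda":
        return QuadraticDiscriminantAnalysis(reg_param=1e-6)
    if spec.family == "svm_linear":
        return SVC(kernel="linear", C=spec.svm_c, random_state=spec.seed)
    if spec.family == "mlp":
        return MLPClassifier(
            hidden_layer_sizes=(spec.mlp_hidden,),
            early_stopping=True,
            max_iter=500,
            random_state=spec.seed,
        )
    raise ModelError(f"unknown family {spec.family!r}")


# ---------------------------------------------------------------------------
# Gini impurity and importance


def gini_node(p) -> float:
    """Gini impurity 1 - sum(p_i^2) of a class-probability vector."""
    p = np.asarray(p, dtype=float)
    if (p < 0).any():
        raise ModelError("class probabilities must be non-negative")
    if abs(p.sum() - 1.0) > 1e-9:
        raise ModelError(f"class probabilities must sum to 1, got {p.sum()}")
    return float(1.0 - (p**2).sum())


@dataclass
class TreeStructure:
    """The node arrays of one fitted decision tree, sufficient for Eq.-style
    importance recomputation and plain traversal prediction."""

    children_left: np.ndarray
    children_right: np.ndarray
    feature: np.ndarray
    threshold: np.ndarray
    class_probs: np.ndarray  # (n_nodes, n_classes), rows sum to 1
    reach: np.ndarray  # weighted_n_node_samples / root weight

    @classmethod
    def from_sklearn(cls, tree) -> "TreeStructure":
        t = tree.tree_
        value = t.value[:, 0, :].astype(float)
        value = value / value.sum(axis=1, keepdims=True)
        reach = t.weighted_n_node_samples / t.weighted_n_node_samples[0]
        return cls(
            children_left=t.children_left.copy(),
            children_right=t.children_right.copy(),
            feature=t.feature.copy(),
            threshold=t.threshold.copy(),
            class_probs=value,
            reach=reach.astype(float),
        )

    @property
    def node_count(self) -> int:
        return len(self.feature)

    def node_contributions(self) -> np.ndarray:
        """Per-feature sum of reach-weighted impurity decreases (unnormalized)."""
        n_features = int(self.feature.max()) + 1 if (self.feature >= 0).any() else 1
        contrib = np.zeros(n_features)
        for k in range(self.node_count):
            left, right = self.children_left[k], self.children_right[k]
            if left == -1:  # leaf
                continue
            dec = (
                self.reach[k] * gini_node(self.class_probs[k])
                - self.reach[left] * gini_node(self.class_probs[left])
                - self.reach[right] * gini_node(self.class_probs[right])
            )
            contrib[self.feature[k]] += dec
        return contrib

    def predict_index(self, X: np.ndarray) -> np.ndarray:
        """Class-index prediction by iterative traversal."""
        node = np.zeros(len(X), dtype=int)
        active = self.children_left[node] != -1
        while active.any():
            idx = np.flatnonzero(active)
            cur = node[idx]
            go_left = X[idx, self.feature[cur]] <= self.threshold[cur]
            node[idx] = np.where(
                go_left, self.children_left[cur], self.children_right[cur]
            )
            active = self.children_left[node] != -1
        return self.class_probs[node].argmax(axis=1)


def importance_from_trees(
    trees: list[TreeStructure],
    n_features: int,
    denominator: str = "per_tree",
) -> np.ndarray:
    """Average importance across trees.

    ``denominator='per_tree'`` divides each tree's summed contributions by its
    own node count before averaging; ``'forest'`` divides the summed
    contributions by the total node count across the forest instead.
    """
    if denominator not in ("per_tree", "forest"):
        raise ModelError("denominator must be 'per_tree' or 'forest'")
    totals = np.zeros(n_features)
    if denominator == "per_tree":
        for ts in trees:
            c = np.zeros(n_features)
            raw = ts.node_contributions()
            c[: len(raw)] = raw
            totals += c / ts.node_count
        return totals / len(trees)
    all_nodes = sum(ts.node_count for ts in trees)
    for ts in trees:
        raw = ts.node_contributions()
        totals[: len(raw)] += raw
    return totals / all_nodes


# ---------------------------------------------------------------------------
# scaler


@dataclass
class Scaler:
    """Training-fold feature statistics: median imputation then z-scoring."""

    means: np.ndarray
    sds: np.ndarray
    medians: np.ndarray

    @classmethod
    def fit(cls, X: np.ndarray) -> "Scaler":
        medians = np.nanmedian(X, axis=0)
        medians = np.where(np.isnan(medians), 0.0, medians)
        X_imp = np.where(np.isnan(X), medians, X)
        means = X_imp.mean(axis=0)
        sds = X_imp.std(axis=0)
        return cls(means=means, sds=np.where(sds > 0, sds, 1.0), medians=medians)

    def transform(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        n_nan = int(np.isnan(X).sum())
        if n_nan:
            logger.debug("scaler: imputing %d missing values with training medians", n_nan)
            X = np.where(np.isnan(X), self.medians, X)
        return (X - self.means) / self.sds


# ---------------------------------------------------------------------------
# model / results


def _as_xy(data, feature_names=None):
    if isinstance(data, LabeledFeatureMatrix):
        return data.X, data.labels, list(FEATURE_COLUMNS)
    raise ModelError("data must be a LabeledFeatureMatrix (or use from_arrays)")


class ActivityClassifier:
    """A physical-activity classifier specification bound to training data.

    Parameters
    ----------
    data : LabeledFeatureMatrix
        Training epochs with labels and metadata.
    spec : ClassifierSpec, optional
        Classifier family and hyperparameters (default: 100-tree random
        forest).
    """

    def __init__(self, data, spec: ClassifierSpec | None = None):
        self.spec = spec or ClassifierSpec()
        self._X, self._y, self.feature_names = _as_xy(data)
        self.classes = np.unique(self._y)
        if len(self.classes) < 2:
            raise ModelError("training data must contain at least 2 classes")

    @classmethod
    def from_arrays(
        cls, X, y, spec: ClassifierSpec | None = None, feature_names=None
    ) -> "ActivityClassifier":
        """Build from bare arrays (used by tests and toy examples)."""
        obj = cls.__new__(cls)
        obj.spec = spec or ClassifierSpec()
        obj._X = np.asarray(X, dtype=float)
        obj._y = np.asarray(y)
        obj.feature_names = list(
            feature_names
            if feature_names is not None
            else [f"f{i}" for i in range(obj._X.shape[1])]
        )
        obj.classes = np.unique(obj._y)
        if len(obj.classes) < 2:
            raise ModelError("training data must contain at least 2 classes")
        return obj

    def fit(self) -> "ActivityClassifierResults":
        scaler = Scaler.fit(self._X)
        Z = scaler.transform(self._X)
        est = _build_estimator(self.spec, Z.shape[1])
        est.fit(Z, self._y)
        return ActivityClassifierResults(self, est, scaler)


class ActivityClassifierResults:
    """Fitted classifier: estimator + training-fold scaler + diagnostics."""

    def __init__(self, model: ActivityClassifier, estimator, scaler: Scaler):
        self.model = model
        self.spec = model.spec
        self.estimator = estimator
        self.scaler = scaler
        self.classes_ = np.asarray(estimator.classes_)

    # -- prediction ---------------------------------------------------------

    def _check_columns(self, data) -> np.ndarray:
        if isinstance(data, LabeledFeatureMatrix):
            if list(FEATURE_COLUMNS) != self.model.feature_names:
                missing = set(self.model.feature_names) - set(FEATURE_COLUMNS)
                extra = set(FEATURE_COLUMNS) - set(self.model.feature_names)
                raise ModelError(f"column mismatch: missing={missing}, extra={extra}")
            return data.X
        X = np.asarray(data, dtype=float)
        if X.ndim != 2 or X.shape[1] != len(self.model.feature_names):
            raise ModelError(
                f"expected {len(self.model.feature_names)} feature columns, "
                f"got {X.shape[1] if X.ndim == 2 else 'non-2D input'}"
            )
        return X

    def predict(self, data) -> np.ndarray:
        """Apply the stored scaler, then the model. RF ties resolve to the
        lowest class index (argmax of averaged votes)."""
        X = self._check_columns(data)
        return self.estimator.predict(self.scaler.transform(X))

    # -- importance ---------------------------------------------------------

    @property
    def is_tree_ensemble(self) -> bool:
        return self.spec.family in TREE_ENSEMBLES

    def tree_structures(self) -> list[TreeStructure]:
        if not self.is_tree_ensemble:
            raise ModelError(
                f"{self.spec.family} does not expose tree structure; "
                "importance requires a tree ensemble"
            )
        return [TreeStructure.from_sklearn(t) for t in self.estimator.estimators_]

    def feature_importances(self, denominator: str = "per_tree") -> pd.DataFrame:
        """Per-feature mean Gini-impurity-decrease importance.

        Returns a DataFrame (feature, importance) sorted descending.
        """
        trees = self.tree_structures()
        scores = importance_from_trees(
            trees, len(self.model.feature_names), denominator=denominator
        )
        table = pd.DataFrame(
            {"feature": self.model.feature_names, "importance": scores}
        )
        return table.sort_values(
            "importance", ascending=False, ignore_index=True
        )

    # -- reporting ----------------------------------------------------------

    def summary(self) -> str:
        counts = pd.Series(self.model._y).value_counts()
        lines = [
            "Activity classifier results",
            "=" * 43,
            f"family:          {self.spec.family}",
            f"features:        {len(self.model.feature_names)}",
            f"training rows:   {len(self.model._y)}",
            "class counts:    "
            + ", ".join(f"{c}={counts[c]}" for c in sorted(counts.index)),
        ]
        if self.is_tree_ensemble:
            lines.append(f"trees:           {self.spec.n_trees}")
            top = self.feature_importances().head(5)
            lines.append("top-5 features by Gini importance:")
            for _, row in top.iterrows():
                lines.append(f"  {row['feature']:<22s} {row['importance']:.3e}")
        return "\n".join(lines)

    # -- persistence --------------------------------------------------------

    def save(self, path) -> None:
        """Serialize spec + scaler + tree structures as JSON (ensembles only),
        so importance is recomputable without retraining."""
        trees = self.tree_structures()
        payload = {
            "spec": self.spec.__dict__,
            "classes": self.classes_.tolist(),
            "feature_names": self.model.feature_names,
            "scaler": {
                "means": self.scaler.means.tolist(),
                "sds": self.scaler.sds.tolist(),
                "medians": self.scaler.medians.tolist(),
            },
            "trees": [
                {
                    "children_left": ts.children_left.tolist(),
                    "children_right": ts.children_right.tolist(),
                    "feature": ts.feature.tolist(),
                    "threshold": ts.threshold.tolist(),
                    "class_probs": ts.class_probs.tolist(),
                    "reach": ts.reach.tolist(),
                }
                for ts in trees
            ],
        }
        Path(path).write_text(json.dumps(payload))


class SavedEnsemble:
    """A tree ensemble re-loaded from the JSON structure written by
    :meth:`ActivityClassifierResults.save`: supports importance recomputation
    and majority-vote prediction without scikit-learn objects."""

    def __init__(self, payload: dict):
        self.spec = ClassifierSpec(**payload["spec"])
        self.classes_ = np.asarray(payload["classes"])
        self.feature_names = list(payload["feature_names"])
        sc = payload["scaler"]
        self.scaler = Scaler(
            means=np.asarray(sc["means"]),
            sds=np.asarray(sc["sds"]),
            medians=np.asarray(sc["medians"]),
        )
        self.trees = [
            TreeStructure(
                children_left=np.asarray(t["children_left"]),
                children_right=np.asarray(t["children_right"]),
                feature=np.asarray(t["feature"]),
                threshold=np.asarray(t["threshold"]),
                class_probs=np.asarray(t["class_probs"]),
                reach=np.asarray(t["reach"]),
            )
            for t in payload["trees"]
        ]

    @classmethod
    def load(cls, path) -> "SavedEnsemble":
        return cls(json.loads(Path(path).read_text()))

    def feature_importances(self, denominator: str = "per_tree") -> pd.DataFrame:
        scores = importance_from_trees(
            self.trees, len(self.feature_names), denominator=denominator
        )
        table = pd.DataFrame({"feature": self.feature_names, "importance": scores})
        return table.sort_values("importance", ascending=False, ignore_index=True)

    def predict(self, data) -> np.ndarray:
        X = data.X if isinstance(data, LabeledFeatureMatrix) else np.asarray(data, float)
        Z = self.scaler.transform(X)
        votes = np.zeros((len(Z), len(self.classes_)), dtype=int)
        for ts in self.trees:
            pred = ts.predict_index(Z)
            votes[np.arange(len(Z)), pred] += 1
        return self.classes_[votes.argmax(axis=1)]


# ---------------------------------------------------------------------------
# functional wrappers (thin aliases over the model/results objects)


def fit_classifier(train_matrix, spec: ClassifierSpec | None = None):
    """Fit a classifier on a training matrix; returns the results object."""
    return ActivityClassifier(train_matrix, spec).fit()


def predict(results: ActivityClassifierResults, matrix) -> np.ndarray:
    return results.predict(matrix)


def feature_importance(
    results: ActivityClassifierResults, denominator: str = "per_tree"
) -> pd.DataFrame:
    return results.feature_importances(denominator=denominator)
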