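"""Classifier fitting, Gini importance arithmetic, persistence, leakage guards."""

import numpy as np
import pytest

from harpipe import ActivityClassifier, ClassifierSpec, SavedEnsemble, gini_node
from harpipe.modeling import (
    ModelError,
    Scaler,
    TreeStructure,
    importance_from_trees,
)


def separable_blobs(n_per=100, n_features=6, n_classes=2, gap=6.0, seed=0):
    rng = np.random.default_rng(seed)
    X, y = [], []
    for c in range(n_classes):
        X.append(rng.normal(c * gap, 1.0, size=(n_per, n_features)))
        y += [f"class_{c}"] * n_per
    return np.vstack(X), np.array(y)


class TestGiniNode:
    @pytest.mark.parametrize("p,expected", [
        ((1, 0, 0, 0), 0.0),
        ((0.25, 0.25, 0.25, 0.25), 0.75),
        ((0.5, 0.5), 0.5),
    ])
    def test_closed_form_values(self, p, expected):
        assert gini_node(p) == pytest.approx(expected, abs=1e-12)

    def test_negative_probability_rejected(self):
        with pytest.raises(ModelError):
            gini_node([1.2, -0.2])

    def test_non_normalized_rejected(self):
        with pytest.raises(ModelError):
            gini_node([0.5, 0.4])


class TestImportanceArithmetic:
    def test_hand_built_stump(self):
        """A stump splitting a (1/2, 1/2) root into two pure equal-reach
        children on feature 0: decrease = 1*0.5 - 0.5*0 - 0.5*0 = 0.5,
        divided by its 3 nodes."""
        stump = TreeStructure(
            children_left=np.array([1, -1, -1]),
            children_right=np.array([2, -1, -1]),
            feature=np.array([0, -2, -2]),
            threshold=np.array([0.0, -2.0, -2.0]),
            class_probs=np.array([[0.5, 0.5], [1.0, 0.0], [0.0, 1.0]]),
            reach=np.array([1.0, 0.5, 0.5]),
        )
        scores = importance_from_trees([stump], n_features=3)
        assert scores[0] == pytest.approx(0.5 / 3, abs=1e-12)
        assert scores[1] == scores[2] == 0.0

    def test_forest_denominator_variant(self):
        stump = TreeStructure(
            children_left=np.array([1, -1, -1]),
            children_right=np.array([2, -1, -1]),
            feature=np.array([0, -2, -2]),
            threshold=np.array([0.0, -2.0, -2.0]),
            class_probs=np.array([[0.5, 0.5], [1.0, 0.0], [0.0, 1.0]]),
            reach=np.array([1.0, 0.5, 0.5]),
        )
        per_tree = importance_from_trees([stump, stump], 1, denominator="per_tree")
        forest = importance_from_trees([stump, stump], 1, denominator="forest")
        assert per_tree[0] == pytest.approx(0.5 / 3)
        assert forest[0] == pytest.approx(1.0 / 6)


class TestFitPredict:
    def test_separable_data_perfect_training_accuracy(self):
        X, y = separable_blobs()
        res = ActivityClassifier.from_arrays(X, y, ClassifierSpec(seed=0)).fit()
        assert (res.predict(X) == y).all()

    def test_same_seed_identical_predictions(self):
        X, y = separable_blobs(gap=1.0)
        r1 = ActivityClassifier.from_arrays(X, y, ClassifierSpec(seed=7)).fit()
        r2 = ActivityClassifier.from_arrays(X, y, ClassifierSpec(seed=7)).fit()
        np.testing.assert_array_equal(r1.predict(X), r2.predict(X))

    def test_shuffled_labels_score_at_chance(self):
        """Held-out balanced accuracy under a permutation null is ~1/k."""
        rng = np.random.default_rng(0)
        X = rng.normal(size=(400, 10))
        y = np.array(["a", "b"] * 200)
        res = ActivityClassifier.from_arrays(
            X[:300], y[:300], ClassifierSpec(n_trees=50, seed=0)
        ).fit()
        pred = res.predict(X[300:])
        acc = (pred == y[300:]).mean()
        assert 0.3 < acc < 0.7

    def test_deep_tree_memorizes_training_set(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(100, 5))
        y = np.array(["a", "b"] * 50)
        res = ActivityClassifier.from_arrays(
            X, y, ClassifierSpec(family="decision_tree", seed=0)
        ).fit()
        assert (res.predict(X) == y).all()

    def test_identical_rows_identical_predictions(self):
        X, y = separable_blobs()
        res = ActivityClassifier.from_arrays(X, y, ClassifierSpec(seed=0)).fit()
        test = np.tile(X[0], (7, 1))
        assert len(set(res.predict(test))) == 1

    @pytest.mark.parametrize("family", [
        "adaboost", "decision_tree", "knn", "lda", "qda", "svm_linear", "mlp",
    ])
    def test_all_comparator_families_fit_separable_data(self, family):
        X, y = separable_blobs(n_per=60)
        res = ActivityClassifier.from_arrays(
            X, y, ClassifierSpec(family=family, n_trees=20, seed=0)
        ).fit()
        assert (res.predict(X) == y).mean() > 0.95

    def test_single_class_rejected(self):
        X = np.zeros((10, 3))
        with pytest.raises(ModelError):
            ActivityClassifier.from_arrays(X, np.array(["a"] * 10))

    def test_column_mismatch_rejected(self):
        X, y = separable_blobs()
        res = ActivityClassifier.from_arrays(X, y).fit()
        with pytest.raises(ModelError, match="feature columns"):
            res.predict(X[:, :4])


@pytest.fixture(scope="module")
def fitted_rf():
    X, y = separable_blobs(n_per=80, n_features=8, n_classes=3, gap=2.0)
    return (
        ActivityClassifier.from_arrays(X, y, ClassifierSpec(n_trees=25, seed=3)).fit(),
        X,
        y,
    )


class TestEnsembleStructure:
    def test_vote_equals_per_tree_tally(self, fitted_rf):
        """The ensemble prediction matches a brute-force majority tally over
        the exported tree structures (pure leaves make soft and hard votes
        coincide off ties)."""
        res, X, y = fitted_rf
        Z = res.scaler.transform(X)
        votes = np.zeros((len(X), len(res.classes_)), dtype=int)
        for ts in res.tree_structures():
            pred = ts.predict_index(Z)
            votes[np.arange(len(X)), pred] += 1
        tally = res.classes_[votes.argmax(axis=1)]
        sk = res.predict(X)
        assert (tally == sk).mean() > 0.99

    def test_all_node_contributions_non_negative(self, fitted_rf):
        res, _, _ = fitted_rf
        for ts in res.tree_structures():
            assert (ts.node_contributions() >= -1e-12).all()

    def test_unused_feature_has_zero_importance(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(200, 30))
        X[:, 0] = (np.arange(200) < 100) * 10.0  # only feature 0 informative
        X[:, 20:] = 1.0  # constant columns admit no split: never used
        y = np.array(["a"] * 100 + ["b"] * 100)
        res = ActivityClassifier.from_arrays(
            X, y, ClassifierSpec(n_trees=20, seed=0)
        ).fit()
        table = res.feature_importances().set_index("feature")["importance"]
        assert table.idxmax() == "f0"
        used = set()
        for ts in res.tree_structures():
            used |= set(ts.feature[ts.feature >= 0].tolist())
        unused = [f"f{i}" for i in range(30) if i not in used]
        assert unused, "expected some never-split features in this forest"
        assert table[unused].abs().max() == pytest.approx(0.0, abs=1e-15)

    def test_importance_rank_agrees_with_sklearn(self, fitted_rf):
        """Independent cross-check: despite the different per-tree
        normalization, the ranking correlates strongly with scikit-learn's
        impurity importance."""
        from scipy.stats import spearmanr

        res, _, _ = fitted_rf
        mine = res.feature_importances().set_index("feature")["importance"]
        sk = res.estimator.feature_importances_
        mine = mine[[f"f{i}" for i in range(len(sk))]].to_numpy()
        rho = spearmanr(mine, sk).statistic
        assert rho > 0.9

    def test_non_ensemble_importance_rejected(self):
        X, y = separable_blobs(n_per=30)
        res = ActivityClassifier.from_arrays(
            X, y, ClassifierSpec(family="knn")
        ).fit()
        with pytest.raises(ModelError, match="tree ensemble"):
            res.feature_importances()

    def test_json_round_trip_preserves_importance_and_predictions(
        self, fitted_rf, tmp_path
    ):
        res, X, y = fitted_rf
        path = tmp_path / "model.json"
        res.save(path)
        loaded = SavedEnsemble.load(path)
        a = res.feature_importances()
        b = loaded.feature_importances()
        np.testing.assert_allclose(
            a["importance"].to_numpy(), b["importance"].to_numpy(), rtol=1e-12
        )
        assert (loaded.predict(X) == res.predict(X)).mean() > 0.99


class TestScalerLeakage:
    def test_stored_means_are_training_only(self):
        X, y = separable_blobs(n_per=50)
        res = ActivityClassifier.from_arrays(X, y).fit()
        np.testing.assert_allclose(res.scaler.means, X.mean(axis=0), rtol=1e-9)
        extra = np.vstack([X, np.full((30, X.shape[1]), 100.0)])
        assert not np.allclose(res.scaler.means, extra.mean(axis=0))

    def test_median_imputation_of_flagged_values(self):
        X, y = separable_blobs(n_per=40)
        X[3, 2] = np.nan
        res = ActivityClassifier.from_arrays(X, y).fit()
        test = X[:5].copy()
        test[:, 2] = np.nan
        assert len(res.predict(test)) == 5  # imputed, no NaN crash

    def test_summary_mentions_family_and_counts(self):
        X, y = separable_blobs(n_per=30)
        res = ActivityClassifier.from_arrays(X, y, ClassifierSpec(n_trees=10)).fit()
        text = res.summary()
        assert "random_forest" in text and "class_0=30" in text
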