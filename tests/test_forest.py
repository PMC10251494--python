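import json

import numpy as np
import pytest

from prforest import (
    Hyperparameters,
    PRForestModel,
    compute_class_weights,
    feature_importances,
    fit_forest,
    predict_labels,
    predict_proba_forest,
)

from conftest import make_dataset


class TestHyperparameters:
    def test_validation(self):
        with pytest.raises(ValueError):
            Hyperparameters(n_trees=0)
        with pytest.raises(ValueError):
            Hyperparameters(keep_probability=1.5)
        with pytest.raises(ValueError):
            Hyperparameters(min_samples_split=2, min_samples_leaf=3)
        with pytest.raises(ValueError):
            Hyperparameters(max_depth=0)

    def test_with_seed(self):
        hp = Hyperparameters(seed=1)
        assert hp.with_seed(9).seed == 9 and hp.seed == 1


class TestComputeClassWeights:
    def test_study_composition(self):
        # 81 one-hot positive + 29 one-hot stable + 32 at 50/50:
        # effective counts (stable, positive) = (45, 97)
        PMF = np.vstack(
            [np.tile([0.0, 1.0], (81, 1)),
             np.tile([1.0, 0.0], (29, 1)),
             np.tile([0.5, 0.5], (32, 1))]
        )
        w = compute_class_weights(PMF)
        assert w == pytest.approx([142 / (2 * 45), 142 / (2 * 97)])
        assert w == pytest.approx([1.5778, 0.7320], abs=1e-4)

    def test_balanced_gives_ones(self):
        PMF = np.array([[1.0, 0.0], [0.0, 1.0], [1.0, 0.0], [0.0, 1.0]])
        assert compute_class_weights(PMF) == pytest.approx([1.0, 1.0])

    def test_symmetric_soft_gives_ones(self):
        PMF = np.tile([0.5, 0.5], (4, 1))
        assert compute_class_weights(PMF) == pytest.approx([1.0, 1.0])

    def test_empty_class_is_error(self):
        PMF = np.array([[1.0, 0.0], [1.0, 0.0]])
        with pytest.raises(ValueError, match="zero effective count"):
            compute_class_weights(PMF)


class TestFitForest:
    def test_deterministic_given_seed(self, naive_dataset):
        hp = Hyperparameters(n_trees=10, seed=42)
        m1 = fit_forest(naive_dataset, hp)
        m2 = fit_forest(naive_dataset, hp)
        X = naive_dataset.X[:20]
        assert np.array_equal(
            predict_proba_forest(m1, X), predict_proba_forest(m2, X)
        )
        for t1, t2 in zip(m1.trees, m2.trees):
            assert np.array_equal(t1.feature, t2.feature)
            assert np.array_equal(t1.threshold, t2.threshold, equal_nan=True)
            assert np.array_equal(t1.dist, t2.dist)

    def test_different_seeds_differ(self, naive_dataset):
        m1 = fit_forest(naive_dataset, Hyperparameters(n_trees=5, seed=1))
        m2 = fit_forest(naive_dataset, Hyperparameters(n_trees=5, seed=2))
        assert m1.bootstrap_sample_ids != m2.bootstrap_sample_ids

    def test_n_trees_respected(self, naive_dataset, small_hp):
        model = fit_forest(naive_dataset, small_hp)
        assert len(model.trees) == small_hp.n_trees
        assert len(model.bootstrap_sample_ids) == small_hp.n_trees
        assert all(len(ids) == len(naive_dataset) for ids in model.bootstrap_sample_ids)

    def test_leaf_distributions_match_deterministic_routing(self):
        # dx=0, one-hot labels: leaves reproduce class-weighted label
        # frequencies of the samples deterministically routed to them
        rng = np.random.default_rng(3)
        X = rng.normal(size=(40, 2))
        y = rng.integers(0, 2, 40)
        ds = make_dataset(X, y)
        hp = Hyperparameters(
            n_trees=3, max_features="all", min_samples_split=2,
            min_samples_leaf=1, seed=0,
        )
        model = fit_forest(ds, hp)
        w = model.class_weights
        for tree in model.trees:
            boot = tree.bootstrap_indices
            counts = np.bincount(boot, minlength=len(ds))
            for i in np.flatnonzero(counts):
                node = 0
                while tree.feature[node] != -1:
                    if X[i, tree.feature[node]] > tree.threshold[node]:
                        node = tree.right[node]
                    else:
                        node = tree.left[node]
                # routed leaf must put positive mass on this sample's class
                assert tree.dist[node, y[i]] > 0
            # leaf masses total the bootstrap size
            leaves = tree.feature == -1
            assert tree.mass[leaves].sum() == pytest.approx(counts.sum())

    def test_engine_dispatch(self, naive_dataset, probabilistic_dataset):
        hp = Hyperparameters(n_trees=1, seed=0)
        assert fit_forest(naive_dataset, hp).engine == "fast"
        assert fit_forest(probabilistic_dataset, hp).engine == "fast"
        ds = naive_dataset.subset(np.r_[0:15, 85:100])  # both classes present
        ds.DX = ds.DX + 0.1
        assert fit_forest(ds, hp).engine == "reference"


class TestPredictProbaForest:
    def test_rows_sum_to_one(self, naive_dataset, small_hp):
        model = fit_forest(naive_dataset, small_hp)
        proba = predict_proba_forest(model, naive_dataset.X)
        assert proba.shape == (len(naive_dataset), 2)
        assert np.allclose(proba.sum(axis=1), 1.0, atol=1e-9)

    def test_averaging_contract(self, naive_dataset, small_hp):
        model = fit_forest(naive_dataset, small_hp)
        from prforest.tree import predict_proba_tree

        x = naive_dataset.X[11]
        per_tree = [predict_proba_tree(t, x) for t in model.trees]
        assert predict_proba_forest(model, x[None, :])[0] == pytest.approx(
            np.mean(per_tree, axis=0), abs=1e-12
        )

    def test_wrong_width_rejected(self, naive_dataset, small_hp):
        model = fit_forest(naive_dataset, small_hp)
        with pytest.raises(ValueError, match="columns"):
            predict_proba_forest(model, np.zeros((2, 3)))

    def test_untrained_model_rejected(self, naive_dataset, small_hp):
        model = fit_forest(naive_dataset, small_hp)
        model.trees = []
        with pytest.raises(RuntimeError, match="no trees"):
            predict_proba_forest(model, naive_dataset.X[:1])

    def test_uncertain_test_points_still_normalized(self, naive_dataset, small_hp):
        model = fit_forest(naive_dataset, small_hp)
        X = naive_dataset.X[:5]
        DX = np.full_like(X, 50.0)
        proba = predict_proba_forest(model, X, DX)
        assert np.allclose(proba.sum(axis=1), 1.0, atol=1e-9)

    def test_argmax_tie_goes_to_lower_class(self):
        ds = make_dataset([[0.0], [1.0]], [0, 1])
        hp = Hyperparameters(n_trees=2, max_depth=1, min_samples_split=2,
                             min_samples_leaf=1, seed=0)
        model = fit_forest(ds, hp)
        # exactly at the threshold both classes can tie; fabricate a tie
        model.trees = model.trees[:1]
        model.trees[0].dist[:] = 0.5
        assert predict_labels(model, np.array([[0.5]]))[0] == 0


class TestFeatureImportances:
    def test_single_depth_one_tree(self):
        # feature 1 is constant, so the single split must use feature 0
        X = [[float(i), 5.0] for i in range(10)]
        ds = make_dataset(X, [0] * 5 + [1] * 5)
        hp = Hyperparameters(n_trees=1, max_features="all", max_depth=1,
                             min_samples_split=2, min_samples_leaf=1, seed=0)
        model = fit_forest(ds, hp)
        assert model.trees[0].n_nodes == 3
        assert feature_importances(model) == pytest.approx([1.0, 0.0])

    def test_normalized_and_non_negative(self, naive_dataset, small_hp):
        imp = feature_importances(fit_forest(naive_dataset, small_hp))
        assert np.all(imp >= 0)
        assert imp.sum() == pytest.approx(1.0, abs=1e-9)

    @pytest.mark.parametrize("seed", range(10))
    def test_separating_feature_dominates_noise(self, seed):
        rng = np.random.default_rng(seed)
        n = 60
        y = rng.integers(0, 2, n)
        X = np.column_stack([rng.normal(size=n), y + rng.normal(scale=0.05, size=n)])
        ds = make_dataset(X, y)
        model = fit_forest(ds, Hyperparameters(n_trees=20, max_features="all", seed=seed))
        imp = feature_importances(model)
        assert imp[1] > imp[0]


class TestSerialization:
    def test_json_round_trip(self, naive_dataset, small_hp, tmp_path):
        model = fit_forest(naive_dataset, small_hp)
        path = tmp_path / "model.json"
        model.save(path)
        again = PRForestModel.load(path)
        X = naive_dataset.X[:25]
        assert np.array_equal(
            predict_proba_forest(model, X), predict_proba_forest(again, X)
        )
        assert again.hyperparameters == model.hyperparameters
        assert again.class_names == model.class_names
        assert again.bootstrap_sample_ids == model.bootstrap_sample_ids

    def test_schema_is_plain_json(self, naive_dataset, small_hp, tmp_path):
        model = fit_forest(naive_dataset, small_hp)
        path = tmp_path / "model.json"
        model.save(path)
        d = json.loads(path.read_text())
        assert d["schema_version"] == 1
        assert len(d["trees"]) == small_hp.n_trees

    def test_unknown_schema_rejected(self):
        with pytest.raises(ValueError, match="schema"):
            PRForestModel.from_dict({"schema_version": 99})
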