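import numpy as np
import pytest

from prforest import (
    Hyperparameters,
    LabelPolicy,
    fit_forest,
)
from prforest.evaluation import (
    HyperparameterGrid,
    build_fold_plan,
    evaluate_fold,
    run_comparison,
    select_hyperparameters,
    stratified_kfold,
)

from conftest import make_dataset

SMALL_GRID = HyperparameterGrid(n_trees=(20,), max_features=("sqrt",))


class TestStratifiedKFold:
    def test_study_sizes(self, default_cohort):
        fold = stratified_kfold(default_cohort.dataset.nominal, 7, seed=0)
        sizes = np.bincount(fold, minlength=7)
        assert sorted(sizes) in ([20, 20, 20, 20, 20, 21, 21],)
        assert all(len(default_cohort.dataset.nominal) - s in (121, 122) for s in sizes)

    def test_balanced_binary_14(self):
        labels = np.array([0, 1] * 7)
        fold = stratified_kfold(labels, 7, seed=3)
        for f in range(7):
            sel = labels[fold == f]
            assert len(sel) == 2 and set(sel) == {0, 1}

    def test_partition_contract(self, rng):
        labels = rng.integers(0, 2, 100)
        fold = stratified_kfold(labels, 5, seed=1)
        assert fold.min() >= 0 and fold.max() < 5
        assert np.all(fold >= 0)
        assert sum((fold == f).sum() for f in range(5)) == 100

    def test_per_class_counts_within_one_of_proportional(self, rng):
        labels = rng.integers(0, 3, 200)
        k = 6
        fold = stratified_kfold(labels, k, seed=2)
        for c in np.unique(labels):
            counts = np.bincount(fold[labels == c], minlength=k)
            assert counts.max() - counts.min() <= 1

    def test_small_class_rejected(self):
        labels = np.array([0] * 20 + [1] * 3)
        with pytest.raises(ValueError, match="fewer than k"):
            stratified_kfold(labels, 7, seed=0)

    def test_deterministic(self):
        labels = np.tile([0, 1, 1], 20)
        a = stratified_kfold(labels, 4, seed=9)
        b = stratified_kfold(labels, 4, seed=9)
        c = stratified_kfold(labels, 4, seed=10)
        assert np.array_equal(a, b)
        assert not np.array_equal(a, c)


class TestFoldPlan:
    def test_nested_partition(self, default_cohort):
        labels = default_cohort.dataset.nominal
        plan = build_fold_plan(labels, 7, seed=5)
        all_test = np.sort(np.concatenate([t for _, t in plan.outer]))
        assert np.array_equal(all_test, np.arange(len(labels)))
        for i, (train_idx, test_idx) in enumerate(plan.outer):
            assert not set(train_idx) & set(test_idx)
            inner_val = np.sort(np.concatenate([v for _, v in plan.inner[i]]))
            assert np.array_equal(inner_val, np.sort(train_idx))
            for tr, va in plan.inner[i]:
                assert not set(tr) & set(va)
                assert not set(va) & set(test_idx)

    def test_reconstructible_from_seed(self, default_cohort):
        labels = default_cohort.dataset.nominal
        p1 = build_fold_plan(labels, 7, seed=8)
        p2 = build_fold_plan(labels, 7, seed=8)
        for (a, b), (c, d) in zip(p1.outer, p2.outer):
            assert np.array_equal(a, c) and np.array_equal(b, d)


class TestEvaluateFold:
    def test_perfect_predictions(self):
        ds = make_dataset(
            [[0.0], [0.1], [5.0], [5.1]], [0, 0, 1, 1],
            class_names=("stable", "new_disease_activity"),
        )
        model = fit_forest(ds, Hyperparameters(
            n_trees=1, max_features="all", min_samples_split=2,
            min_samples_leaf=1, seed=0))
        ev = evaluate_fold(model, ds, np.arange(4), positive_index=1)
        assert (ev.tp, ev.fp, ev.fn, ev.tn) == (2, 0, 0, 2)

    def test_posthoc_samples_excluded_from_counts(self, default_cohort, naive_dataset):
        model = fit_forest(naive_dataset, Hyperparameters(n_trees=5, seed=0))
        ds = default_cohort.dataset
        all_idx = np.arange(len(ds))
        ev = evaluate_fold(model, ds, all_idx, positive_index=1)
        assert ev.n_confirmed == 110
        assert ev.tp + ev.fp + ev.fn + ev.tn == 110

    def test_counts_match_brute_force(self, default_cohort, naive_dataset):
        from prforest import predict_proba_forest

        model = fit_forest(naive_dataset, Hyperparameters(n_trees=5, seed=1))
        ds = default_cohort.dataset
        idx = np.arange(40)
        ev = evaluate_fold(model, ds, idx, positive_index=1)
        tp = fp = fn = tn = 0
        for i in idx:
            if not ds.confirmed[i]:
                continue
            score = predict_proba_forest(model, ds.X[i][None, :])[0, 1]
            pred = score > 0.5
            truth = ds.nominal[i] == 1
            tp += pred and truth
            fp += pred and not truth
            fn += (not pred) and truth
            tn += (not pred) and not truth
        assert (ev.tp, ev.fp, ev.fn, ev.tn) == (tp, fp, fn, tn)

    def test_no_confirmed_returns_none(self, naive_dataset, default_cohort):
        ds = default_cohort.dataset
        model = fit_forest(naive_dataset, Hyperparameters(n_trees=2, seed=0))
        posthoc_idx = np.flatnonzero(~ds.confirmed)
        assert evaluate_fold(model, ds, posthoc_idx, positive_index=1) is None


class TestSelectHyperparameters:
    def test_single_candidate_returned(self, default_cohort):
        ds = default_cohort.dataset
        plan = build_fold_plan(ds.nominal, 7, seed=0)
        chosen = select_hyperparameters(
            ds, plan.inner[0], SMALL_GRID, LabelPolicy("naive"),
            Hyperparameters(), (0, 2, 0),
        )
        assert chosen.n_trees == 20
        assert chosen.max_features == "sqrt"

    def test_degenerate_candidate_loses(self, default_cohort):
        # a 1-tree depth-1 forest vs a real forest: the real one wins
        ds = default_cohort.dataset
        plan = build_fold_plan(ds.nominal, 7, seed=1)
        # grid over n_trees only; the 1-tree candidate scores worse on average
        grid = HyperparameterGrid(n_trees=(1, 50), max_features=("sqrt",))
        chosen = select_hyperparameters(
            ds, plan.inner[0], grid, LabelPolicy("naive"),
            Hyperparameters(), (1, 2, 0),
        )
        assert chosen.n_trees == 50

    def test_invariant_to_grid_order_without_ties(self, default_cohort):
        ds = default_cohort.dataset
        plan = build_fold_plan(ds.nominal, 7, seed=2)
        g1 = HyperparameterGrid(n_trees=(1, 50), max_features=("sqrt",))
        g2 = HyperparameterGrid(n_trees=(50, 1), max_features=("sqrt",))
        c1 = select_hyperparameters(ds, plan.inner[0], g1, LabelPolicy("naive"),
                                    Hyperparameters(), (2, 2, 0))
        c2 = select_hyperparameters(ds, plan.inner[0], g2, LabelPolicy("naive"),
                                    Hyperparameters(), (2, 2, 0))
        assert c1 == c2


class TestRunComparison:
    def test_report_shape_and_recomputability(self, default_cohort):
        reports = run_comparison(
            default_cohort.dataset,
            [LabelPolicy("exclude"), LabelPolicy("naive"), LabelPolicy("probabilistic")],
            SMALL_GRID, k=7, seed=0,
        )
        assert [r.policy for r in reports] == ["exclude", "naive", "probabilistic"]
        for rep in reports:
            assert len(rep.folds) == 7
            for f in rep.folds:
                assert not f.get("skipped")
                # metrics recomputable from stored confusion counts
                from prforest.metrics import precision_recall_f1

                prf = precision_recall_f1(f["tp"], f["fp"], f["fn"])
                assert f["recall"] == pytest.approx(prf.recall, nan_ok=True)
                assert f["precision"] == pytest.approx(prf.precision, nan_ok=True)
                assert f["f1"] == pytest.approx(prf.f1, nan_ok=True)
            vals = [f["auc"] for f in rep.folds]
            assert rep.metric_mean("auc") == pytest.approx(np.mean(vals))
            assert rep.metric_sd("auc") == pytest.approx(np.std(vals, ddof=1))

    def test_paired_design_same_test_folds(self, default_cohort):
        reports = run_comparison(
            default_cohort.dataset,
            [LabelPolicy("naive"), LabelPolicy("probabilistic")],
            SMALL_GRID, k=7, seed=3,
        )
        a, b = reports
        for fa, fb in zip(a.folds, b.folds):
            assert fa["n_test_confirmed"] == fb["n_test_confirmed"]

    def test_exclude_trains_on_confirmed_only(self, default_cohort, monkeypatch):
        seen = []
        import prforest.evaluation as ev
        orig = ev.fit_forest

        def spy(dataset, hp, **kw):
            seen.append(bool(dataset.confirmed.all()))
            return orig(dataset, hp, **kw)

        monkeypatch.setattr(ev, "fit_forest", spy)
        run_comparison(default_cohort.dataset, [LabelPolicy("exclude")],
                       SMALL_GRID, k=7, seed=0)
        assert seen and all(seen)

    def test_manifest_embedded(self, default_cohort):
        (rep,) = run_comparison(default_cohort.dataset, [LabelPolicy("naive")],
                                SMALL_GRID, k=7, seed=4)
        assert rep.manifest["grid"] == SMALL_GRID.to_dict()
        assert rep.seed == 4
        assert "version" in rep.manifest
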