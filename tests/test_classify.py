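import numpy as np
import pandas as pd
import pytest

import methylclass as mc
from methylclass.classify import UNKNOWN, _stratified_folds


@pytest.fixture(scope="module")
def tiny_split():
    """Small split for fast classifier mechanics tests."""
    cfg = mc.SimConfig(n_classes=3, samples_per_class=15, n_probes=1500,
                       n_informative=60, n_outlier_classes=3,
                       n_unseen_outlier_classes=1, outlier_pool_size=40,
                       outlier_test_size=8, test_per_class=5, seed=5)
    return mc.simulate_split(cfg)


def _training_set(split, fraction=0.1, seed=0):
    bm = split.bm
    sheet = split.sheet
    ref_ids = sheet.table.index[sheet.table["cohort"] == "reference"]
    pool_ids = sheet.table.index[sheet.table["cohort"] == "unknown_pool"]
    return mc.assemble_training_set(
        bm.subset_samples(ref_ids),
        sheet.table.loc[ref_ids, "label"].to_numpy(dtype=object),
        bm.subset_samples(pool_ids), sheet,
        per_category_fraction=fraction, seed=seed)


class TestAssembleTrainingSet:
    def test_per_category_draw_sizes(self, tiny_split):
        ts = _training_set(tiny_split, fraction=0.1, seed=0)
        # 3 classes x 15 reference + 2 seen categories x round(0.1*40)
        assert ts.bm.n_samples == 45 + 2 * 4
        assert (ts.labels == UNKNOWN).sum() == 8
        assert set(ts.provenance[ts.labels == UNKNOWN]) == {"unknown_pool"}

    def test_minimum_one_per_category(self, tiny_split):
        ts = _training_set(tiny_split, fraction=0.001, seed=0)
        assert (ts.labels == UNKNOWN).sum() == 2  # one per non-empty category

    def test_empty_pool_warns(self, tiny_split):
        split = tiny_split
        ref_ids = split.sheet.table.index[split.sheet.table["cohort"] == "reference"]
        with pytest.warns(UserWarning, match="no Unknown pool"):
            ts = mc.assemble_training_set(
                split.bm.subset_samples(ref_ids),
                split.sheet.table.loc[ref_ids, "label"].to_numpy(dtype=object),
                None, None)
        assert UNKNOWN not in set(ts.labels)

    def test_same_seed_same_selection(self, tiny_split):
        a = _training_set(tiny_split, seed=11)
        b = _training_set(tiny_split, seed=11)
        assert list(a.bm.sample_ids) == list(b.bm.sample_ids)

    def test_incompatible_probe_sets_error(self, tiny_split):
        split = tiny_split
        ref_ids = split.sheet.table.index[split.sheet.table["cohort"] == "reference"]
        pool_ids = split.sheet.table.index[split.sheet.table["cohort"] == "unknown_pool"]
        ref = split.bm.subset_samples(ref_ids)
        pool = split.bm.subset_samples(pool_ids)
        pool = pool.subset_probes(pool.probe_ids[:-1])
        with pytest.raises(ValueError, match="incompatible"):
            mc.assemble_training_set(ref,
                                     split.sheet.table.loc[ref_ids, "label"].to_numpy(dtype=object),
                                     pool, split.sheet)


class TestBalancedLogLoss:
    def test_perfect_predictions_zero(self):
        scores = np.eye(3)
        assert mc.balanced_log_loss(scores, ["a", "b", "c"], ["a", "b", "c"]) == 0

    def test_uniform_predictions_log_k(self):
        scores = np.full((5, 4), 0.25)
        labels = ["a", "a", "a", "b", "c"]  # unbalanced sizes
        loss = mc.balanced_log_loss(scores, labels, ["a", "b", "c", "d"])
        assert loss == pytest.approx(np.log(4))

    def test_hand_computed_weighted_sum(self):
        """2 classes, sizes (2,1), true-class probs (0.8, 0.6, 0.9):
        weights (0.75, 0.75, 1.5), loss = 0.2362 (hand-computed)."""
        scores = np.array([[0.8, 0.2], [0.6, 0.4], [0.1, 0.9]])
        labels = ["a", "a", "b"]
        loss = mc.balanced_log_loss(scores, labels, ["a", "b"])
        expected = (0.75 * -np.log(0.8) + 0.75 * -np.log(0.6)
                    + 1.5 * -np.log(0.9)) / 3.0
        assert loss == pytest.approx(expected)
        assert loss == pytest.approx(0.236, abs=5e-4)

    def test_equal_sizes_reduce_to_plain_mean(self):
        rng = np.random.default_rng(0)
        scores = rng.dirichlet(np.ones(3), size=12)
        labels = np.repeat(["a", "b", "c"], 4)
        bal = mc.balanced_log_loss(scores, labels, ["a", "b", "c"])
        idx = {"a": 0, "b": 1, "c": 2}
        plain = np.mean([-np.log(scores[i, idx[l]]) for i, l in enumerate(labels)])
        assert bal == pytest.approx(plain)

    def test_label_outside_columns_errors(self):
        with pytest.raises(ValueError, match="outside"):
            mc.balanced_log_loss(np.eye(2), ["a", "z"], ["a", "b"])


class TestGrids:
    def test_svm_grid_values_and_order(self):
        g = mc.svm_grid()
        # kernel -> cost -> gamma enumeration; linear block first
        assert g.combos[0] == {"kernel": "linear", "cost": 1.0}
        assert g.combos[5] == {"kernel": "linear", "cost": 32.0}
        assert g.combos[6]["kernel"] == "rbf"
        assert g.combos[6]["gamma"] == pytest.approx(2.0 ** -3 / 20000)
        assert len(g.combos) == 6 + 6 * 7
        costs = {c["cost"] for c in g.combos}
        assert costs == {2.0 ** e for e in range(6)}

    def test_rf_grid_values(self):
        g = mc.rf_grid()
        assert len(g.combos) == 2 * 11
        mtrys = sorted({c["mtry"] for c in g.combos})
        assert mtrys[0] == max(1, round(2 ** -5 * np.sqrt(20000)))
        assert mtrys[-1] == round(2 ** 5 * np.sqrt(20000))


class TestStratifiedFolds:
    def test_cover_each_sample_once_and_balanced(self):
        rng = np.random.default_rng(0)
        labels = np.asarray(list("aaaaaaaaaabbbbbccccc"), dtype=object)
        ids = [f"s{i}" for i in range(len(labels))]
        folds = _stratified_folds(labels, ids, 5, seed=0)
        assert len(folds) == len(labels)
        for lab in "abc":
            per_fold = np.bincount(folds[labels == lab], minlength=5)
            assert per_fold.max() - per_fold.min() <= 1

    def test_invariant_to_sample_order(self):
        labels = np.asarray(list("aaaabbbbcccc"), dtype=object)
        ids = np.asarray([f"s{i}" for i in range(12)], dtype=object)
        f1 = dict(zip(ids, _stratified_folds(labels, ids, 4, seed=3)))
        perm = np.random.default_rng(1).permutation(12)
        f2 = dict(zip(ids[perm], _stratified_folds(labels[perm], ids[perm], 4, seed=3)))
        assert f1 == f2


@pytest.fixture(scope="module")
def fitted_small(tiny_split):
    ts = _training_set(tiny_split, fraction=0.1, seed=0)
    grid = mc.svm_grid(kernels=("linear",), cost_exponents=(0, 5),
                       k_features=500)
    clf = mc.cv_grid_search(ts, grid, k_features=500, folds=5, seed=0)
    return tiny_split, ts, clf


class TestCVGridSearch:
    def test_single_point_grid_wins(self, tiny_split):
        ts = _training_set(tiny_split, fraction=0.1, seed=0)
        grid = mc.HyperParamGrid("svm", [{"kernel": "linear", "cost": 1.0}])
        clf = mc.cv_grid_search(ts, grid, k_features=200, folds=3, seed=0)
        assert clf.best_params_ == {"kernel": "linear", "cost": 1.0}

    def test_fold_contract(self, fitted_small):
        _, ts, clf = fitted_small
        folds = clf.fold_assignment_
        assert len(folds) == ts.bm.n_samples
        assert set(folds) == set(range(clf.n_folds_))
        # stratification: per-class fold counts within +-1
        lab = pd.Series(ts.labels, index=ts.bm.sample_ids)
        for c in set(ts.labels):
            per = folds[lab == c].value_counts().reindex(
                range(clf.n_folds_), fill_value=0)
            assert per.max() - per.min() <= 1

    def test_winner_beats_most_regularized_corner(self, fitted_small):
        """On separable data the selected combination outperforms the
        weakest corner of the grid (sanity of the selection signal)."""
        _, _, clf = fitted_small
        losses = clf.cv_results_["mean_balanced_loss"]
        assert clf.best_loss_ == losses.min()
        assert clf.best_loss_ <= losses.max()

    def test_oof_scores_are_probabilities(self, fitted_small):
        _, ts, clf = fitted_small
        s = clf.oof_scores_.to_numpy()
        assert s.shape == (ts.bm.n_samples, len(clf.classes_))
        assert np.allclose(s.sum(axis=1), 1, atol=1e-6)

    def test_per_fold_selection_excludes_heldout_samples(self, tiny_split):
        """Poisoning check: a probe whose variance is driven by a single
        held-out sample cannot enter that fold's feature set."""
        ts = _training_set(tiny_split, fraction=0.1, seed=0)
        rng = np.random.default_rng(0)
        n = ts.bm.n_samples
        # low-variance background so the poison probe dominates wherever
        # the poisoned sample is part of the training fold
        X = np.clip(rng.normal(0.5, 0.01, size=(n, 400)), 0, 1)
        poison_col = 7
        X[:, poison_col] = 0.5  # exactly constant without the poison
        target_id = ts.bm.sample_ids[0]
        target = 0
        X[target, poison_col] = 1.0
        clf = mc.MethylClassifier(
            family="svm",
            grid=mc.HyperParamGrid("svm", [{"kernel": "linear", "cost": 1.0}]),
            k_features=10, folds=5, random_state=0, calibrate=False)
        clf.fit(X, ts.labels, sample_ids=ts.bm.sample_ids)
        target_fold = clf.fold_assignment_.loc[target_id]
        # without the poisoned sample the probe has zero variance: it can
        # never be selected for the fold that holds that sample out
        assert poison_col not in clf.fold_feature_idx_[target_fold]
        # and in every fold where the sample IS in training, it dominates
        for f, idx in enumerate(clf.fold_feature_idx_):
            if f != target_fold:
                assert idx[0] == poison_col

    def test_grid_search_invariant_to_sample_order(self, tiny_split):
        ts = _training_set(tiny_split, fraction=0.1, seed=0)
        grid = mc.HyperParamGrid("svm", [{"kernel": "linear", "cost": 1.0},
                                         {"kernel": "linear", "cost": 32.0}])
        clf1 = mc.MethylClassifier("svm", grid, k_features=200, folds=4,
                                   random_state=0, calibrate=False)
        clf1.fit(ts.bm.X, ts.labels, sample_ids=ts.bm.sample_ids)
        perm = np.random.default_rng(2).permutation(ts.bm.n_samples)
        clf2 = mc.MethylClassifier("svm", grid, k_features=200, folds=4,
                                   random_state=0, calibrate=False)
        clf2.fit(ts.bm.X[perm], ts.labels[perm],
                 sample_ids=ts.bm.sample_ids[perm])
        assert clf1.best_params_ == clf2.best_params_
        assert np.allclose(
            clf1.cv_results_["mean_balanced_loss"],
            clf2.cv_results_["mean_balanced_loss"], atol=1e-9)

    def test_rf_family_scores_sum_to_one(self, tiny_split):
        ts = _training_set(tiny_split, fraction=0.1, seed=0)
        grid = mc.rf_grid(ntrees=(100,), mtry_exponents=(0,), k_features=200)
        clf = mc.cv_grid_search(ts, grid, k_features=200, folds=3, seed=0)
        s = clf.predict_scores(ts.bm.X)
        assert np.allclose(s.sum(axis=1), 1, atol=1e-12)


class TestTrainFinal:
    def test_resubstitution_accuracy_on_separable_data(self, fitted_small):
        tiny_split, ts, clf = fitted_small
        pred = clf.predict(ts.bm.X)
        assert (pred == ts.labels).mean() >= 0.98

    def test_scores_cover_all_classes_including_unknown(self, fitted_small):
        _, ts, clf = fitted_small
        assert set(clf.classes_) == set(ts.labels)
        assert UNKNOWN in clf.classes_
        assert clf.predict_scores(ts.bm.X[:3]).shape == (3, len(clf.classes_))

    def test_archive_roundtrip_identical_predictions(self, tmp_path, fitted_small):
        _, ts, clf = fitted_small
        mc.save_archive(clf, tmp_path / "model", probe_ids=ts.bm.probe_ids)
        clf2 = mc.load_archive(tmp_path / "model")
        p1 = mc.predict_beta_matrix(clf, ts.bm)
        p2 = mc.predict_beta_matrix(clf2, ts.bm)
        assert np.allclose(p1.to_numpy(), p2.to_numpy(), atol=1e-12)
        assert list(p1.columns) == list(p2.columns)

    def test_archive_refuses_newer_schema(self, tmp_path, fitted_small):
        import json
        _, ts, clf = fitted_small
        d = mc.save_archive(clf, tmp_path / "model2", probe_ids=ts.bm.probe_ids)
        meta = json.loads((d / "archive.json").read_text())
        meta["schema_version"] = 99
        (d / "archive.json").write_text(json.dumps(meta))
        with pytest.raises(ValueError, match="newer"):
            mc.load_archive(d)

    def test_missing_probes_named(self, fitted_small):
        _, ts, clf = fitted_small
        reduced = ts.bm.subset_probes(ts.bm.probe_ids[:100])
        with pytest.raises(KeyError):
            mc.predict_beta_matrix(clf, reduced)
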