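import numpy as np
import pandas as pd
import pytest

import methylclass as mc


@pytest.fixture
def toy_bm():
    """3 probes x 2 samples with hand-set values."""
    values = np.array([[0.1, 0.9], [0.5, 0.5], [0.2, 0.8]])
    return mc.BetaMatrix(values, ["cg1", "cg2", "cg3"], ["s1", "s2"],
                         ["450k", "EPIC"])


@pytest.fixture
def small_cohort():
    """A small simulated cohort (fast: 2000 probes, 3 classes)."""
    cfg = mc.SimConfig(n_classes=3, samples_per_class=12, n_probes=2000,
                       n_informative=60, seed=7)
    return mc.simulate_cohort(cfg)


@pytest.fixture(scope="session")
def default_split():
    """The default study-condition cohort: default SimConfig, K=5,
    40 samples/class, seed 1 (shared across slow end-to-end tests)."""
    return mc.simulate_split(mc.SimConfig(seed=1))


@pytest.fixture(scope="session")
def discovery_result(default_split):
    """filter -> top-20k -> t-SNE -> DBSCAN on the reference cohort.

    t-SNE gradient iterations reduced to 1000: convergence on a
    200-sample cohort is reached well before the full 4000 and the suite
    stays within desk-scale runtime.
    """
    split = default_split
    ref_bm, _ = split.part("reference")
    fbm = mc.filter_probes(ref_bm, split.manifest)
    fs = mc.select_top_variant(fbm, 20000)
    sub = mc.project(fbm, fs)
    emb = mc.tsne_embed(sub, n_iter=1000, seed=42)
    ca = mc.dbscan_cluster(emb)
    truth = split.truth.labels.loc[ref_bm.sample_ids].to_numpy()
    return {"split": split, "ref_bm": ref_bm, "sub": sub, "emb": emb,
            "ca": ca, "truth": truth}


@pytest.fixture(scope="session")
def trained_pipeline(default_split):
    """End-to-end SVM pipeline on the simulated split (reduced grid)."""
    split = default_split
    bm = mc.filter_probes(split.bm, split.manifest)
    sheet = split.sheet
    ref_ids = sheet.table.index[sheet.table["cohort"] == "reference"]
    pool_ids = sheet.table.index[sheet.table["cohort"] == "unknown_pool"]
    test_ids = sheet.table.index[sheet.table["cohort"] == "test"]
    ref_bm = bm.subset_samples(ref_ids)
    ref_labels = sheet.table.loc[ref_ids, "label"].to_numpy(dtype=object)
    ts = mc.assemble_training_set(ref_bm, ref_labels,
                                  bm.subset_samples(pool_ids), sheet,
                                  per_category_fraction=0.05, seed=1)
    grid = mc.svm_grid(kernels=("linear", "rbf"), cost_exponents=(0, 5),
                       gamma_exponents=(0,), k_features=20000)
    clf = mc.cv_grid_search(ts, grid, k_features=20000, folds=5, seed=1)
    test_bm = bm.subset_samples(test_ids)
    proba = mc.predict_beta_matrix(clf, test_bm)
    labels, conf = mc.predict_class(proba)
    report = mc.evaluate_predictions(labels, proba, sheet.subset(test_ids))
    return {"split": split, "ts": ts, "clf": clf, "test_bm": test_bm,
            "proba": proba, "pred_labels": labels, "report": report,
            "test_sheet": sheet.subset(test_ids)}


def brute_force_dbscan(X, eps, min_pts):
    """Textbook O(n^2) DBSCAN: independent oracle for cluster labels."""
    X = np.asarray(X, dtype=float)
    n = len(X)
    d = np.sqrt(((X[:, None, :] - X[None, :, :]) ** 2).sum(-1))
    neighbors = [np.where(d[i] <= eps)[0] for i in range(n)]
    core = np.array([len(nb) >= min_pts for nb in neighbors])
    labels = np.full(n, -2)  # -2 unvisited, -1 noise
    cluster = -1
    for i in range(n):
        if labels[i] != -2 or not core[i]:
            continue
        cluster += 1
        labels[i] = cluster
        stack = list(neighbors[i])
        while stack:
            j = stack.pop()
            if labels[j] == -1:
                labels[j] = cluster  # border point re-claimed
            if labels[j] != -2:
                continue
            labels[j] = cluster
            if core[j]:
                stack.extend(neighbors[j])
    labels[labels == -2] = -1
    return labels


def pair_count_auc(truth, scores):
    """Mann-Whitney concordance AUC with half ties: independent oracle."""
    truth = np.asarray(truth).astype(int)
    scores = np.asarray(scores, dtype=float)
    pos = scores[truth == 1]
    neg = scores[truth == 0]
    wins = (pos[:, None] > neg[None, :]).sum()
    ties = (pos[:, None] == neg[None, :]).sum()
    return (wins + 0.5 * ties) / (len(pos) * len(neg))
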