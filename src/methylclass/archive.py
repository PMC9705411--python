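"""Model archive: a versioned directory bundle for trained classifiers.

Layout::

    archive.json     schema version, family, winning hyperparameters,
                     class order, k_features, calibration (affine map)
    features.tsv     frozen feature list (probe_id, variance)
    model.joblib     the fitted sklearn model

Loading refuses archives written with a newer schema.
"""

from __future__ import annotations

import json
from pathlib import Path

import joblib
import numpy as np
import pandas as pd

from .calibrate import RidgeMultinomialCalibrator
from .classify import MethylClassifier
from .features import FeatureSet, VarianceFeatureSelector

SCHEMA_VERSION = 1

__all__ = ["save_archive", "load_archive", "SCHEMA_VERSION"]


def save_archive(clf: MethylClassifier, directory, probe_ids=None) -> Path:
    """Serialize a fitted classifier (with calibration) to `directory`.

    `probe_ids` names the training feature columns; positional names are
    used when omitted.
    """
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    if probe_ids is None:
        probe_ids = [f"feature_{i}" for i in range(clf.n_features_in_)]
    fs = clf.selector_.feature_set(probe_ids)
    fs.to_tsv(d / "features.tsv")
    meta = {
        "schema_version": SCHEMA_VERSION,
        "family": clf.family,
        "best_params": clf.best_params_,
        "best_loss": clf.best_loss_,
        "classes": list(clf.classes_),
        "k_features": clf.k_features,
        "random_state": clf.random_state,
        "n_features_in": int(clf.n_features_in_),
        "calibration": None,
    }
    if clf.calibrator_ is not None:
        cal = clf.calibrator_
        meta["calibration"] = {
            "classes": list(cal.classes_),
            "lambda": cal.lambda_,
            "coef": cal.coef_.tolist(),
            "intercept": cal.intercept_.tolist(),
        }
    (d / "archive.json").write_text(json.dumps(meta, indent=2) + "\n")
    joblib.dump(clf.model_, d / "model.joblib")
    return d


def load_archive(directory) -> MethylClassifier:
    """Reconstruct a fitted classifier from an archive directory."""
    d = Path(directory)
    meta = json.loads((d / "archive.json").read_text())
    if meta["schema_version"] > SCHEMA_VERSION:
        raise ValueError(
            f"archive schema {meta['schema_version']} is newer than "
            f"supported {SCHEMA_VERSION}; upgrade the toolkit")
    clf = MethylClassifier(family=meta["family"], k_features=meta["k_features"],
                           random_state=meta.get("random_state", 0))
    clf.classes_ = np.asarray(meta["classes"], dtype=object)
    clf.best_params_ = meta["best_params"]
    clf.best_loss_ = meta.get("best_loss")
    clf.n_features_in_ = meta["n_features_in"]
    clf.model_ = joblib.load(d / "model.joblib")

    fs_df = pd.read_csv(d / "features.tsv", sep="\t")
    sel = VarianceFeatureSelector(k=meta["k_features"])
    sel.n_features_in_ = meta["n_features_in"]
    # rebuild index-based selection from positional feature names when
    # possible; otherwise the caller must project probes before predict
    names = fs_df["probe_id"].to_numpy(dtype=object)
    sel.feature_names_ = names
    variances = fs_df["variance"].to_numpy(dtype=float)
    full_var = np.zeros(meta["n_features_in"])
    idx = []
    for name, v in zip(names, variances):
        if isinstance(name, str) and name.startswith("feature_"):
            j = int(name.split("_", 1)[1])
        else:
            j = None
        idx.append(j)
    if all(j is not None for j in idx):
        sel.selected_idx_ = np.asarray(idx, dtype=int)
    else:
        sel.selected_idx_ = None  # resolved at predict time via probe ids
    for j, v in zip(idx, variances):
        if j is not None:
            full_var[j] = v
    sel.variances_ = full_var
    clf.selector_ = sel
    clf.feature_set_ = FeatureSet(names, variances, meta["k_features"])

    cal_meta = meta.get("calibration")
    if cal_meta is not None:
        cal = RidgeMultinomialCalibrator()
        cal.classes_ = np.asarray(cal_meta["classes"], dtype=object)
        cal.lambda_ = cal_meta["lambda"]
        cal.coef_ = np.asarray(cal_meta["coef"], dtype=float)
        cal.intercept_ = np.asarray(cal_meta["intercept"], dtype=float)
        clf.calibrator_ = cal
    else:
        clf.calibrator_ = None
    return clf
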