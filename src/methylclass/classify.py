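"""Supervised methylation classification with an explicit Unknown class.

The training set combines the discovered reference classes with an
"Unknown" class drawn from a diverse pool of out-of-scope tumors (5% of
each pool category), so that profiles outside the reference spectrum are
rejected rather than force-assigned.  Hyperparameters for an SVM or
random-forest model are chosen by grid search minimizing the
class-balanced multinomial cross-entropy in a stratified five-fold
cross-validation, with the top-k variance feature selection refit inside
every fold.  The winner's out-of-fold scores feed the downstream ridge
calibration.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.ensemble import RandomForestClassifier
from sklearn.svm import SVC
from sklearn.utils.validation import check_is_fitted

from .data import BetaMatrix, SampleSheet
from .features import VarianceFeatureSelector

UNKNOWN = "Unknown"

__all__ = [
    "UNKNOWN",
    "predict_beta_matrix",
    "TrainingSet",
    "HyperParamGrid",
    "svm_grid",
    "rf_grid",
    "assemble_training_set",
    "balanced_log_loss",
    "MethylClassifier",
    "cv_grid_search",
    "train_final",
]


# ---------------------------------------------------------------------------
# Training-set assembly


@dataclass
class TrainingSet:
    """Reference classes plus the Unknown pool draw.

    ``provenance`` records, per sample, whether it came from the
    reference cohort or the unknown pool; Unknown-labeled samples may
    come only from the pool.
    """

    bm: BetaMatrix
    labels: np.ndarray
    provenance: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=object)
        self.provenance = np.asarray(self.provenance, dtype=object)
        n = self.bm.n_samples
        if len(self.labels) != n or len(self.provenance) != n:
            raise ValueError("labels/provenance must match sample count")
        counts = pd.Series(self.labels).value_counts()
        small = counts[counts < 2]
        if len(small):
            raise ValueError(f"classes with fewer than 2 members: {list(small.index)}")
        bad = (self.labels == UNKNOWN) & (self.provenance != "unknown_pool")
        if bad.any():
            raise ValueError("Unknown members must come from the unknown pool")

    @property
    def classes(self) -> list[str]:
        seen: list[str] = []
        for lab in self.labels:
            if lab not in seen:
                seen.append(lab)
        return seen


def assemble_training_set(reference_bm: BetaMatrix, reference_labels,
                          pool_bm: BetaMatrix | None, pool_sheet: SampleSheet | None,
                          per_category_fraction: float = 0.05,
                          seed: int = 0) -> TrainingSet:
    """Combine the reference cohort with a per-category Unknown draw.

    From every category of the pool, ``round(fraction * n)`` samples
    (at least 1 for a non-empty category) are drawn without replacement
    and labeled Unknown.  Probe sets must already be identical (merge
    platforms first).
    """
    reference_labels = np.asarray(reference_labels, dtype=object)
    if pool_bm is None or pool_bm.n_samples == 0 or per_category_fraction == 0:
        warnings.warn("no Unknown pool: training set has no Unknown class",
                      stacklevel=2)
        return TrainingSet(reference_bm, reference_labels,
                           np.full(reference_bm.n_samples, "reference", dtype=object))
    if list(reference_bm.probe_ids) != list(pool_bm.probe_ids):
        raise ValueError("probe sets incompatible; merge platforms / project first")
    rng = np.random.default_rng(seed)
    cats = pool_sheet.table.loc[pool_bm.sample_ids, "category"]
    chosen: list[str] = []
    for cat in sorted(cats.unique()):
        members = list(cats.index[cats == cat])
        n_draw = max(1, int(np.floor(per_category_fraction * len(members) + 0.5)))
        n_draw = min(n_draw, len(members))
        chosen += list(rng.choice(members, size=n_draw, replace=False))
    pool_sub = pool_bm.subset_samples(chosen)
    merged = BetaMatrix(
        np.hstack([reference_bm.values, pool_sub.values]),
        reference_bm.probe_ids.copy(),
        np.concatenate([reference_bm.sample_ids, pool_sub.sample_ids]),
        np.concatenate([reference_bm.platform, pool_sub.platform]),
    )
    labels = np.concatenate([reference_labels,
                             np.full(len(chosen), UNKNOWN, dtype=object)])
    provenance = np.concatenate([
        np.full(reference_bm.n_samples, "reference", dtype=object),
        np.full(len(chosen), "unknown_pool", dtype=object),
    ])
    return TrainingSet(merged, labels, provenance)


# ---------------------------------------------------------------------------
# Class-balanced multinomial cross-entropy


def balanced_log_loss(scores, labels, classes=None, eps: float = 1e-15) -> float:
    """Class-balanced multinomial cross-entropy.

    ``L = sum_i w_{y_i} * (-log p_{i, y_i}) / sum_i w_{y_i}`` with
    inverse-frequency weights ``w_c = N / (K * n_c)`` (mean weight 1), so
    every class contributes equally regardless of size.  Score rows are
    normalized to sum to 1; probabilities are floored at `eps` inside the
    log.  Equals the plain mean cross-entropy when all classes have equal
    size.
    """
    if isinstance(scores, pd.DataFrame):
        classes = list(scores.columns) if classes is None else classes
        scores = scores.to_numpy()
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=object)
    if classes is None:
        raise ValueError("classes required when scores is a bare array")
    classes = list(classes)
    if scores.shape != (len(labels), len(classes)):
        raise ValueError("scores shape inconsistent with labels/classes")
    missing = set(labels) - set(classes)
    if missing:
        raise ValueError(f"labels outside score columns: {sorted(missing)}")
    p = scores / scores.sum(axis=1, keepdims=True)
    col = {c: j for j, c in enumerate(classes)}
    y = np.array([col[lab] for lab in labels])
    counts = np.bincount(y, minlength=len(classes)).astype(float)
    present = counts > 0
    K = int(present.sum())
    if K == 0:
        raise ValueError("no labels")
    w_class = np.zeros(len(classes))
    w_class[present] = len(labels) / (K * counts[present])
    w = w_class[y]
    p_true = np.maximum(p[np.arange(len(labels)), y], eps)
    return float(np.sum(w * -np.log(p_true)) / np.sum(w))


# ---------------------------------------------------------------------------
# Hyperparameter grids


@dataclass
class HyperParamGrid:
    """An ordered list of hyperparameter combinations for one family.

    Enumeration order is part of the contract (grid-search ties go to
    the first enumerated combination): SVM is kernel -> cost -> gamma,
    RF is ntree -> mtry.
    """

    family: str
    combos: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.family not in ("svm", "rf"):
            raise ValueError("family must be 'svm' or 'rf'")
        if not self.combos:
            raise ValueError("empty hyperparameter grid")


def svm_grid(kernels=("linear", "rbf"), cost_exponents=range(0, 6),
             gamma_exponents=range(-3, 4), k_features: int = 20000) -> HyperParamGrid:
    """SVM grid: linear and RBF kernels, C = 2^0..5, gamma = 2^-3..3 / k.

    gamma applies only to the RBF kernel; the linear branch enumerates
    costs alone.
    """
    combos: list[dict] = []
    for kernel in kernels:
        for c in cost_exponents:
            if kernel == "linear":
                combos.append({"kernel": "linear", "cost": 2.0 ** c})
            else:
                for g in gamma_exponents:
                    combos.append({"kernel": kernel, "cost": 2.0 ** c,
                                   "gamma": 2.0 ** g / k_features})
    return HyperParamGrid("svm", combos)


def rf_grid(ntrees=(500, 1000), mtry_exponents=range(-5, 6),
            k_features: int = 20000) -> HyperParamGrid:
    """RF grid: ntree in {500, 1000}, mtry = round(2^m * sqrt(k)) for
    m = -5..5, clipped to [1, n_features] at fit time."""
    combos = [{"ntree": int(t), "mtry": max(1, int(round(2.0 ** m * np.sqrt(k_features))))}
              for t in ntrees for m in mtry_exponents]
    return HyperParamGrid("rf", combos)


def _build_model(family: str, params: dict, n_features: int, random_state: int):
    if family == "svm":
        kwargs = dict(C=params["cost"], kernel=params["kernel"], probability=True,
                      random_state=random_state)
        if params["kernel"] == "rbf":
            kwargs["gamma"] = params["gamma"]
        return SVC(**kwargs)
    mtry = min(max(1, int(params["mtry"])), n_features)
    return RandomForestClassifier(n_estimators=params["ntree"], max_features=mtry,
                                  random_state=random_state, n_jobs=1)


# ---------------------------------------------------------------------------
# The classifier estimator


def _stratified_folds(labels: np.ndarray, sample_ids, n_folds: int, seed: int):
    """Stratified fold assignment keyed by sample id.

    Within every class, samples are ordered by id (or by position when no
    ids are given), shuffled with the fold seed and dealt round-robin, so
    the id -> fold map is invariant to sample order in the input.
    Returns an int array of fold indices aligned with `labels`.
    """
    n = len(labels)
    if sample_ids is None:
        sample_ids = np.arange(n)
    order_key = np.argsort(np.asarray(sample_ids, dtype=object), kind="stable")
    rng = np.random.default_rng(seed)
    folds = np.empty(n, dtype=int)
    for lab in sorted(set(labels)):
        members = [i for i in order_key if labels[i] == lab]
        members = list(rng.permutation(members))
        start = int(rng.integers(0, n_folds))
        for j, i in enumerate(members):
            folds[i] = (start + j) % n_folds
    return folds


class MethylClassifier(BaseEstimator, ClassifierMixin):
    """Grid-searched methylation classifier (SVM or random forest).

    ``fit`` performs the full development protocol: stratified k-fold
    cross-validation with per-fold top-k variance feature selection,
    grid search minimizing :func:`balanced_log_loss` on the held-out
    folds, retraining on the full set at the winning combination, and
    (optionally) ridge-multinomial calibration of the winner's
    out-of-fold scores.

    Parameters
    ----------
    family : {"svm", "rf"}
    grid : HyperParamGrid or None
        Defaults to the full family grid.
    k_features : int, default 20000
        Variance feature selection size (refit per fold and on the
        full set).
    folds : int, default 5
    random_state : int, default 0
    calibrate : bool, default True
        Fit a :class:`methylclass.calibrate.RidgeMultinomialCalibrator`
        on the out-of-fold scores.
    calibration_folds : int, default 10

    Attributes
    ----------
    classes_ : ndarray of str
        Class order (training-set first-appearance order).
    cv_results_ : DataFrame with one row per grid combination.
    best_params_, best_loss_ : winning combination and its mean loss.
    oof_scores_ : DataFrame (samples x classes) of out-of-fold scores at
        the winner.
    fold_assignment_ : Series sample -> fold index.
    fold_feature_idx_ : list of per-fold selected feature indices.
    selector_ : the full-set VarianceFeatureSelector.
    model_ : the final fitted model.
    calibrator_ : fitted calibrator (if requested).
    """

    _archive_schema = 1

    def __init__(self, family: str = "svm", grid: HyperParamGrid | None = None,
                 k_features: int = 20000, folds: int = 5, random_state: int = 0,
                 calibrate: bool = True, calibration_folds: int = 10):
        self.family = family
        self.grid = grid
        self.k_features = k_features
        self.folds = folds
        self.random_state = random_state
        self.calibrate = calibrate
        self.calibration_folds = calibration_folds

    # -- fitting ----------------------------------------------------------
    def fit(self, X, y, sample_ids=None):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=object)
        if X.ndim != 2 or X.shape[0] != len(y):
            raise ValueError("X must be (n_samples, n_features) aligned with y")
        if sample_ids is not None:
            # canonical sample order: SVM probability fitting is
            # order-sensitive, so results must be keyed to ids, not rows
            sample_ids = np.asarray(sample_ids, dtype=object)
            order = np.argsort(sample_ids, kind="stable")
            X, y, sample_ids = X[order], y[order], sample_ids[order]
        classes: list[str] = []
        for lab in y:
            if lab not in classes:
                classes.append(lab)
        if len(classes) < 2:
            raise ValueError("need at least two classes")
        self.classes_ = np.asarray(classes, dtype=object)

        grid = self.grid if self.grid is not None else (
            svm_grid(k_features=self.k_features) if self.family == "svm"
            else rf_grid(k_features=self.k_features))
        if grid.family != self.family:
            raise ValueError(f"grid family {grid.family!r} != {self.family!r}")

        min_class = pd.Series(y).value_counts().min()
        n_folds = self.folds
        if min_class < n_folds:
            n_folds = max(2, int(min_class))
            warnings.warn(f"smallest class has {min_class} members; "
                          f"reducing folds to {n_folds}", stacklevel=2)
        folds = _stratified_folds(y, sample_ids, n_folds, self.random_state)

        n, K, G = X.shape[0], len(classes), len(grid.combos)
        oof = np.zeros((G, n, K))
        self.fold_feature_idx_ = []
        for f in range(n_folds):
            val = folds == f
            tr = ~val
            sel = VarianceFeatureSelector(k=self.k_features).fit(X[tr])
            self.fold_feature_idx_.append(sel.selected_idx_.copy())
            Xtr, Xval = sel.transform(X[tr]), sel.transform(X[val])
            ytr = y[tr]
            for g, params in enumerate(grid.combos):
                model = _build_model(self.family, params, Xtr.shape[1],
                                     self.random_state)
                model.fit(Xtr, ytr)
                proba = model.predict_proba(Xval)
                aligned = np.zeros((Xval.shape[0], K))
                for j, c in enumerate(model.classes_):
                    aligned[:, classes.index(c)] = proba[:, j]
                oof[g, val] = aligned

        losses = np.array([balanced_log_loss(oof[g], y, classes)
                           for g in range(G)])
        best = int(np.argmin(losses))  # ties -> first enumerated combination
        self.cv_results_ = pd.DataFrame({"params": grid.combos,
                                         "mean_balanced_loss": losses})
        self.best_params_ = grid.combos[best]
        self.best_loss_ = float(losses[best])
        index = (np.asarray(sample_ids, dtype=object) if sample_ids is not None
                 else pd.RangeIndex(n))
        self.oof_scores_ = pd.DataFrame(oof[best], index=index, columns=classes)
        self.fold_assignment_ = pd.Series(folds, index=index, name="fold")
        self.n_folds_ = n_folds
        self.grid_ = grid

        # final refit on the full training set
        self.selector_ = VarianceFeatureSelector(k=self.k_features).fit(X)
        Xsel = self.selector_.transform(X)
        self.model_ = _build_model(self.family, self.best_params_, Xsel.shape[1],
                                   self.random_state)
        self.model_.fit(Xsel, y)
        self.n_features_in_ = X.shape[1]

        if self.calibrate:
            from .calibrate import RidgeMultinomialCalibrator
            self.calibrator_ = RidgeMultinomialCalibrator(
                folds=self.calibration_folds,
                random_state=self.random_state).fit(self.oof_scores_, y)
        else:
            self.calibrator_ = None
        return self

    # -- prediction -------------------------------------------------------
    def _raw_scores(self, X) -> np.ndarray:
        check_is_fitted(self, "model_")
        X = np.asarray(X, dtype=float)
        proba = self.model_.predict_proba(self.selector_.transform(X))
        aligned = np.zeros((X.shape[0], len(self.classes_)))
        order = list(self.classes_)
        for j, c in enumerate(self.model_.classes_):
            aligned[:, order.index(c)] = proba[:, j]
        return aligned

    def predict_scores(self, X) -> np.ndarray:
        """Raw per-class scores (SVM: pairwise-coupled Platt
        probabilities; RF: tree-vote fractions)."""
        return self._raw_scores(X)

    def predict_proba(self, X) -> np.ndarray:
        """Calibrated class probabilities (raw scores if uncalibrated)."""
        raw = self._raw_scores(X)
        if self.calibrator_ is None:
            return raw
        return self.calibrator_.predict_proba(raw)

    def predict(self, X) -> np.ndarray:
        from .calibrate import predict_class
        labels, _ = predict_class(
            pd.DataFrame(self.predict_proba(X), columns=self.classes_))
        return labels


def predict_beta_matrix(clf: MethylClassifier, bm: BetaMatrix) -> pd.DataFrame:
    """Score a BetaMatrix against a trained classifier by probe id.

    The matrix is projected onto the classifier's frozen feature list
    (error naming missing probes) and calibrated probabilities are
    returned as a samples x classes DataFrame.
    """
    from .features import project
    check_is_fitted(clf, "model_")
    fs = getattr(clf, "feature_set_", None)
    if fs is None:
        raise ValueError("classifier carries no feature set; fit via "
                         "cv_grid_search/train_final or load an archive")
    sub = project(bm, fs)
    X = sub.X  # samples x k, frozen feature order
    proba = clf.model_.predict_proba(X)
    aligned = np.zeros((X.shape[0], len(clf.classes_)))
    order = list(clf.classes_)
    for j, c in enumerate(clf.model_.classes_):
        aligned[:, order.index(c)] = proba[:, j]
    if clf.calibrator_ is not None:
        aligned = clf.calibrator_.predict_proba(aligned)
    return pd.DataFrame(aligned, index=bm.sample_ids, columns=clf.classes_)


# ---------------------------------------------------------------------------
# Module-level operation wrappers


def cv_grid_search(ts: TrainingSet, grid: HyperParamGrid, k_features: int = 20000,
                   folds: int = 5, seed: int = 0) -> MethylClassifier:
    """Run the grid-search CV protocol on a training set; returns the
    fitted :class:`MethylClassifier` (its ``cv_results_`` is the
    leaderboard, ``oof_scores_`` the winner's out-of-fold scores)."""
    clf = MethylClassifier(family=grid.family, grid=grid, k_features=k_features,
                           folds=folds, random_state=seed)
    clf.fit(ts.bm.X, ts.labels, sample_ids=ts.bm.sample_ids)
    clf.feature_set_ = clf.selector_.feature_set(ts.bm.probe_ids)
    return clf


def train_final(ts: TrainingSet, winner: dict, family: str = "svm",
                k_features: int = 20000, seed: int = 0,
                calibrate: bool = False) -> MethylClassifier:
    """Retrain on the full training set at fixed winning hyperparameters
    (a one-point grid, so no search is repeated)."""
    grid = HyperParamGrid(family, [winner])
    clf = MethylClassifier(family=family, grid=grid, k_features=k_features,
                           random_state=seed, calibrate=calibrate)
    clf.fit(ts.bm.X, ts.labels, sample_ids=ts.bm.sample_ids)
    clf.feature_set_ = clf.selector_.feature_set(ts.bm.probe_ids)
    return clf
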