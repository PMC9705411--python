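"""Ridge-multinomial calibration of raw classifier scores.

Raw SVM/RF scores are mapped to interpretable class probabilities by a
ridge-penalized multinomial logistic regression fitted on the *out-of-fold*
scores from the hyperparameter cross-validation (never on resubstitution
scores, which would be over-confident).  The ridge penalty lambda is
chosen by internal cross-validation as the value with minimum mean
cross-validated multinomial deviance, over a descending grid auto-scaled
from the data.

The multinomial parameterization is symmetric (one ridge-penalized
coefficient vector per class, no reference class, intercepts
unpenalized), so permuting class columns and labels permutes the
calibrated output identically.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.linear_model import LogisticRegressionCV
from sklearn.model_selection import StratifiedKFold
from sklearn.utils.validation import check_is_fitted

__all__ = ["RidgeMultinomialCalibrator", "CalibratedScores",
           "fit_calibration", "calibrate", "predict_class"]


def _auto_lambda_grid(S: np.ndarray, y_idx: np.ndarray, n_classes: int,
                      n_values: int = 100, decades: float = 4.0) -> np.ndarray:
    """Descending lambda grid auto-scaled from the score matrix.

    Scaled from the largest absolute score-indicator covariance
    ``max |S^T (Y - p0)| / n`` (inflated two decades upward so the top of
    the path is effectively intercept-only under ridge, which has no
    finite null point), spanning `decades` decades downward.
    """
    n = S.shape[0]
    Y = np.zeros((n, n_classes))
    Y[np.arange(n), y_idx] = 1.0
    resid = Y - Y.mean(axis=0, keepdims=True)
    base = np.abs(S.T @ resid).max() / n
    base = max(base, 1e-6)
    lam_max = base * 100.0
    return np.logspace(np.log10(lam_max), np.log10(lam_max) - decades, n_values)


class RidgeMultinomialCalibrator(BaseEstimator, TransformerMixin):
    """Ridge-penalized multinomial logistic calibration model.

    Parameters
    ----------
    folds : int, default 10
        Internal cross-validation folds for selecting lambda.
    lambda_grid : array-like or None
        Descending ridge penalties; None auto-scales a 100-value grid.
    random_state : int, default 0

    Attributes
    ----------
    classes_ : ndarray — class order, identical to the score columns.
    lambda_ : float — selected penalty (minimum mean CV deviance).
    coef_, intercept_ : the affine map into class logits.
    """

    def __init__(self, folds: int = 10, lambda_grid=None, random_state: int = 0):
        self.folds = folds
        self.lambda_grid = lambda_grid
        self.random_state = random_state

    def fit(self, S, y):
        if isinstance(S, pd.DataFrame):
            self.classes_ = np.asarray(S.columns, dtype=object)
            S = S.to_numpy(dtype=float)
        else:
            S = np.asarray(S, dtype=float)
            self.classes_ = None
        y = np.asarray(y, dtype=object)
        if self.classes_ is None:
            # class order = column order convention: first appearance in y
            seen: list = []
            for lab in y:
                if lab not in seen:
                    seen.append(lab)
            if len(seen) != S.shape[1]:
                raise ValueError("cannot infer class order; pass a DataFrame "
                                 "with class columns")
            self.classes_ = np.asarray(seen, dtype=object)
        order = {c: j for j, c in enumerate(self.classes_)}
        missing = set(y) - set(order)
        if missing:
            raise ValueError(f"labels absent from score columns: {sorted(missing)}")
        absent = set(order) - set(y)
        if absent:
            raise ValueError(f"classes absent from labels: {sorted(absent)}")
        y_idx = np.array([order[lab] for lab in y])
        n, K = S.shape

        lambdas = (np.asarray(self.lambda_grid, dtype=float)
                   if self.lambda_grid is not None
                   else _auto_lambda_grid(S, y_idx, K))
        lambdas = np.sort(lambdas)[::-1]
        if np.any(lambdas <= 0):
            raise ValueError("ridge penalties must be positive")
        Cs = 1.0 / (n * lambdas)  # sklearn C  <->  glmnet lambda

        folds = min(self.folds, int(pd.Series(y_idx).value_counts().min()))
        if folds < self.folds:
            warnings.warn(f"reducing calibration folds to {folds} "
                          "(smallest class size)", stacklevel=2)
        cv = StratifiedKFold(n_splits=max(2, folds), shuffle=True,
                             random_state=self.random_state)
        lr = LogisticRegressionCV(
            Cs=Cs, cv=cv, l1_ratios=(0.0,), solver="lbfgs",
            scoring="neg_log_loss", max_iter=5000, refit=True,
            random_state=self.random_state, use_legacy_attributes=True,
        ).fit(S, y_idx)
        self._lr = lr
        self.C_ = float(np.atleast_1d(lr.C_)[0])
        self.lambda_ = 1.0 / (n * self.C_)
        # align coefficient rows with classes_ (lr.classes_ are sorted indices)
        coef = np.zeros((K, K))
        intercept = np.zeros(K)
        for row, cls_idx in enumerate(lr.classes_):
            coef[int(cls_idx)] = lr.coef_[row]
            intercept[int(cls_idx)] = lr.intercept_[row]
        self.coef_ = coef
        self.intercept_ = intercept
        return self

    def predict_proba(self, S) -> np.ndarray:
        """Softmax of the fitted affine map; rows sum to 1."""
        check_is_fitted(self, "coef_")
        if isinstance(S, pd.DataFrame):
            if list(S.columns) != list(self.classes_):
                raise ValueError("score columns do not match calibration class order")
            S = S.to_numpy(dtype=float)
        S = np.asarray(S, dtype=float)
        if S.shape[1] != self.coef_.shape[1]:
            raise ValueError("score matrix width does not match calibration model")
        logits = S @ self.coef_.T + self.intercept_
        logits -= logits.max(axis=1, keepdims=True)
        p = np.exp(logits)
        p /= p.sum(axis=1, keepdims=True)
        return p

    transform = predict_proba


@dataclass
class CalibratedScores:
    """Samples x classes calibrated probabilities (rows sum to 1)."""

    probabilities: pd.DataFrame

    def __post_init__(self) -> None:
        p = self.probabilities.to_numpy()
        if p.size:
            if (p < -1e-12).any() or (p > 1 + 1e-12).any():
                raise ValueError("probabilities outside [0, 1]")
            if np.abs(p.sum(axis=1) - 1).max() > 1e-9:
                raise ValueError("rows must sum to 1 within 1e-9")

    @property
    def classes(self) -> list[str]:
        return list(self.probabilities.columns)

    def to_tsv(self, path) -> None:
        labels, conf = predict_class(self.probabilities)
        out = self.probabilities.copy()
        out["predicted_class"] = labels
        out["max_probability"] = conf
        out.to_csv(path, sep="\t", index_label="sample_id", float_format="%.10g")


def fit_calibration(oof_scores: pd.DataFrame, labels, lambda_grid=None,
                    folds: int = 10, seed: int = 0) -> RidgeMultinomialCalibrator:
    """Fit the calibration model on out-of-fold classifier scores."""
    return RidgeMultinomialCalibrator(folds=folds, lambda_grid=lambda_grid,
                                      random_state=seed).fit(oof_scores, labels)


def calibrate(model: RidgeMultinomialCalibrator, raw: pd.DataFrame) -> CalibratedScores:
    """Apply a fitted calibration model to raw scores."""
    p = model.predict_proba(raw)
    index = raw.index if isinstance(raw, pd.DataFrame) else pd.RangeIndex(len(p))
    return CalibratedScores(pd.DataFrame(p, index=index, columns=model.classes_))


def predict_class(cal: pd.DataFrame | CalibratedScores):
    """Per-sample final prediction: the class with the highest calibrated
    score, plus that probability.  Exact ties go to the first class in
    column order, with a warning."""
    df = cal.probabilities if isinstance(cal, CalibratedScores) else cal
    if len(df) == 0:
        raise ValueError("empty score matrix")
    p = df.to_numpy(dtype=float)
    best = p.argmax(axis=1)  # argmax takes the first maximum
    ties = (p == p[np.arange(len(p)), best][:, None]).sum(axis=1) > 1
    if ties.any():
        warnings.warn(f"{int(ties.sum())} tied prediction(s); "
                      "first class in order chosen", stacklevel=2)
    labels = np.asarray(df.columns, dtype=object)[best]
    return labels, p[np.arange(len(p)), best]
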