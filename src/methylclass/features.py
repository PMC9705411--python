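"""Variance-based CpG feature selection.

Every downstream step (embedding, clustering, classification) operates on
the k most variant CpG sites of its *own* training data — inside
cross-validation the selection is refit on each training part and applied
to the held-out fold.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_array, check_is_fitted

from .data import BetaMatrix

__all__ = ["FeatureSet", "VarianceFeatureSelector", "select_top_variant", "project"]


@dataclass
class FeatureSet:
    """An ordered top-k variance feature set.

    ``probe_ids`` are sorted by descending sample variance (ties broken by
    input probe order); ``variances`` are the corresponding values.
    """

    probe_ids: np.ndarray
    variances: np.ndarray
    k: int

    def __post_init__(self) -> None:
        self.probe_ids = np.asarray(self.probe_ids, dtype=object)
        self.variances = np.asarray(self.variances, dtype=float)
        if len(self.probe_ids) != len(self.variances):
            raise ValueError("probe_ids and variances length mismatch")
        if len(self.probe_ids) > self.k:
            raise ValueError("feature set longer than k")
        if np.any(np.diff(self.variances) > 1e-12):
            raise ValueError("variances must be non-increasing")

    def __len__(self) -> int:
        return len(self.probe_ids)

    def to_tsv(self, path) -> None:
        pd.DataFrame({"probe_id": self.probe_ids, "variance": self.variances}).to_csv(
            path, sep="\t", index=False, float_format="%.17g")

    @classmethod
    def from_tsv(cls, path, k: int | None = None) -> "FeatureSet":
        df = pd.read_csv(path, sep="\t")
        return cls(df["probe_id"].to_numpy(dtype=object),
                   df["variance"].to_numpy(dtype=float),
                   k if k is not None else len(df))


class VarianceFeatureSelector(BaseEstimator, TransformerMixin):
    """Select the k features with largest sample variance (ddof=1).

    Unlike a plain support-mask selector, :meth:`transform` returns the
    selected columns in *descending-variance order*, so the transformed
    matrix aligns with the serialized :class:`FeatureSet`.  Ties are
    broken by input column order.

    Parameters
    ----------
    k : int, default 20000
        Number of features to retain; if ``k >= n_features`` all features
        are returned (variance-sorted).

    Attributes
    ----------
    variances_ : ndarray of shape (n_features,)
        Sample variance of every input feature.
    selected_idx_ : ndarray of shape (min(k, n_features),)
        Input column indices of the selection, descending variance.
    """

    def __init__(self, k: int = 20000):
        self.k = k

    def fit(self, X, y=None):
        if self.k < 1:
            raise ValueError(f"k must be >= 1, got {self.k}")
        X = check_array(X, dtype=float)
        if X.shape[0] < 2:
            raise ValueError("variance requires at least 2 samples")
        self.n_features_in_ = X.shape[1]
        self.variances_ = X.var(axis=0, ddof=1)
        order = np.argsort(-self.variances_, kind="stable")  # ties -> input order
        self.selected_idx_ = order[: min(self.k, X.shape[1])]
        return self

    def transform(self, X):
        check_is_fitted(self, "selected_idx_")
        X = check_array(X, dtype=float)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"X has {X.shape[1]} features, selector was fitted on {self.n_features_in_}")
        return X[:, self.selected_idx_]

    def feature_set(self, probe_ids) -> FeatureSet:
        """Materialize the fitted selection against probe identifiers."""
        check_is_fitted(self, "selected_idx_")
        probe_ids = np.asarray(probe_ids, dtype=object)
        if len(probe_ids) != self.n_features_in_:
            raise ValueError("probe_ids length mismatch with fitted data")
        return FeatureSet(probe_ids[self.selected_idx_],
                          self.variances_[self.selected_idx_], self.k)


def select_top_variant(bm: BetaMatrix, k: int = 20000) -> FeatureSet:
    """Rank probes of `bm` by sample variance and keep the top k."""
    sel = VarianceFeatureSelector(k=k).fit(bm.X)
    return sel.feature_set(bm.probe_ids)


def project(bm: BetaMatrix, fs: FeatureSet) -> BetaMatrix:
    """Restrict `bm` to the probes of `fs`, in feature-set order."""
    missing = [p for p in fs.probe_ids if p not in set(bm.probe_ids)]
    if missing:
        raise KeyError(f"feature-set probes absent from matrix: {missing[:10]}")
    return bm.subset_probes(fs.probe_ids)
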