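"""Unsupervised class discovery on methylation profiles.

A cohort is embedded into two dimensions with t-SNE (perplexity 20,
4000 gradient iterations by default), classes are called on the embedding
with DBSCAN (minPts 6), samples in no dense region are labeled NOISE and
excluded from the reference set, and the robustness of the partition is
quantified by iterative random downsampling to 80% of the cohort with
Pearson correlation of the re-embedded against the reference coordinates
(300 iterations by default).

t-SNE coordinates are not rotation/sign-identifiable, so the stability
re-embeddings are warm-started from the reference coordinates of the
retained samples: the coordinate correlation is only meaningful under a
shared frame.  Warm restarts skip the early-exaggeration phase — starting
a converged configuration with re-exaggeration would tear the clusters
apart rather than refine them.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import pearsonr
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.cluster import DBSCAN
from sklearn.manifold import TSNE
from sklearn.metrics import silhouette_score
from sklearn.neighbors import NearestNeighbors

from .data import BetaMatrix

NOISE = "NOISE"

__all__ = [
    "NOISE",
    "Embedding",
    "ClusterAssignment",
    "StabilityReport",
    "TSNEEmbedder",
    "DensityClusterer",
    "estimate_eps",
    "select_eps",
    "tsne_embed",
    "dbscan_cluster",
    "exclude_noise",
    "stability_downsample",
]


@dataclass
class Embedding:
    """A 2-D t-SNE embedding of a cohort."""

    coords: np.ndarray  # (n_samples, 2)
    sample_ids: np.ndarray
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.sample_ids = np.asarray(self.sample_ids, dtype=object)
        if self.coords.ndim != 2 or self.coords.shape[1] != 2:
            raise ValueError("coords must be (n_samples, 2)")
        if self.coords.shape[0] != len(self.sample_ids):
            raise ValueError("one coordinate row per sample required")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite embedding coordinates")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.coords, index=self.sample_ids, columns=["x", "y"])


@dataclass
class ClusterAssignment:
    """Per-sample discovered class label ('class_1'..'class_K' or NOISE)."""

    sample_ids: np.ndarray
    labels: np.ndarray
    min_pts: int = 6
    eps: float = np.nan

    def __post_init__(self) -> None:
        self.sample_ids = np.asarray(self.sample_ids, dtype=object)
        self.labels = np.asarray(self.labels, dtype=object)
        if len(self.sample_ids) != len(self.labels):
            raise ValueError("one label per sample required")
        counts = pd.Series(self.labels).value_counts()
        small = counts.drop(NOISE, errors="ignore") < self.min_pts
        if small.any():
            raise ValueError(
                f"clusters smaller than min_pts={self.min_pts}: "
                f"{list(counts.index[:len(small)][small])}")

    @property
    def classes(self) -> list[str]:
        seen: list[str] = []
        for lab in self.labels:
            if lab != NOISE and lab not in seen:
                seen.append(lab)
        return seen

    @property
    def n_clusters(self) -> int:
        return len(set(self.labels) - {NOISE})

    def to_frame(self, emb: Embedding | None = None) -> pd.DataFrame:
        df = pd.DataFrame({"cluster": self.labels}, index=self.sample_ids)
        if emb is not None:
            df = emb.to_frame().join(df)
        return df


@dataclass
class StabilityReport:
    """Downsampling stability of a reference embedding."""

    per_iteration_r: np.ndarray
    fraction: float = 0.8

    def __post_init__(self) -> None:
        self.per_iteration_r = np.asarray(self.per_iteration_r, dtype=float)
        if np.any(np.abs(self.per_iteration_r) > 1 + 1e-12):
            raise ValueError("correlation coefficients must lie in [-1, 1]")

    @property
    def median_r(self) -> float:
        return float(np.median(self.per_iteration_r))

    @property
    def range_r(self) -> tuple[float, float]:
        return float(self.per_iteration_r.min()), float(self.per_iteration_r.max())

    def __str__(self) -> str:
        lo, hi = self.range_r
        return (f"stability over {len(self.per_iteration_r)} iterations "
                f"(fraction={self.fraction}): median r = {self.median_r:.3f} "
                f"(range: {lo:.3f} to {hi:.3f})")


class TSNEEmbedder(BaseEstimator):
    """t-SNE into two dimensions with cohort-discovery defaults.

    Parameters mirror the Rtsne conventions used for methylation class
    discovery: ``perplexity=20``, ``n_iter=4000``.  ``init`` may be "pca"
    (deterministic default) or an (n, 2) array for warm starts; for array
    inits early exaggeration is disabled.
    """

    def __init__(self, perplexity: float = 20.0, n_iter: int = 4000,
                 random_state: int = 42, init="pca"):
        self.perplexity = perplexity
        self.n_iter = n_iter
        self.random_state = random_state
        self.init = init

    def fit_transform(self, X, y=None):
        X = np.asarray(X, dtype=float)
        n = X.shape[0]
        if n <= 3 * self.perplexity:
            raise ValueError(
                f"need n_samples > 3*perplexity ({3 * self.perplexity:.0f}), got {n}")
        warm = isinstance(self.init, np.ndarray)
        tsne = TSNE(
            n_components=2,
            perplexity=self.perplexity,
            max_iter=self.n_iter,
            init=self.init,
            early_exaggeration=1.0 if warm else 12.0,
            learning_rate="auto",
            random_state=self.random_state,
        )
        self.embedding_ = tsne.fit_transform(X)
        return self.embedding_


class DensityClusterer(BaseEstimator, ClusterMixin):
    """DBSCAN over 2-D embedding coordinates with data-driven eps.

    ``eps="auto"`` selects the neighborhood radius by a small model
    sweep (:func:`select_eps`): candidate radii are drawn from the
    min_pts-nearest-neighbor distance curve and the radius whose DBSCAN
    solution maximizes the coverage-weighted silhouette is kept.  The
    classical k-distance knee (:func:`estimate_eps`) is the fallback
    when no candidate yields more than one cluster.

    Attributes
    ----------
    labels_ : ndarray of int
        DBSCAN labels; -1 marks noise.
    eps_ : float
        Neighborhood radius actually used.
    """

    def __init__(self, min_pts: int = 6, eps="auto"):
        self.min_pts = min_pts
        self.eps = eps

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        self.eps_ = select_eps(X, self.min_pts) if self.eps == "auto" else float(self.eps)
        if self.eps_ <= 0:
            raise ValueError(f"eps must be positive, got {self.eps_}")
        self.labels_ = DBSCAN(eps=self.eps_, min_samples=self.min_pts).fit(X).labels_
        return self


def estimate_eps(coords: np.ndarray, min_pts: int = 6,
                 significance: float = 0.15) -> float:
    """Knee of the sorted min_pts-nearest-neighbor distance curve.

    Both axes of the ascending k-distance curve are normalized to [0, 1]
    and the knee is the point of maximum *convex* deviation below the
    end-to-end chord (the maximum-curvature criterion): a flat dense body
    followed by a steep tail of sparse points.  A knee only exists when
    that deviation exceeds `significance`; for a near-linear or concave
    curve (no density break, hence no noise regime to cut off) the top of
    the curve is returned so that every observed neighborhood is dense.
    Degenerate curves (all distances equal, e.g. coincident points)
    return a small positive radius.
    """
    coords = np.asarray(coords, dtype=float)
    n = coords.shape[0]
    k = min(min_pts, n)
    nn = NearestNeighbors(n_neighbors=k).fit(coords)
    dist, _ = nn.kneighbors(coords)
    d = np.sort(dist[:, -1])  # k-distance curve, ascending
    if d[-1] <= 0:
        return 1e-12
    if np.isclose(d[0], d[-1]):
        return float(d[-1])
    x = np.linspace(0.0, 1.0, n)
    y = (d - d[0]) / (d[-1] - d[0])
    dev = x - y  # positive where the curve dips below the chord (convex)
    knee = int(np.argmax(dev))
    if dev[knee] < significance:
        return float(d[-1])
    return float(max(d[knee], 1e-12))


def select_eps(coords: np.ndarray, min_pts: int = 6,
               min_coverage: float = 0.5) -> float:
    """Data-driven DBSCAN radius for embedding coordinates.

    The k-distance knee alone is unreliable on t-SNE output, whose
    within-cluster density falls off smoothly instead of breaking at a
    noise tail.  Here candidate radii — upper quantiles of the
    min_pts-nearest-neighbor distance curve plus multiples of its
    maximum — are each clustered, and the radius maximizing the
    silhouette of the clustered points, weighted by the fraction of
    points clustered, wins.  Solutions clustering fewer than
    `min_coverage` of the points or yielding a single cluster are not
    eligible; if nothing is eligible the k-distance knee
    (:func:`estimate_eps`) is returned.
    """
    coords = np.asarray(coords, dtype=float)
    n = len(coords)
    k = min(min_pts, n)
    nn = NearestNeighbors(n_neighbors=k).fit(coords)
    d = np.sort(nn.kneighbors(coords)[0][:, -1])
    if d[-1] <= 0:
        return estimate_eps(coords, min_pts)
    cand = np.unique(np.r_[np.quantile(d, np.linspace(0.5, 1.0, 11)),
                           d[-1] * np.array([1.25, 1.5, 2.0, 3.0, 4.0, 6.0])])
    cand = cand[cand > 0]
    best_eps, best_score = None, -np.inf
    for eps in cand:
        labels = DBSCAN(eps=eps, min_samples=min_pts).fit(coords).labels_
        m = labels != -1
        if len(set(labels[m])) < 2 or m.sum() < min_coverage * n:
            continue
        score = silhouette_score(coords[m], labels[m]) * (m.sum() / n)
        if score > best_score:
            best_eps, best_score = float(eps), score
    if best_eps is None:
        return estimate_eps(coords, min_pts)
    return best_eps


def tsne_embed(bm: BetaMatrix, perplexity: float = 20.0, n_iter: int = 4000,
               seed: int = 42, init="pca") -> Embedding:
    """Embed a cohort (samples of `bm`) into 2-D with t-SNE."""
    emb = TSNEEmbedder(perplexity=perplexity, n_iter=n_iter,
                       random_state=seed, init=init)
    coords = emb.fit_transform(bm.X)
    return Embedding(coords, bm.sample_ids,
                     params={"perplexity": perplexity, "iterations": n_iter, "seed": seed})


def dbscan_cluster(emb: Embedding, min_pts: int = 6, eps="auto") -> ClusterAssignment:
    """Call classes on an embedding with DBSCAN; unclustered points are NOISE.

    Cluster labels are renumbered 'class_1'..'class_K' in order of first
    appearance along the sample axis.
    """
    clus = DensityClusterer(min_pts=min_pts, eps=eps).fit(emb.coords)
    raw = clus.labels_
    mapping: dict[int, str] = {}
    labels = np.empty(len(raw), dtype=object)
    for i, lab in enumerate(raw):
        if lab == -1:
            labels[i] = NOISE
        else:
            if lab not in mapping:
                mapping[lab] = f"class_{len(mapping) + 1}"
            labels[i] = mapping[lab]
    return ClusterAssignment(emb.sample_ids, labels, min_pts=min_pts, eps=clus.eps_)


def exclude_noise(bm: BetaMatrix, ca: ClusterAssignment):
    """Drop NOISE samples from matrix and assignment (reference-set step)."""
    if set(bm.sample_ids) - set(ca.sample_ids):
        raise ValueError("assignment does not cover all samples")
    lab = pd.Series(ca.labels, index=ca.sample_ids).loc[bm.sample_ids]
    keep = (lab != NOISE).to_numpy()
    if not keep.any():
        warnings.warn("all samples are noise points", stacklevel=2)
    kept_ids = bm.sample_ids[keep]
    return (
        bm.subset_samples(kept_ids) if keep.any() else
        BetaMatrix(bm.values[:, keep], bm.probe_ids, kept_ids, bm.platform[keep]),
        ClusterAssignment(kept_ids, lab.to_numpy(dtype=object)[keep],
                          min_pts=ca.min_pts, eps=ca.eps),
    )


def stability_downsample(bm: BetaMatrix, reference_emb: Embedding,
                         n_iterations: int = 300, fraction: float = 0.8,
                         seed: int = 42, perplexity: float | None = None,
                         n_iter: int | None = None) -> StabilityReport:
    """Downsampling stability of a reference t-SNE embedding.

    Per iteration: draw ``floor(fraction * n)`` samples without
    replacement, re-embed them with t-SNE warm-started at their reference
    coordinates, and compute one Pearson r between the concatenated
    (x, y) reference coordinates and the concatenated re-embedded
    coordinates of the retained samples.

    `perplexity` / `n_iter` default to the reference embedding's
    parameters.
    """
    if not (0 < fraction <= 1):
        raise ValueError(f"fraction must lie in (0, 1], got {fraction}")
    ids = list(reference_emb.sample_ids)
    if set(bm.sample_ids) - set(ids):
        raise ValueError("reference embedding does not cover all samples")
    perplexity = perplexity if perplexity is not None else reference_emb.params.get("perplexity", 20)
    n_iter = n_iter if n_iter is not None else reference_emb.params.get("iterations", 4000)
    ref = reference_emb.to_frame().loc[bm.sample_ids].to_numpy()
    n = bm.n_samples
    m = int(np.floor(fraction * n))
    rng = np.random.default_rng(seed)
    rs = []
    for it in range(n_iterations):
        idx = np.sort(rng.choice(n, size=m, replace=False))
        sub_X = bm.X[idx]
        init = ref[idx].copy()
        it_seed = int(rng.integers(0, 2**31 - 1))
        coords = TSNEEmbedder(perplexity=perplexity, n_iter=n_iter,
                              random_state=it_seed, init=init).fit_transform(sub_X)
        r, _ = pearsonr(ref[idx].ravel(order="F"), coords.ravel(order="F"))
        rs.append(r)
    return StabilityReport(np.asarray(rs), fraction=fraction)
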