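"""Synthetic methylation-cohort simulator.

Generates beta-value cohorts with planted tumor classes so every pipeline
stage — probe filtering, platform merging, discovery, classification,
outlier detection, evaluation — is exercisable without any external data.

The noise model is a Beta distribution around class-specific mean
profiles: a probe with mean mu for a sample is drawn as
``Beta(mu * nu, (1 - mu) * nu)`` with concentration ``nu``
(``noise_precision``), the standard methylation noise model that keeps
values in [0, 1] by construction.  Background (uninformative) probe means
are a 50/50 mixture of low-methylated ``Beta(2, 10)`` and
high-methylated ``Beta(10, 2)`` archetypes — the bimodal marginal shape
of real array data.  Each class perturbs its own set of informative CpGs
by flipping their methylation state on the logit scale (a shift of
``effect`` at the scale midpoint, squashed by the logistic so means stay
inside (0, 1) without clipping).  Tumor purity dilutes every tumor
profile toward a shared normal profile before sampling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .data import BetaMatrix, ProbeManifest, SampleSheet, VALID_CHROMOSOMES

__all__ = ["SimConfig", "GroundTruth", "SimulatedSplit", "simulate_cohort",
           "simulate_split", "platform_views"]


@dataclass
class SimConfig:
    """Configuration of a synthetic methylation cohort.

    Attributes
    ----------
    n_classes : int
        Number of planted tumor classes (the "sinonasal-analog" classes).
    samples_per_class : int or sequence of int
        Reference cohort size per class.
    n_probes : int
        Total CpG probes on the synthetic array.
    n_informative : int
        Differentially methylated CpGs per class (disjoint across classes
        unless ``informative_overlap > 0``).
    effect : float
        Mean beta shift of informative probes at the scale midpoint,
        toward the opposite methylation state (hyper for low-methylated
        background probes, hypo for high-methylated ones).
    noise_precision : float
        Concentration nu of the per-value Beta jitter; larger = tighter.
    purity_range : (float, float)
        Per-sample tumor fraction, uniform over this range; the tumor
        mean profile is mixed with the shared normal profile.
    n_outlier_classes, outlier_pool_size, outlier_test_size : int
        Out-of-scope tumor classes (one coarse category each) used for
        the Unknown pool and the non-sinonasal test set; pool/test sizes
        are per class.
    n_unseen_outlier_classes : int
        Outlier classes present only in the test partition (never in the
        Unknown pool) — the "unseen diagnosis" condition.
    test_per_class : int
        Held-out in-scope test samples per planted class.
    platform_split : float
        Fraction of samples tagged EPIC (rest 450k).
    platform_probe_drop : float
        Fraction of probes private to each platform (exercises merging).
    flagged_fraction : float
        Fraction of probes flagged sex-chromosomal, SNP-associated and
        cross-reactive, respectively (exercises probe filtering).
    informative_overlap : float
        Fraction of each class's informative set shared with the next
        class (0 = clean planted structure).
    seed : int
        Base seed; identical configs produce identical cohorts.
    """

    n_classes: int = 5
    samples_per_class: int | tuple = 40
    n_probes: int = 30000
    n_informative: int = 300
    effect: float = 0.45
    noise_precision: float = 50.0
    purity_range: tuple = (0.3, 1.0)
    n_outlier_classes: int = 4
    outlier_pool_size: int = 500
    outlier_test_size: int = 25
    n_unseen_outlier_classes: int = 2
    test_per_class: int = 10
    platform_split: float = 0.5
    platform_probe_drop: float = 0.05
    flagged_fraction: float = 0.02
    informative_overlap: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        sizes = self.class_sizes
        if self.n_classes < 1 or any(s < 1 for s in sizes):
            raise ValueError("class counts and sizes must be positive")
        if not (0 < self.effect < 1):
            raise ValueError("effect must lie in (0, 1)")
        lo, hi = self.purity_range
        if not (0 <= lo <= hi <= 1):
            raise ValueError("purity_range must satisfy 0 <= lo <= hi <= 1")
        if self.n_probes < self.n_classes * self.n_informative:
            raise ValueError("not enough probes for disjoint informative sets")

    @property
    def class_sizes(self) -> list[int]:
        if np.isscalar(self.samples_per_class):
            return [int(self.samples_per_class)] * self.n_classes
        sizes = list(self.samples_per_class)
        if len(sizes) != self.n_classes:
            raise ValueError("samples_per_class length must equal n_classes")
        return sizes


@dataclass
class GroundTruth:
    """Planted truth of a simulated cohort."""

    labels: pd.Series                 # sample_id -> true class
    informative: dict                 # class -> ndarray of probe ids
    purity: pd.Series                 # sample_id -> tumor fraction
    class_means: pd.DataFrame = field(repr=False, default=None)  # probes x classes


def _logit_shift(mu: np.ndarray, effect: float, direction: np.ndarray) -> np.ndarray:
    """Shift probe means on the logit scale toward the opposite state.

    The step size is the logit distance between 0.5 - effect/2 and
    0.5 + effect/2, i.e. a beta shift of exactly `effect` at the scale
    midpoint; the logistic squash keeps extremes inside (0, 1).
    """
    delta = logit(0.5 + effect / 2) - logit(0.5 - effect / 2)
    return expit(logit(mu) + direction * delta)


def _sample_beta(rng: np.random.Generator, mean: np.ndarray, nu: float) -> np.ndarray:
    mean = np.clip(mean, 1e-4, 1 - 1e-4)
    return np.clip(rng.beta(mean * nu, (1 - mean) * nu), 0.0, 1.0)


class _CohortBuilder:
    """Shared machinery for :func:`simulate_cohort` and :func:`simulate_split`."""

    def __init__(self, cfg: SimConfig):
        self.cfg = cfg
        self.rng = np.random.default_rng(cfg.seed)
        self.probe_ids = np.array([f"cg{i:08d}" for i in range(cfg.n_probes)], dtype=object)
        # background: bimodal mixture of methylation archetypes
        low = self.rng.beta(2, 10, size=cfg.n_probes)
        high = self.rng.beta(10, 2, size=cfg.n_probes)
        is_high = self.rng.random(cfg.n_probes) < 0.5
        self.normal_mean = np.where(is_high, high, low)
        self._free = list(self.rng.permutation(cfg.n_probes))
        self.informative: dict[str, np.ndarray] = {}
        self.class_means: dict[str, np.ndarray] = {}
        self._prev_class: str | None = None

    def add_class(self, name: str) -> None:
        cfg = self.cfg
        n_shared = 0
        shared: list[int] = []
        if cfg.informative_overlap > 0 and self._prev_class is not None:
            n_shared = int(round(cfg.informative_overlap * cfg.n_informative))
            prev = self.informative[self._prev_class]
            pos = pd.Index(self.probe_ids).get_indexer(prev[:n_shared])
            shared = list(pos)
        own = [self._free.pop() for _ in range(cfg.n_informative - n_shared)]
        idx = np.array(shared + own, dtype=int)
        direction = np.where(self.normal_mean[idx] < 0.5, 1.0, -1.0)
        mean = self.normal_mean.copy()
        mean[idx] = _logit_shift(mean[idx], cfg.effect, direction)
        self.informative[name] = self.probe_ids[idx]
        self.class_means[name] = mean
        self._prev_class = name

    def draw_samples(self, name: str, n: int, prefix: str):
        cfg = self.cfg
        lo, hi = cfg.purity_range
        purity = self.rng.uniform(lo, hi, size=n)
        mu = self.class_means[name]
        cols, ids = [], []
        for j in range(n):
            m = purity[j] * mu + (1 - purity[j]) * self.normal_mean
            cols.append(_sample_beta(self.rng, m, cfg.noise_precision))
            ids.append(f"{prefix}_{name}_{j:03d}")
        return np.column_stack(cols), np.array(ids, dtype=object), purity

    def manifest(self) -> ProbeManifest:
        cfg = self.cfg
        p = cfg.n_probes
        chrom = np.array([VALID_CHROMOSOMES[i % 22] for i in range(p)], dtype=object)
        n_flag = int(round(cfg.flagged_fraction * p))
        flat = self.rng.permutation(p)
        sex = flat[:n_flag]
        snp = flat[n_flag:2 * n_flag]
        cross = flat[2 * n_flag:3 * n_flag]
        chrom[sex] = np.where(self.rng.random(len(sex)) < 0.5, "chrX", "chrY")
        snp_flag = np.zeros(p, dtype=int)
        snp_flag[snp] = 1
        cross_flag = np.zeros(p, dtype=int)
        cross_flag[cross] = 1
        table = pd.DataFrame(
            {
                "chromosome": chrom,
                "position": np.arange(1, p + 1) * 1000,
                "snp_flag": snp_flag,
                "cross_reactive_flag": cross_flag,
            },
            index=pd.Index(self.probe_ids, name="probe_id"),
        )
        return ProbeManifest(table)

    def platforms(self, n: int) -> np.ndarray:
        tags = np.where(self.rng.random(n) < self.cfg.platform_split, "EPIC", "450k")
        return tags.astype(object)


def simulate_cohort(cfg: SimConfig | None = None):
    """Simulate a single reference-style cohort.

    Returns ``(BetaMatrix, SampleSheet, ProbeManifest, GroundTruth)``
    with ``cfg.n_classes`` planted classes and ``cfg.class_sizes``
    samples per class, all tagged cohort="reference".
    """
    cfg = cfg or SimConfig()
    b = _CohortBuilder(cfg)
    blocks, ids, labels, purities = [], [], [], []
    for c, size in enumerate(cfg.class_sizes, start=1):
        name = f"class_{c}"
        b.add_class(name)
        vals, sids, pur = b.draw_samples(name, size, "ref")
        blocks.append(vals)
        ids.append(sids)
        labels += [name] * size
        purities.append(pur)
    values = np.hstack(blocks)
    sample_ids = np.concatenate(ids)
    platform = b.platforms(len(sample_ids))
    bm = BetaMatrix(values, b.probe_ids, sample_ids, platform)
    sheet = SampleSheet(pd.DataFrame(
        {"label": labels, "cohort": "reference", "category": "sinonasal",
         "platform": platform},
        index=pd.Index(sample_ids, name="sample_id")))
    truth = GroundTruth(
        labels=pd.Series(labels, index=sample_ids, name="true_class"),
        informative=b.informative,
        purity=pd.Series(np.concatenate(purities), index=sample_ids, name="purity"),
        class_means=pd.DataFrame(b.class_means, index=b.probe_ids),
    )
    return bm, sheet, b.manifest(), truth


@dataclass
class SimulatedSplit:
    """A full train/test study design on one synthetic array.

    One BetaMatrix holds every sample; the sheet's ``cohort`` column
    partitions them into reference (planted in-scope classes),
    unknown_pool (out-of-scope tumors eligible for Unknown training) and
    test (held-out in-scope samples plus *all* outlier categories,
    including categories never seen in the pool).
    """

    bm: BetaMatrix
    sheet: SampleSheet
    manifest: ProbeManifest
    truth: GroundTruth
    seen_categories: list[str]
    unseen_categories: list[str]

    def part(self, cohort: str):
        ids = self.sheet.table.index[self.sheet.table["cohort"] == cohort]
        return self.bm.subset_samples(ids), self.sheet.subset(ids)


def simulate_split(cfg: SimConfig | None = None) -> SimulatedSplit:
    """Simulate reference + Unknown-pool + test partitions.

    Outlier classes are split into seen categories (contributing both to
    the Unknown pool and the test set) and
    ``cfg.n_unseen_outlier_classes`` unseen categories present only in
    the test partition.
    """
    cfg = cfg or SimConfig()
    if cfg.n_unseen_outlier_classes >= cfg.n_outlier_classes:
        raise ValueError("need at least one outlier class in the Unknown pool")
    b = _CohortBuilder(cfg)
    if cfg.n_probes < (cfg.n_classes + cfg.n_outlier_classes) * cfg.n_informative:
        raise ValueError("not enough probes for disjoint informative sets")

    blocks, ids, rows, purities = [], [], [], []

    def emit(name, n, prefix, label, cohort, category):
        vals, sids, pur = b.draw_samples(name, n, prefix)
        blocks.append(vals)
        ids.append(sids)
        purities.append(pur)
        for s in sids:
            rows.append((s, label, cohort, category))

    for c in range(1, cfg.n_classes + 1):
        name = f"class_{c}"
        b.add_class(name)
        emit(name, cfg.class_sizes[c - 1], "ref", name, "reference", "sinonasal")
        emit(name, cfg.test_per_class, "test", name, "test", "sinonasal")

    n_seen = cfg.n_outlier_classes - cfg.n_unseen_outlier_classes
    seen_cats, unseen_cats = [], []
    for o in range(1, cfg.n_outlier_classes + 1):
        name = f"outlier_{o}"
        cat = f"category_{o}"
        b.add_class(name)
        if o <= n_seen:
            seen_cats.append(cat)
            emit(name, cfg.outlier_pool_size, "pool", cat, "unknown_pool", cat)
        else:
            unseen_cats.append(cat)
        emit(name, cfg.outlier_test_size, "otest", cat, "test", cat)

    values = np.hstack(blocks)
    sample_ids = np.concatenate(ids)
    platform = b.platforms(len(sample_ids))
    bm = BetaMatrix(values, b.probe_ids, sample_ids, platform)
    df = pd.DataFrame(rows, columns=["sample_id", "label", "cohort", "category"]
                      ).set_index("sample_id")
    df["platform"] = platform
    sheet = SampleSheet(df)
    true_class = np.array([s.split("_", 1)[1].rsplit("_", 1)[0] for s in sample_ids],
                          dtype=object)
    truth = GroundTruth(
        labels=pd.Series(true_class, index=sample_ids, name="true_class"),
        informative=b.informative,
        purity=pd.Series(np.concatenate(purities), index=sample_ids, name="purity"),
        class_means=pd.DataFrame(b.class_means, index=b.probe_ids),
    )
    return SimulatedSplit(bm, sheet, b.manifest(), truth, seen_cats, unseen_cats)


def platform_views(bm: BetaMatrix, drop_fraction: float = 0.05, seed: int = 0):
    """Split a tagged cohort into per-platform matrices with partially
    disjoint probe sets (each platform loses a private random
    `drop_fraction` of probes), emulating 450k/EPIC probe-set differences
    ahead of :func:`methylclass.data.merge_platforms`."""
    rng = np.random.default_rng(seed)
    p = bm.n_probes
    n_drop = int(round(drop_fraction * p))
    perm = rng.permutation(p)
    drop_a, drop_b = set(perm[:n_drop]), set(perm[n_drop:2 * n_drop])
    keep_a = [i for i in range(p) if i not in drop_a]
    keep_b = [i for i in range(p) if i not in drop_b]
    mask_a = bm.platform == "450k"
    a = BetaMatrix(bm.values[np.ix_(keep_a, np.where(mask_a)[0])],
                   bm.probe_ids[keep_a], bm.sample_ids[mask_a], bm.platform[mask_a])
    mask_b = ~mask_a
    b = BetaMatrix(bm.values[np.ix_(keep_b, np.where(mask_b)[0])],
                   bm.probe_ids[keep_b], bm.sample_ids[mask_b], bm.platform[mask_b])
    return a, b
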