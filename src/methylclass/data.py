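"""Core data containers and I/O for methylation beta matrices.

The universal currency of the pipeline is the :class:`BetaMatrix`: a
probes x samples matrix of beta values (per-CpG methylation fractions in
[0, 1]) with probe/sample identifiers and a per-sample platform tag
(450k, EPIC or synthetic).  Companion objects are the
:class:`ProbeManifest` (chromosome, position and quality flags per probe)
and the :class:`SampleSheet` (label, cohort and coarse category per
sample).

The toolkit's contract starts at beta values: raw IDAT decoding and
normalization are delegated upstream.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

VALID_PLATFORMS = ("450k", "EPIC", "synthetic")
VALID_CHROMOSOMES = tuple(f"chr{i}" for i in range(1, 23)) + ("chrX", "chrY")
VALID_COHORTS = ("reference", "unknown_pool", "test")

__all__ = [
    "BetaMatrix",
    "ProbeManifest",
    "SampleSheet",
    "QCConfig",
    "load_beta_matrix",
    "read_beta_matrix",
    "write_beta_matrix",
    "read_manifest",
    "write_manifest",
    "read_sample_sheet",
    "write_sample_sheet",
    "filter_probes",
    "qc_filter_samples",
    "merge_platforms",
]


def _check_unique(ids: np.ndarray, what: str) -> None:
    if len(np.unique(ids)) != len(ids):
        seen, dupes = set(), []
        for i in ids:
            if i in seen:
                dupes.append(i)
            seen.add(i)
        raise ValueError(f"duplicate {what} ids: {dupes[:5]}")


@dataclass
class BetaMatrix:
    """Probes x samples matrix of beta values in [0, 1].

    Parameters
    ----------
    values : ndarray of shape (n_probes, n_samples)
        Beta values; must be finite and within [0, 1].
    probe_ids, sample_ids : sequences of str
        Unique row/column identifiers.
    platform : sequence of str, one per sample
        Each from ``{"450k", "EPIC", "synthetic"}``.
    """

    values: np.ndarray
    probe_ids: np.ndarray
    sample_ids: np.ndarray
    platform: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.probe_ids = np.asarray(self.probe_ids, dtype=object)
        self.sample_ids = np.asarray(self.sample_ids, dtype=object)
        self.platform = np.asarray(self.platform, dtype=object)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (probes x samples)")
        if self.values.shape != (len(self.probe_ids), len(self.sample_ids)):
            raise ValueError(
                f"shape {self.values.shape} inconsistent with "
                f"{len(self.probe_ids)} probes x {len(self.sample_ids)} samples"
            )
        if len(self.platform) != len(self.sample_ids):
            raise ValueError("one platform tag per sample required")
        if self.values.size and not np.all(np.isfinite(self.values)):
            raise ValueError("beta values must be finite")
        if self.values.size and (self.values.min() < 0 or self.values.max() > 1):
            raise ValueError(
                "beta out of range: values must lie in [0, 1] "
                f"(observed range [{self.values.min():.4g}, {self.values.max():.4g}])"
            )
        _check_unique(self.probe_ids, "probe")
        _check_unique(self.sample_ids, "sample")
        bad = set(self.platform) - set(VALID_PLATFORMS)
        if bad:
            raise ValueError(f"unknown platform tags {sorted(bad)}; allowed {VALID_PLATFORMS}")

    # -- basic views ------------------------------------------------------
    @property
    def n_probes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def X(self) -> np.ndarray:
        """Samples x probes view for scikit-learn style estimators."""
        return self.values.T

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.probe_ids, columns=self.sample_ids)

    # -- subsetting -------------------------------------------------------
    def subset_probes(self, probe_ids) -> "BetaMatrix":
        """Restrict to `probe_ids`, in the given order."""
        idx = pd.Index(self.probe_ids)
        pos = idx.get_indexer(list(probe_ids))
        if (pos < 0).any():
            missing = [p for p, q in zip(probe_ids, pos) if q < 0]
            raise KeyError(f"probes not in matrix: {missing[:10]}")
        return BetaMatrix(self.values[pos], np.asarray(list(probe_ids), dtype=object),
                          self.sample_ids.copy(), self.platform.copy())

    def subset_samples(self, sample_ids) -> "BetaMatrix":
        idx = pd.Index(self.sample_ids)
        pos = idx.get_indexer(list(sample_ids))
        if (pos < 0).any():
            missing = [s for s, q in zip(sample_ids, pos) if q < 0]
            raise KeyError(f"samples not in matrix: {missing[:10]}")
        return BetaMatrix(self.values[:, pos], self.probe_ids.copy(),
                          np.asarray(list(sample_ids), dtype=object), self.platform[pos])


@dataclass
class ProbeManifest:
    """Per-probe annotation: chromosome, position and quality flags."""

    table: pd.DataFrame  # index probe_id; columns chromosome, position, snp_flag, cross_reactive_flag

    def __post_init__(self) -> None:
        required = {"chromosome", "position", "snp_flag", "cross_reactive_flag"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"manifest missing columns {sorted(missing)}")
        if self.table.index.has_duplicates:
            raise ValueError("duplicate probe ids in manifest")
        bad = set(self.table["chromosome"]) - set(VALID_CHROMOSOMES)
        if bad:
            raise ValueError(f"invalid chromosomes {sorted(bad)[:5]}")
        if (self.table["position"] < 0).any():
            raise ValueError("positions must be non-negative")
        self.table = self.table.assign(
            snp_flag=self.table["snp_flag"].astype(bool),
            cross_reactive_flag=self.table["cross_reactive_flag"].astype(bool),
        )

    @property
    def probe_ids(self) -> np.ndarray:
        return self.table.index.to_numpy(dtype=object)


@dataclass
class SampleSheet:
    """Per-sample metadata: label, cohort and coarse category."""

    table: pd.DataFrame  # index sample_id; columns label, cohort, category [, platform]

    def __post_init__(self) -> None:
        required = {"label", "cohort", "category"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"sample sheet missing columns {sorted(missing)}")
        if self.table.index.has_duplicates:
            raise ValueError("duplicate sample ids in sample sheet")
        bad = set(self.table["cohort"]) - set(VALID_COHORTS)
        if bad:
            raise ValueError(f"invalid cohort values {sorted(bad)}; allowed {VALID_COHORTS}")

    @property
    def sample_ids(self) -> np.ndarray:
        return self.table.index.to_numpy(dtype=object)

    def subset(self, sample_ids) -> "SampleSheet":
        return SampleSheet(self.table.loc[list(sample_ids)].copy())


@dataclass
class QCConfig:
    """Sample-level detection-p QC: drop a sample when the fraction of
    probes with detection p >= `detection_p_threshold` exceeds
    `sample_fail_fraction` (the wateRmelon pfilter perc=5 rule)."""

    sample_fail_fraction: float = 0.05
    detection_p_threshold: float = 0.05

    def __post_init__(self) -> None:
        for name in ("sample_fail_fraction", "detection_p_threshold"):
            v = getattr(self, name)
            if not (0 < v < 1):
                raise ValueError(f"{name} must lie in (0, 1), got {v}")


# ---------------------------------------------------------------------------
# I/O: delimited text (TSV/CSV); probes as rows by convention


def _sep_for(path: Path) -> str:
    return "," if Path(path).suffix.lower() == ".csv" else "\t"


def read_beta_matrix(path, platform=None, orientation: str = "probes_as_rows") -> BetaMatrix:
    """Read a beta matrix from delimited text.

    Header row names samples, first column names probes (the public
    methylation-matrix convention); set ``orientation="samples_as_rows"``
    for transposed input.  ``platform`` is either a single tag applied to
    all samples or a per-sample sequence; defaults to "450k".
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path), index_col=0)
    if orientation == "samples_as_rows":
        df = df.T
    elif orientation != "probes_as_rows":
        raise ValueError(f"unknown orientation {orientation!r}")
    values = df.to_numpy(dtype=float)
    if platform is None:
        platform = "450k"
    if isinstance(platform, str):
        platform = [platform] * df.shape[1]
    return BetaMatrix(values, df.index.to_numpy(dtype=object),
                      df.columns.to_numpy(dtype=object), np.asarray(platform, dtype=object))


def write_beta_matrix(bm: BetaMatrix, path) -> None:
    path = Path(path)
    bm.to_frame().to_csv(path, sep=_sep_for(path), index_label="probe_id",
                         float_format="%.17g")


def read_manifest(path) -> ProbeManifest:
    """Read a probe manifest TSV with columns probe_id, chromosome,
    position, snp_flag, cross_reactive_flag (flags 0/1)."""
    df = pd.read_csv(path, sep=_sep_for(Path(path)), index_col="probe_id")
    return ProbeManifest(df)


def write_manifest(man: ProbeManifest, path) -> None:
    out = man.table.copy()
    out["snp_flag"] = out["snp_flag"].astype(int)
    out["cross_reactive_flag"] = out["cross_reactive_flag"].astype(int)
    out.to_csv(path, sep=_sep_for(Path(path)), index_label="probe_id")


def read_sample_sheet(path) -> SampleSheet:
    df = pd.read_csv(path, sep=_sep_for(Path(path)), index_col="sample_id")
    return SampleSheet(df)


def write_sample_sheet(sheet: SampleSheet, path) -> None:
    sheet.table.to_csv(path, sep=_sep_for(Path(path)), index_label="sample_id")


def load_beta_matrix(path, manifest_path, sheet_path):
    """Load and cross-validate a beta matrix, manifest and sample sheet.

    Returns ``(BetaMatrix, ProbeManifest, SampleSheet)``.  Every sample in
    the sheet must be present in the matrix; out-of-range beta values are
    an error, never silently clipped.  If the sheet has a ``platform``
    column it supplies per-sample platform tags.
    """
    sheet = read_sample_sheet(sheet_path)
    man = read_manifest(manifest_path)
    bm = read_beta_matrix(path)
    if "platform" in sheet.table.columns:
        plat = sheet.table["platform"].reindex(bm.sample_ids)
        if plat.notna().all():
            bm = BetaMatrix(bm.values, bm.probe_ids, bm.sample_ids,
                            plat.to_numpy(dtype=object))
    missing = set(sheet.sample_ids) - set(bm.sample_ids)
    if missing:
        raise ValueError(f"samples in sheet missing from matrix: {sorted(missing)[:10]}")
    return bm, man, sheet


# ---------------------------------------------------------------------------
# Filtering and merging


def filter_probes(bm: BetaMatrix, man: ProbeManifest) -> BetaMatrix:
    """Drop probes on sex chromosomes, SNP-associated probes and probes
    with reported cross-reactivity; input probe order is preserved."""
    missing = set(bm.probe_ids) - set(man.probe_ids)
    if missing:
        raise ValueError(f"probes missing from manifest: {sorted(missing)[:10]}")
    ann = man.table.loc[list(bm.probe_ids)]
    drop = (
        ann["chromosome"].isin(["chrX", "chrY"])
        | ann["snp_flag"]
        | ann["cross_reactive_flag"]
    ).to_numpy()
    keep = ~drop
    if not keep.any():
        warnings.warn("all probes removed by filtering", stacklevel=2)
    return BetaMatrix(bm.values[keep], bm.probe_ids[keep], bm.sample_ids.copy(),
                      bm.platform.copy())


def qc_filter_samples(bm: BetaMatrix, detection_p: np.ndarray,
                      cfg: QCConfig | None = None) -> BetaMatrix:
    """Remove samples whose fraction of failing probes (detection
    p >= threshold) strictly exceeds ``sample_fail_fraction``."""
    cfg = cfg or QCConfig()
    detection_p = np.asarray(detection_p, dtype=float)
    if detection_p.shape != bm.values.shape:
        raise ValueError(
            f"detection_p shape {detection_p.shape} != matrix shape {bm.values.shape}"
        )
    fail_frac = (detection_p >= cfg.detection_p_threshold).mean(axis=0)
    keep = fail_frac <= cfg.sample_fail_fraction  # strict removal rule
    return BetaMatrix(bm.values[:, keep], bm.probe_ids.copy(),
                      bm.sample_ids[keep], bm.platform[keep])


def merge_platforms(a: BetaMatrix, b: BetaMatrix) -> BetaMatrix:
    """Merge two (probe-filtered) matrices on their shared probes.

    The result keeps the probe order of `a` restricted to the
    intersection; samples are concatenated with platform tags preserved.
    """
    dup = set(a.sample_ids) & set(b.sample_ids)
    if dup:
        raise ValueError(f"duplicate sample ids across inputs: {sorted(dup)[:10]}")
    shared = [p for p in a.probe_ids if p in set(b.probe_ids)]
    if not shared:
        raise ValueError("empty probe intersection; matrices cannot be merged")
    a_sub = a.subset_probes(shared)
    b_sub = b.subset_probes(shared)
    return BetaMatrix(
        np.hstack([a_sub.values, b_sub.values]),
        np.asarray(shared, dtype=object),
        np.concatenate([a.sample_ids, b.sample_ids]),
        np.concatenate([a.platform, b.platform]),
    )
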