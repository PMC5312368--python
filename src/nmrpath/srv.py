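"""Statistical recoupling of variables (SRV).

High-resolution 0.001-ppm buckets belonging to the same NMR peak are highly
correlated across samples; buckets from noise regions are not. SRV exploits
this to merge consecutive buckets into peak-coherent clusters that become
the variables for all downstream multivariate and correlation analyses.

The rule implemented here is the run-merging form: compute the "coupling
landscape" (Pearson correlation across samples between each pair of
consecutive buckets), take maximal runs of boundaries at or above a
threshold, and keep runs at least as long as a minimum cluster length
derived from the singlet size (default 0.01 ppm at 0.001-ppm resolution,
i.e. 10 buckets). Cluster intensity is the sum of member buckets, which
preserves the integral semantics of total-sum normalization. The threshold
may be calibrated as the 95th percentile of boundary correlations inside a
declared noise region.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ArgumentError, InsufficientDataError
from .preprocess import SpectrumMatrix

__all__ = [
    "SrvParams",
    "Cluster",
    "ClusterSet",
    "ClusterMatrix",
    "coupling_landscape",
    "calibrate_threshold",
    "build_clusters",
    "summarize_clusters",
    "coverage_fraction",
]


@dataclass
class SrvParams:
    singlet_size: float = 0.01  # ppm; peak base width of a resolved weak singlet
    resolution: float = 0.001  # ppm per bucket
    landscape_threshold: float = 0.8
    noise_region: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.singlet_size < self.resolution:
            raise ArgumentError("singlet_size must be >= resolution")
        if not 0.0 < self.landscape_threshold < 1.0:
            raise ArgumentError("landscape_threshold must lie in (0, 1)")

    @property
    def min_cluster_len(self) -> int:
        return max(1, round(self.singlet_size / self.resolution))


@dataclass(frozen=True)
class Cluster:
    start: int  # bucket index, inclusive
    end: int  # bucket index, inclusive
    ppm_lo: float
    ppm_hi: float

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def ppm_center(self) -> float:
        return 0.5 * (self.ppm_lo + self.ppm_hi)


@dataclass
class ClusterSet:
    """Ordered, non-overlapping contiguous bucket runs on a common axis."""

    clusters: list[Cluster]
    ppm: np.ndarray = field(repr=False, default=None)

    def __post_init__(self) -> None:
        for a, b in zip(self.clusters, self.clusters[1:]):
            if b.start <= a.end:
                raise ArgumentError("clusters overlap or are unsorted")

    def __len__(self) -> int:
        return len(self.clusters)

    def __iter__(self):
        return iter(self.clusters)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cluster": [f"c{i + 1:04d}" for i in range(len(self.clusters))],
                "ppm_lo": [c.ppm_lo for c in self.clusters],
                "ppm_hi": [c.ppm_hi for c in self.clusters],
                "n_buckets": [c.length for c in self.clusters],
            }
        )


@dataclass
class ClusterMatrix:
    """Samples x clusters aggregated (summed) intensities."""

    values: np.ndarray
    clusters: ClusterSet
    sample_ids: list[str]
    group_labels: list[str]
    aggregation: str = "sum"

    @property
    def cluster_ids(self) -> list[str]:
        return [f"c{i + 1:04d}" for i in range(len(self.clusters))]

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(self.values, index=self.sample_ids, columns=self.cluster_ids)
        frame.insert(0, "group", self.group_labels)
        return frame


def coupling_landscape(m: SpectrumMatrix) -> np.ndarray:
    """Pearson correlation across samples between each consecutive bucket pair.

    Element i correlates bucket i with bucket i+1. Boundaries touching a
    zero-variance bucket are assigned 0 by convention, which breaks runs.
    """
    if m.n_samples < 3:
        raise InsufficientDataError("coupling landscape needs at least 3 samples")
    if m.n_buckets < 2:
        raise InsufficientDataError("coupling landscape needs at least 2 buckets")
    x = m.intensities - m.intensities.mean(axis=0)
    sd = x.std(axis=0, ddof=1)
    cov = (x[:, :-1] * x[:, 1:]).sum(axis=0) / (m.n_samples - 1)
    denom = sd[:-1] * sd[1:]
    out = np.zeros(m.n_buckets - 1)
    ok = denom > 0
    out[ok] = np.clip(cov[ok] / denom[ok], -1.0, 1.0)
    return out


def calibrate_threshold(
    landscape: np.ndarray, ppm: np.ndarray, noise_region: tuple[float, float], q: float = 95.0
) -> float:
    """Threshold as the q-th percentile of boundary correlations in a noise region."""
    lo, hi = min(noise_region), max(noise_region)
    centers = 0.5 * (ppm[:-1] + ppm[1:])
    sel = (centers >= lo) & (centers <= hi)
    if not sel.any():
        raise ArgumentError(f"noise region [{lo}, {hi}] ppm contains no boundaries")
    return float(np.percentile(landscape[sel], q))


def build_clusters(
    landscape: np.ndarray, params: SrvParams, ppm: np.ndarray
) -> ClusterSet:
    """Maximal runs of boundaries >= threshold, kept if long enough.

    A run of k qualifying boundaries spans k+1 buckets; runs spanning fewer
    buckets than ``params.min_cluster_len`` are discarded.
    """
    thr = params.landscape_threshold
    if params.noise_region is not None:
        thr = max(thr, calibrate_threshold(landscape, ppm, params.noise_region))
    good = landscape >= thr
    clusters: list[Cluster] = []
    i = 0
    nb = len(landscape) + 1
    while i < len(landscape):
        if not good[i]:
            i += 1
            continue
        j = i
        while j < len(landscape) and good[j]:
            j += 1
        start, end = i, j  # buckets start..end inclusive (j boundaries -> j+1 buckets)
        if end - start + 1 >= params.min_cluster_len:
            lo = float(min(ppm[start], ppm[end]))
            hi = float(max(ppm[start], ppm[end]))
            clusters.append(Cluster(start=start, end=end, ppm_lo=lo, ppm_hi=hi))
        i = j + 1
    assert all(c.end < nb for c in clusters)
    return ClusterSet(clusters=clusters, ppm=ppm)


def summarize_clusters(m: SpectrumMatrix, clusters: ClusterSet) -> ClusterMatrix:
    """Aggregate member-bucket intensities (sum) per cluster and sample."""
    if len(clusters) == 0:
        raise ArgumentError("empty cluster set: downstream analyses are undefined")
    if clusters.clusters[-1].end >= m.n_buckets:
        raise ArgumentError("clusters extend beyond the spectral axis")
    cols = [m.intensities[:, c.start : c.end + 1].sum(axis=1) for c in clusters]
    return ClusterMatrix(
        values=np.column_stack(cols),
        clusters=clusters,
        sample_ids=list(m.sample_ids),
        group_labels=list(m.group_labels),
    )


def coverage_fraction(m: SpectrumMatrix, clusters: ClusterSet) -> float:
    """Fraction of total absolute signal captured inside clusters, pooled over samples."""
    total = np.abs(m.intensities).sum()
    if total == 0:
        raise ArgumentError("all-zero matrix: coverage fraction undefined")
    inside = sum(
        np.abs(m.intensities[:, c.start : c.end + 1]).sum() for c in clusters
    )
    return float(inside / total)
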