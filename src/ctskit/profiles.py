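"""Anchor-centred tag-density matrices, average profiles, k-means heatmap
clustering and per-base track aggregation (footprints, conservation,
retained histones).

Densities are normalized to tags per 10 million mapped tags, the unit the
metaplots report. A window of half-width W around an anchor covers
[anchor - W, anchor + W) and is divided into 2W / bin bins.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.signal import find_peaks
from scipy.stats import rankdata

from .genomic_io import ScoreTrack, TagLibrary

NORMALIZATION_TARGET = 1e7  # tags per 10 million


@dataclass
class ProfileMatrix:
    """anchors x bins matrix of normalized tag density."""

    anchors: list[tuple[str, int]]
    window: int  # half-width, bp
    bin: int  # bp
    values: np.ndarray  # (n_anchors, n_bins), tags per 10 million
    library_size: int

    @property
    def n_bins(self) -> int:
        return (2 * self.window) // self.bin

    @property
    def bin_centers(self) -> np.ndarray:
        """Offsets of bin centers relative to the anchor."""
        edges = np.arange(self.n_bins + 1) * self.bin - self.window
        return (edges[:-1] + edges[1:]) / 2

    def raw_counts(self) -> np.ndarray:
        """De-normalized per-bin tag counts (exact integers up to float)."""
        return self.values * (self.library_size / NORMALIZATION_TARGET)


def profile_matrix(
    tags: TagLibrary,
    anchors: Sequence[tuple[str, int]],
    window: int = 5000,
    bin: int = 100,
    library_size: int | None = None,
) -> ProfileMatrix:
    """Count tags per bin per anchor window, normalized to tags/10M.

    ``library_size`` defaults to the library's total tag count. Windows
    truncated at chromosome ends simply collect no tags in out-of-bounds
    bins.
    """
    if (2 * window) % bin != 0:
        raise ValueError("bin must divide 2*window")
    if library_size is None:
        library_size = tags.total
    if library_size <= 0:
        raise ValueError("library_size must be positive")
    n_bins = (2 * window) // bin
    values = np.zeros((len(anchors), n_bins))
    rel_edges = np.arange(n_bins + 1) * bin - window
    for i, (chrom, pos) in enumerate(anchors):
        arr = tags.positions(chrom)
        idx = np.searchsorted(arr, pos + rel_edges)
        values[i] = np.diff(idx)
    values *= NORMALIZATION_TARGET / library_size
    return ProfileMatrix(list(anchors), window, bin, values, library_size)


def average_profile(matrix: ProfileMatrix) -> np.ndarray:
    """Per-bin mean across anchors (normalization by region count)."""
    if matrix.values.shape[0] == 0:
        raise ValueError("empty profile matrix has no average profile")
    return matrix.values.mean(axis=0)


@dataclass
class ClusterResult:
    labels: np.ndarray
    k: int
    seed: int
    objective: float  # final within-cluster sum of squares
    objective_trace: list[float] = field(default_factory=list)


def _normalize_rows(values: np.ndarray, normalization: str) -> np.ndarray:
    if normalization == "linear":
        lo = values.min(axis=1, keepdims=True)
        hi = values.max(axis=1, keepdims=True)
        span = np.where(hi > lo, hi - lo, 1.0)
        return (values - lo) / span
    if normalization == "rank":
        return np.apply_along_axis(rankdata, 1, values)
    raise ValueError(f"unknown normalization {normalization!r}")


def _farthest_point_init(X: np.ndarray, k: int, rng: np.random.Generator):
    centers = [X[rng.integers(len(X))]]
    d2 = np.sum((X - centers[0]) ** 2, axis=1)
    for _ in range(1, k):
        nxt = int(np.argmax(d2))
        centers.append(X[nxt])
        d2 = np.minimum(d2, np.sum((X - centers[-1]) ** 2, axis=1))
    return np.array(centers)


def kmeans_rows(
    matrix: ProfileMatrix | np.ndarray,
    k: int,
    seed: int = 0,
    normalization: str = "linear",
    max_iter: int = 300,
) -> ClusterResult:
    """Deterministic Lloyd k-means over row-normalized profiles.

    "linear" rescales each row min-max to [0, 1]; "rank" replaces each row
    by its within-row ranks. Initialization is farthest-point seeding from
    a seed-determined first center, so identical inputs and seed give
    identical labels; the within-cluster sum-of-squares trace is recorded.
    """
    values = matrix.values if isinstance(matrix, ProfileMatrix) else np.asarray(matrix, float)
    if k < 1:
        raise ValueError("k must be >= 1")
    if values.shape[0] < k:
        raise ValueError("fewer rows than clusters")
    X = _normalize_rows(values, normalization)
    rng = np.random.default_rng(seed)
    centers = _farthest_point_init(X, k, rng)
    labels = np.zeros(len(X), dtype=int)
    trace: list[float] = []
    for _ in range(max_iter):
        d2 = ((X[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
        new_labels = np.argmin(d2, axis=1)
        obj = float(d2[np.arange(len(X)), new_labels].sum())
        trace.append(obj)
        for j in range(k):
            members = X[new_labels == j]
            if len(members):
                centers[j] = members.mean(axis=0)
        if np.array_equal(new_labels, labels) and len(trace) > 1:
            labels = new_labels
            break
        labels = new_labels
    d2 = ((X[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
    objective = float(d2[np.arange(len(X)), labels].sum())
    trace.append(objective)
    return ClusterResult(labels, k, seed, objective, trace)


def track_matrix(
    track: ScoreTrack,
    anchors: Sequence[tuple[str, int]],
    window: int = 150,
    bin: int = 5,
) -> np.ndarray:
    """Per-anchor per-bin mean track value; uncovered bases count as 0."""
    if (2 * window) % bin != 0:
        raise ValueError("bin must divide 2*window")
    n_bins = (2 * window) // bin
    out = np.zeros((len(anchors), n_bins))
    for i, (chrom, pos) in enumerate(anchors):
        per_base = track.values_over(chrom, pos - window, pos + window)
        out[i] = per_base.reshape(n_bins, bin).mean(axis=1)
    return out


def aggregate_track(
    track: ScoreTrack,
    anchors: Sequence[tuple[str, int]],
    window: int = 150,
    bin: int = 5,
) -> np.ndarray:
    """Mean track value per bin across anchors (metaplot vector)."""
    if len(anchors) == 0:
        raise ValueError("no anchors to aggregate over")
    return track_matrix(track, anchors, window, bin).mean(axis=0)


def count_protection_dips(
    profile: np.ndarray, min_prominence: float = 0.3
) -> int:
    """Number of local minima with prominence >= min_prominence.

    A protection footprint appears as a dip in cleavage density; a single
    bound motif leaves one dip, a clustered pair two dips separated by the
    linker.
    """
    profile = np.asarray(profile, dtype=float)
    if len(profile) < 3:
        raise ValueError("profile too short")
    minima, _ = find_peaks(-profile, prominence=min_prominence)
    return int(len(minima))
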