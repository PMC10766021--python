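"""Spatial clustering of tumor cells: the first stage of the score.

Tumor cells (Ki67-positive and Ki67-negative alike) are grouped into
spatial clusters in two steps: average-linkage agglomerative clustering
(Euclidean metric) of a seeded random subset of at most 10,000 cells, cut
at a 300-pixel linkage threshold, followed by nearest-neighbor assignment
of all remaining tumor cells to the cluster of their closest clustered
cell. Nontumor cells never take part.

The threshold is read strictly: clusters merge while their average-linkage
distance is below the threshold, and agglomeration stops at distances at
or above it, so two points exactly 300 px apart stay in separate clusters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree
from sklearn.cluster import AgglomerativeClustering

from .cells_io import CellTable
from .errors import UnscorableSlideError

__all__ = [
    "ClusteringConfig",
    "ClusterAssignment",
    "subsample_cells",
    "agglomerate",
    "assign_remainder",
    "cluster_tumor_cells",
]


@dataclass(frozen=True)
class ClusteringConfig:
    """Tunables of the two-step clustering.

    distance_threshold_px: linkage cut in pixels at x40 (default 300).
    subsample_max: cells entering agglomeration; the rest are
        back-assigned by nearest neighbor (default 10,000).
    seed: subsampling seed, fixed by default for reproducible runs.
    """

    distance_threshold_px: float = 300.0
    subsample_max: int = 10_000
    seed: int = 0


@dataclass
class ClusterAssignment:
    """Partition of tumor cells into spatial clusters.

    ``cluster_ids[i]`` is the cluster of ``points[i]``; ids are contiguous
    0..n_clusters-1 (relabelled by first occurrence) and every cluster is
    non-empty.
    """

    points: np.ndarray
    cluster_ids: np.ndarray
    n_clusters: int
    cell_indices: np.ndarray = field(default=None)  # indices into the tumor subset

    def __post_init__(self) -> None:
        if self.cell_indices is None:
            self.cell_indices = np.arange(len(self.points))

    def cluster_sizes(self) -> np.ndarray:
        return np.bincount(self.cluster_ids, minlength=self.n_clusters)


def _relabel_first_occurrence(labels: np.ndarray) -> tuple[np.ndarray, int]:
    """Map arbitrary labels to contiguous ids in order of first appearance."""
    mapping: dict[int, int] = {}
    out = np.empty(len(labels), dtype=int)
    for i, lab in enumerate(labels):
        if lab not in mapping:
            mapping[lab] = len(mapping)
        out[i] = mapping[lab]
    return out, len(mapping)


def subsample_cells(
    n_cells: int, max_n: int = 10_000, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Seeded uniform subsample of cell indices.

    Returns (subset, remainder) index arrays, both sorted ascending; their
    union is 0..n_cells-1 and they are disjoint. If the table fits within
    ``max_n`` the subset is everything and the remainder empty.
    """
    if max_n <= 0:
        raise ValueError("max_n must be positive")
    if n_cells <= max_n:
        return np.arange(n_cells), np.array([], dtype=int)
    rng = np.random.default_rng(seed)
    subset = np.sort(rng.choice(n_cells, size=max_n, replace=False))
    mask = np.zeros(n_cells, dtype=bool)
    mask[subset] = True
    return subset, np.nonzero(~mask)[0]


def agglomerate(
    points: np.ndarray,
    distance_threshold: float = 300.0,
) -> ClusterAssignment:
    """Average-linkage (UPGMA) agglomerative clustering cut at a threshold.

    Merging proceeds bottom-up while the smallest average inter-cluster
    distance is strictly below ``distance_threshold``; a single point
    yields one cluster.
    """
    points = np.asarray(points, dtype=float).reshape(-1, 2)
    if len(points) == 0:
        raise UnscorableSlideError("cannot cluster an empty point set")
    if distance_threshold <= 0:
        raise ValueError("distance_threshold must be positive")
    if len(points) == 1:
        return ClusterAssignment(points=points, cluster_ids=np.zeros(1, dtype=int), n_clusters=1)
    model = AgglomerativeClustering(
        n_clusters=None,
        distance_threshold=distance_threshold,
        linkage="average",
        metric="euclidean",
    )
    raw = model.fit_predict(points)
    labels, n = _relabel_first_occurrence(raw)
    return ClusterAssignment(points=points, cluster_ids=labels, n_clusters=n)


def assign_remainder(
    remainder: np.ndarray,
    assignment: ClusterAssignment,
) -> np.ndarray:
    """Cluster ids for remainder points by the nearest-neighbor rule.

    Each remainder point takes the cluster of its Euclidean-nearest
    clustered point; exact distance ties resolve to the lowest cluster id.
    """
    remainder = np.asarray(remainder, dtype=float).reshape(-1, 2)
    if len(assignment.points) == 0:
        raise UnscorableSlideError("no clustered points to assign against")
    if len(remainder) == 0:
        return np.array([], dtype=int)
    tree = cKDTree(assignment.points)
    dists, idx = tree.query(remainder)
    out = assignment.cluster_ids[idx].copy()
    for i, (pt, d) in enumerate(zip(remainder, dists)):
        # exact-tie check: all clustered points at the minimal distance
        cand = tree.query_ball_point(pt, r=d * (1 + 1e-12) + 1e-12)
        if len(cand) > 1:
            dd = np.linalg.norm(assignment.points[cand] - pt, axis=1)
            tied = [c for c, dc in zip(cand, dd) if dc == dd.min()]
            out[i] = int(assignment.cluster_ids[tied].min())
    return out


def cluster_tumor_cells(
    cells: CellTable,
    config: ClusteringConfig | None = None,
    seed: int | None = None,
) -> ClusterAssignment:
    """Full two-step clustering of the tumor cells of one slide.

    Restricts to tumor-class cells, subsamples at most ``subsample_max``
    of them for agglomeration, and back-assigns the rest by nearest
    neighbor. Raises :class:`UnscorableSlideError` when the slide has no
    tumor cells.
    """
    config = config or ClusteringConfig()
    if seed is None:
        seed = config.seed
    tumor = cells.tumor_subset()
    if len(tumor) == 0:
        raise UnscorableSlideError(f"slide {cells.slide_id}: no tumor cells")
    pts = tumor.coordinates()
    subset, remainder = subsample_cells(len(pts), config.subsample_max, seed)
    core = agglomerate(pts[subset], config.distance_threshold_px)
    if len(remainder) == 0:
        return ClusterAssignment(
            points=pts,
            cluster_ids=core.cluster_ids,
            n_clusters=core.n_clusters,
            cell_indices=np.arange(len(pts)),
        )
    rem_ids = assign_remainder(pts[remainder], core)
    all_ids = np.empty(len(pts), dtype=int)
    all_ids[subset] = core.cluster_ids
    all_ids[remainder] = rem_ids
    return ClusterAssignment(
        points=pts,
        cluster_ids=all_ids,
        n_clusters=core.n_clusters,
        cell_indices=np.arange(len(pts)),
    )
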