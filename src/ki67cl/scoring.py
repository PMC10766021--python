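"""Colocalization scoring: per-cluster diversity and slide-level scores.

The Ki67CL score of a slide is the unweighted mean, over spatial clusters
of tumor cells, of the binary Shannon entropy (base 2) of the cluster's
Ki67-positive fraction:

    Ki67CL = -(1/C) * sum_i [ p_i log2 p_i + (1 - p_i) log2 (1 - p_i) ]

where p_i is the Ki67-positive fraction of tumor cells in cluster i and C
the number of clusters. The score lies in [0, 1]: 0 when every cluster is
pure (one class only), 1 when every cluster is perfectly balanced. The
AutoKi67 ratio is the conventional automated Ki67 index: the fraction of
Ki67-positive tumor cells among all tumor cells of the invasive region.

Clusters are weighted equally regardless of size, matching the defining
formula; singleton clusters are legal and contribute entropy 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import xlogy

from .cells_io import CellClass, CellTable, RegionSet, RegionSetting, filter_cells_by_region
from .clustering import ClusteringConfig, ClusterAssignment, cluster_tumor_cells
from .errors import UnscorableSlideError

__all__ = [
    "ClusterStats",
    "SlideScore",
    "cluster_entropy",
    "compute_cluster_stats",
    "ki67cl_score",
    "autoki67_ratio",
    "score_slide",
]

_LN2 = np.log(2.0)


@dataclass(frozen=True)
class ClusterStats:
    """Composition of one spatial cluster of tumor cells."""

    cluster_id: int
    n_pos: int
    n_neg: int

    @property
    def p_plus(self) -> float:
        return self.n_pos / (self.n_pos + self.n_neg)

    @property
    def entropy(self) -> float:
        return cluster_entropy(self.p_plus)


@dataclass(frozen=True)
class SlideScore:
    """Slide-level scores under one region setting."""

    slide_id: str
    ki67cl: float
    autoki67: float
    n_clusters: int
    n_tumor_cells: int
    region_setting: RegionSetting | None = None
    seed: int | None = None


def cluster_entropy(p_plus: float) -> float:
    """Binary Shannon entropy (bits) of a positive-cell fraction.

    Uses the convention 0*log2(0) = 0, so pure clusters score exactly 0
    and a balanced cluster scores exactly 1.
    """
    if not 0.0 <= p_plus <= 1.0:
        raise ValueError(f"p_plus outside [0,1]: {p_plus}")
    if p_plus in (0.0, 1.0):
        return 0.0
    if p_plus == 0.5:
        return 1.0
    return float(-(xlogy(p_plus, p_plus) + xlogy(1.0 - p_plus, 1.0 - p_plus)) / _LN2)


def compute_cluster_stats(
    classes: list[CellClass], assignment: ClusterAssignment
) -> list[ClusterStats]:
    """Per-cluster Ki67+/Ki67- counts for clustered tumor cells.

    ``classes`` is aligned with ``assignment.points`` (the tumor subset in
    table order).
    """
    if len(classes) != len(assignment.cluster_ids):
        raise ValueError("classes and cluster ids are not aligned")
    pos = np.array([c is CellClass.TUMOR_POS for c in classes])
    stats = []
    for cid in range(assignment.n_clusters):
        members = assignment.cluster_ids == cid
        n_pos = int(np.count_nonzero(pos & members))
        n_tot = int(np.count_nonzero(members))
        stats.append(ClusterStats(cluster_id=cid, n_pos=n_pos, n_neg=n_tot - n_pos))
    return stats


def ki67cl_score(stats: list[ClusterStats]) -> float:
    """Unweighted mean of per-cluster entropies (the slide-level score)."""
    if not stats:
        raise UnscorableSlideError("no clusters to score")
    return float(np.mean([s.entropy for s in stats]))


def autoki67_ratio(cells: CellTable) -> float:
    """Fraction of Ki67-positive tumor cells among all tumor cells."""
    n_pos = sum(1 for c in cells if c.cell_class is CellClass.TUMOR_POS)
    n_neg = sum(1 for c in cells if c.cell_class is CellClass.TUMOR_NEG)
    if n_pos + n_neg == 0:
        raise UnscorableSlideError(f"slide {cells.slide_id}: no tumor cells")
    return n_pos / (n_pos + n_neg)


def score_slide(
    cells: CellTable,
    regions: RegionSet | None = None,
    setting: RegionSetting | str = RegionSetting.WITH_DCIS,
    clustering: ClusteringConfig | None = None,
    seed: int | None = None,
) -> SlideScore:
    """Compute the Ki67CL score and AutoKi67 ratio of one slide.

    When regions are supplied, the Ki67CL substrate is the cell set under
    ``setting``, while the AutoKi67 ratio always uses the invasive tumor
    region (WITHOUT_DCIS), matching conventional Ki67 scoring practice;
    without regions both use all cells of the table.
    """
    setting = RegionSetting(setting)
    clustering = clustering or ClusteringConfig()
    try:
        if regions is not None and regions.regions:
            scored_cells = filter_cells_by_region(cells, regions, setting)
            auto_cells = filter_cells_by_region(cells, regions, RegionSetting.WITHOUT_DCIS)
        else:
            scored_cells = cells
            auto_cells = cells
        assignment = cluster_tumor_cells(scored_cells, clustering, seed=seed)
        tumor_classes = scored_cells.tumor_subset().classes()
        stats = compute_cluster_stats(tumor_classes, assignment)
        score = ki67cl_score(stats)
        ratio = autoki67_ratio(auto_cells)
    except UnscorableSlideError as exc:
        raise UnscorableSlideError(f"slide {cells.slide_id}: {exc}") from exc
    return SlideScore(
        slide_id=cells.slide_id,
        ki67cl=score,
        autoki67=ratio,
        n_clusters=assignment.n_clusters,
        n_tumor_cells=len(assignment.points),
        region_setting=setting if regions is not None and regions.regions else None,
        seed=seed if seed is not None else clustering.seed,
    )
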