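"""Cell-table and region I/O, region filtering, and detection evaluation.

Cell tables hold classified nucleus centroids (pixel coordinates at x40,
origin top-left) with one of four immunohistochemistry class labels:
Ki67-positive/negative tumor and Ki67-positive/negative nontumor cells.
Regions are tumor / DCIS / normal polygons in the same pixel frame,
exchanged as GeoJSON. Detection evaluation matches predicted centroids to
ground-truth dot annotations by optimal one-to-one assignment within a
fixed pixel radius and derives agreement metrics from the matching.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import cdist
from scipy.stats import spearmanr
from shapely.geometry import Point, Polygon
from shapely.prepared import prep

from .errors import (
    CellFileNotFoundError,
    CoordinateParseError,
    EmptyRegionSetError,
    MissingColumnError,
    UnknownClassLabelError,
)

__all__ = [
    "CellClass",
    "CellRecord",
    "CellTable",
    "Region",
    "RegionSet",
    "RegionSetting",
    "MatchResult",
    "DetectionMetrics",
    "Dialect",
    "read_cells",
    "write_cells",
    "read_regions",
    "write_regions",
    "filter_cells_by_region",
    "match_detections",
    "detection_metrics",
]


class CellClass(str, Enum):
    """The four-class vocabulary of the Ki67 IHC cell classifier."""

    TUMOR_POS = "TUMOR_POS"
    TUMOR_NEG = "TUMOR_NEG"
    NONTUMOR_POS = "NONTUMOR_POS"
    NONTUMOR_NEG = "NONTUMOR_NEG"

    @property
    def is_tumor(self) -> bool:
        return self in (CellClass.TUMOR_POS, CellClass.TUMOR_NEG)

    @property
    def is_positive(self) -> bool:
        return self in (CellClass.TUMOR_POS, CellClass.NONTUMOR_POS)


class RegionSetting(str, Enum):
    """Which region context defines the scoring substrate.

    WITH_DCIS corresponds to whole-slide scoring where in-situ regions are
    retained; WITHOUT_DCIS restricts to the invasive tumor region, as
    conventional Ki67 scoring does.
    """

    WITH_DCIS = "WITH_DCIS"
    WITHOUT_DCIS = "WITHOUT_DCIS"


@dataclass(frozen=True)
class CellRecord:
    """One detected cell: centroid in pixels (x rightward, y downward)."""

    x: float
    y: float
    cell_class: CellClass
    confidence: float | None = None

    def __post_init__(self) -> None:
        if not (math.isfinite(self.x) and math.isfinite(self.y)):
            raise CoordinateParseError(f"non-finite centroid ({self.x}, {self.y})")
        if self.x < 0 or self.y < 0:
            raise CoordinateParseError(f"negative centroid ({self.x}, {self.y})")
        if not isinstance(self.cell_class, CellClass):
            raise UnknownClassLabelError(str(self.cell_class))
        if self.confidence is not None and not (0.0 <= self.confidence <= 1.0):
            raise ValueError(f"confidence outside [0,1]: {self.confidence}")


@dataclass
class CellTable:
    """All classified cells of one slide, in stable (source-file) order."""

    slide_id: str
    cells: list[CellRecord] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.cells)

    def __iter__(self):
        return iter(self.cells)

    def coordinates(self) -> np.ndarray:
        """(n, 2) array of x/y centroids in row order."""
        if not self.cells:
            return np.empty((0, 2), dtype=float)
        return np.array([(c.x, c.y) for c in self.cells], dtype=float)

    def classes(self) -> list[CellClass]:
        return [c.cell_class for c in self.cells]

    def tumor_subset(self) -> "CellTable":
        return CellTable(self.slide_id, [c for c in self.cells if c.cell_class.is_tumor])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "slide_id": self.slide_id,
                "x": [c.x for c in self.cells],
                "y": [c.y for c in self.cells],
                "class": [c.cell_class.value for c in self.cells],
                "confidence": [c.confidence for c in self.cells],
            }
        )


@dataclass(frozen=True)
class Region:
    """One annotated region: exterior ring, optional holes, and a label."""

    polygon: Polygon
    label: str  # TUMOR, DCIS or NORMAL

    def __post_init__(self) -> None:
        if self.label not in ("TUMOR", "DCIS", "NORMAL"):
            raise UnknownClassLabelError(f"region label {self.label!r}")
        if len(self.polygon.exterior.coords) < 4:  # closed ring: >=3 distinct vertices
            raise ValueError("polygon ring needs at least 3 vertices")
        if self.polygon.area == 0:
            raise ValueError("polygon has zero area")


@dataclass
class RegionSet:
    slide_id: str
    regions: list[Region] = field(default_factory=list)

    def by_label(self, label: str) -> list[Polygon]:
        return [r.polygon for r in self.regions if r.label == label]


@dataclass
class MatchResult:
    """One-to-one matching of predicted to ground-truth centroids.

    ``pairs`` holds (prediction index, truth index, distance-in-pixels)
    triples; every matched distance is within the matching radius and no
    index appears twice.
    """

    pairs: list[tuple[int, int, float]]
    unmatched_predictions: list[int]
    unmatched_truths: list[int]

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)


@dataclass
class DetectionMetrics:
    """Detection/classification agreement metrics.

    precision, recall and f1 score the detection task regardless of class
    (a pair within the radius is a true positive). accuracy and kappa score
    class agreement over matched pairs only. spearman correlates per-patch,
    per-class count vectors between prediction and truth. Metrics that are
    undefined (no matched pairs; no patch ids) are NaN, never 0.
    """

    precision: float
    recall: float
    f1: float
    accuracy: float
    kappa: float
    spearman: float


# Default column mapping for delimited cell tables.
DEFAULT_DIALECT = {
    "slide_id": "slide_id",
    "x": "x",
    "y": "y",
    "cell_class": "class",
    "confidence": "confidence",
}

Dialect = dict


def _resolve_sep(path: Path) -> str:
    return "\t" if path.suffix.lower() in (".tsv", ".tab") else ","


def read_cells(path: str | Path, dialect: Dialect | None = None) -> CellTable:
    """Read a delimited cell table (CSV/TSV with header) into a CellTable.

    ``dialect`` maps the canonical field names (slide_id, x, y, cell_class,
    confidence) to the file's column names; omitted keys fall back to the
    default mapping. Unknown class labels are rejected, never coerced.
    """
    path = Path(path)
    if not path.exists():
        raise CellFileNotFoundError(str(path))
    mapping = {**DEFAULT_DIALECT, **(dialect or {})}
    df = pd.read_csv(path, sep=_resolve_sep(path))
    for key in ("x", "y", "cell_class"):
        if mapping[key] not in df.columns:
            raise MissingColumnError(f"column {mapping[key]!r} (for {key}) not in {path.name}")

    slide_col = mapping["slide_id"]
    if slide_col in df.columns and len(df):
        slide_id = str(df[slide_col].iloc[0])
    else:
        slide_id = path.stem

    conf_col = mapping["confidence"]
    has_conf = conf_col in df.columns

    cells: list[CellRecord] = []
    for i, row in enumerate(df.itertuples(index=False)):
        rowd = dict(zip(df.columns, row))
        try:
            x = float(rowd[mapping["x"]])
            y = float(rowd[mapping["y"]])
        except (TypeError, ValueError) as exc:
            raise CoordinateParseError(f"row {i}: {exc}") from exc
        if not (math.isfinite(x) and math.isfinite(y)):
            raise CoordinateParseError(f"row {i}: non-finite coordinate")
        label = str(rowd[mapping["cell_class"]])
        try:
            cls = CellClass(label)
        except ValueError:
            raise UnknownClassLabelError(f"row {i}: {label!r}") from None
        conf = None
        if has_conf and rowd[conf_col] is not None and not pd.isna(rowd[conf_col]):
            conf = float(rowd[conf_col])
        cells.append(CellRecord(x=x, y=y, cell_class=cls, confidence=conf))
    return CellTable(slide_id=slide_id, cells=cells)


def write_cells(table: CellTable, path: str | Path) -> None:
    """Write a CellTable as a delimited file (separator from extension)."""
    path = Path(path)
    table.to_frame().to_csv(path, sep=_resolve_sep(path), index=False)


def _polygon_to_geojson(poly: Polygon) -> dict:
    rings = [list(map(list, poly.exterior.coords))]
    rings += [list(map(list, hole.coords)) for hole in poly.interiors]
    return {"type": "Polygon", "coordinates": rings}


def read_regions(path: str | Path, slide_id: str | None = None) -> RegionSet:
    """Read a GeoJSON FeatureCollection of labelled region polygons."""
    path = Path(path)
    if not path.exists():
        raise CellFileNotFoundError(str(path))
    data = json.loads(path.read_text())
    regions: list[Region] = []
    for feat in data.get("features", []):
        label = feat.get("properties", {}).get("label")
        if label is None:
            raise MissingColumnError("feature missing 'label' property")
        geom = feat["geometry"]
        if geom["type"] != "Polygon":
            raise ValueError(f"unsupported geometry type {geom['type']}")
        rings = geom["coordinates"]
        poly = Polygon(rings[0], holes=rings[1:])
        regions.append(Region(polygon=poly, label=label))
    return RegionSet(slide_id=slide_id or path.stem, regions=regions)


def write_regions(regionset: RegionSet, path: str | Path) -> None:
    features = [
        {
            "type": "Feature",
            "properties": {"label": r.label},
            "geometry": _polygon_to_geojson(r.polygon),
        }
        for r in regionset.regions
    ]
    Path(path).write_text(json.dumps({"type": "FeatureCollection", "features": features}))


def _covered_by_any(polys: list, points: np.ndarray) -> np.ndarray:
    """Boolean mask: point inside or on the boundary of any polygon."""
    mask = np.zeros(len(points), dtype=bool)
    for poly in polys:
        prepared = prep(poly)
        for i, (x, y) in enumerate(points):
            if not mask[i] and prepared.covers(Point(x, y)):
                mask[i] = True
    return mask


def filter_cells_by_region(
    cells: CellTable, regions: RegionSet, setting: RegionSetting | str
) -> CellTable:
    """Restrict a cell table to the region context given by ``setting``.

    WITHOUT_DCIS keeps cells inside TUMOR polygons and outside DCIS polygons
    (the invasive tumor region); WITH_DCIS keeps cells inside TUMOR or DCIS
    polygons. Boundary points count as inside.
    """
    setting = RegionSetting(setting)
    tumor = regions.by_label("TUMOR")
    dcis = regions.by_label("DCIS")
    if setting is RegionSetting.WITHOUT_DCIS and not tumor:
        raise EmptyRegionSetError(
            f"slide {cells.slide_id}: no TUMOR polygons; cannot define the invasive region"
        )
    pts = cells.coordinates()
    if len(pts) == 0:
        return CellTable(cells.slide_id, [])
    in_tumor = _covered_by_any(tumor, pts)
    in_dcis = _covered_by_any(dcis, pts) if dcis else np.zeros(len(pts), dtype=bool)
    if setting is RegionSetting.WITHOUT_DCIS:
        keep = in_tumor & ~in_dcis
    else:
        keep = in_tumor | in_dcis
    return CellTable(cells.slide_id, [c for c, k in zip(cells.cells, keep) if k])


def match_detections(
    predictions: Sequence[tuple[float, float]] | np.ndarray,
    truths: Sequence[tuple[float, float]] | np.ndarray,
    radius: float = 20.0,
) -> MatchResult:
    """Optimally match predicted centroids to ground-truth dots.

    Centroids within ``radius`` pixels of each other may be counted as the
    same cell. The matching is a one-to-one assignment that first maximizes
    the number of pairs within the radius and, among those, minimizes the
    total matched distance (optimal bipartite assignment on the thresholded
    distance matrix), so the result is deterministic.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    preds = np.asarray(predictions, dtype=float).reshape(-1, 2)
    gts = np.asarray(truths, dtype=float).reshape(-1, 2)
    if len(preds) == 0 or len(gts) == 0:
        return MatchResult([], list(range(len(preds))), list(range(len(gts))))

    dist = cdist(preds, gts)
    # A forbidden-pair cost larger than any achievable total of allowed
    # pairs makes the assignment maximize pair count before total distance.
    big = radius * (min(dist.shape) + 1) + 1.0
    cost = np.where(dist <= radius, dist, big)
    rows, cols = linear_sum_assignment(cost)
    pairs = [
        (int(r), int(c), float(dist[r, c]))
        for r, c in zip(rows, cols)
        if dist[r, c] <= radius
    ]
    matched_p = {p for p, _, _ in pairs}
    matched_t = {t for _, t, _ in pairs}
    return MatchResult(
        pairs=pairs,
        unmatched_predictions=[i for i in range(len(preds)) if i not in matched_p],
        unmatched_truths=[j for j in range(len(gts)) if j not in matched_t],
    )


def detection_metrics(
    match: MatchResult,
    pred_classes: Sequence,
    truth_classes: Sequence,
    pred_patches: Sequence | None = None,
    truth_patches: Sequence | None = None,
) -> DetectionMetrics:
    """Agreement metrics for a detection/classification run.

    ``pred_classes``/``truth_classes`` are aligned with the point lists the
    matching was computed from. If per-point patch identifiers are given,
    Spearman rho is computed over the concatenated per-patch, per-class
    count vectors of predictions versus truths; otherwise it is NaN.
    """
    from sklearn.metrics import accuracy_score, cohen_kappa_score

    tp = match.n_pairs
    fp = len(match.unmatched_predictions)
    fn = len(match.unmatched_truths)
    precision = tp / (tp + fp) if tp + fp else float("nan")
    recall = tp / (tp + fn) if tp + fn else float("nan")
    f1 = 2 * tp / (2 * tp + fp + fn) if 2 * tp + fp + fn else float("nan")

    if tp == 0:
        accuracy = kappa = float("nan")
    else:
        y_pred = [pred_classes[p] for p, _, _ in match.pairs]
        y_true = [truth_classes[t] for _, t, _ in match.pairs]
        accuracy = float(accuracy_score(y_true, y_pred))
        if len(set(y_true) | set(y_pred)) < 2:
            kappa = 1.0 if y_true == y_pred else float("nan")
        else:
            kappa = float(cohen_kappa_score(y_true, y_pred))

    spearman = float("nan")
    if pred_patches is not None and truth_patches is not None:
        patches = sorted(set(pred_patches) | set(truth_patches), key=str)
        classes = sorted({str(c) for c in pred_classes} | {str(c) for c in truth_classes})
        def counts(cls_seq, patch_seq):
            vec = []
            for patch in patches:
                for cls in classes:
                    vec.append(
                        sum(
                            1
                            for c, p in zip(cls_seq, patch_seq)
                            if str(c) == cls and p == patch
                        )
                    )
            return vec
        v_pred = counts(pred_classes, pred_patches)
        v_true = counts(truth_classes, truth_patches)
        if len(v_pred) >= 2 and (len(set(v_pred)) > 1 or len(set(v_true)) > 1):
            rho = spearmanr(v_pred, v_true).statistic
            spearman = float(rho)
        elif v_pred == v_true:
            spearman = 1.0

    return DetectionMetrics(
        precision=precision,
        recall=recall,
        f1=f1,
        accuracy=accuracy,
        kappa=kappa,
        spearman=spearman,
    )
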