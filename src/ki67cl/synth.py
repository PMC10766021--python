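"""Synthetic slides, cohorts, and probability maps.

The slide generator emulates the spatial organization a slide-level
colocalization score responds to: tumor cells scattered in Gaussian blobs
on a jittered grid, with a single ``mixing`` dial interpolating between
fully class-segregated blobs (each blob purely Ki67-positive or purely
Ki67-negative) and well-mixed blobs (class drawn independently per cell).
Overall Ki67 positivity is held fixed across the dial, so mixing moves
spatial arrangement only. The cohort generator draws survival times from
a two-group proportional-hazards model tied to the true slide score, for
power and parameter-recovery studies of the validation protocol.

Everything is deterministic under a fixed seed. Generated tables use the
same pixel scale as the 300-px clustering threshold, so defaults interact
the way real slides do.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from shapely.geometry import Polygon, box

from .cells_io import CellClass, CellRecord, CellTable, Region, RegionSet
from .detection import DotSet, ProbabilityMap, dots_to_density
from .survival import SurvivalRecord

__all__ = [
    "SlideSimConfig",
    "CohortSimConfig",
    "simulate_slide",
    "simulate_cohort",
    "simulate_probability_map",
]


@dataclass(frozen=True)
class SlideSimConfig:
    """Spatial point-pattern generator settings (pixels at x40).

    mixing=0 makes each blob single-class (class chosen so the expected
    overall positivity is preserved); mixing=1 assigns every cell's class
    independently. blob_spacing defaults to well above the 300-px
    clustering threshold so blobs map to clusters.
    """

    n_blobs: int = 9
    cells_per_blob: int = 60
    blob_sigma: float = 60.0
    blob_spacing: float = 1500.0
    positivity: float = 0.5
    mixing: float = 1.0
    nontumor_fraction: float = 0.0
    seed: int = 0
    emit_regions: bool = False
    dcis_cells: int = 0

    def __post_init__(self) -> None:
        for name in ("positivity", "mixing", "nontumor_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} outside [0,1]: {v}")
        if self.n_blobs <= 0 or self.cells_per_blob <= 0:
            raise ValueError("counts must be positive")


@dataclass(frozen=True)
class CohortSimConfig:
    """Two-group exponential proportional-hazards cohort settings.

    Defaults emulate a ~10-year breast-cancer-specific-survival follow-up:
    baseline hazard 0.01 events/month (median survival ~69 months in the
    baseline group), light independent censoring, administrative cap at
    120 months.
    """

    n_patients: int = 600
    baseline_hazard: float = 0.01
    hazard_ratio_high: float = 2.0
    score_threshold: float = 0.5
    censoring_rate: float = 0.005
    follow_up_cap: float = 120.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.baseline_hazard <= 0 or self.hazard_ratio_high <= 0:
            raise ValueError("hazard parameters must be positive")
        if self.censoring_rate < 0:
            raise ValueError("censoring_rate must be non-negative")


def _blob_centers(config: SlideSimConfig, rng: np.random.Generator) -> np.ndarray:
    """Blob centers on a jittered square grid with the configured spacing."""
    side = int(np.ceil(np.sqrt(config.n_blobs)))
    centers = []
    for i in range(config.n_blobs):
        gx, gy = i % side, i // side
        jitter = rng.normal(0.0, config.blob_spacing * 0.05, size=2)
        centers.append([
            (gx + 1) * config.blob_spacing + jitter[0],
            (gy + 1) * config.blob_spacing + jitter[1],
        ])
    return np.array(centers)


def simulate_slide(
    config: SlideSimConfig, slide_id: str = "synthetic"
) -> tuple[CellTable, RegionSet | None]:
    """Generate one synthetic slide (and optionally its region polygons).

    With ``emit_regions`` a TUMOR bounding box around the invasive blobs
    is written, plus a disjoint DCIS box holding ``dcis_cells`` extra
    tumor cells when requested.
    """
    rng = np.random.default_rng(config.seed)
    centers = _blob_centers(config, rng)

    cells: list[CellRecord] = []
    for cx, cy in centers:
        pts = rng.normal([cx, cy], config.blob_sigma, size=(config.cells_per_blob, 2))
        pts = np.abs(pts)  # keep the frame non-negative
        if rng.random() < 1.0 - config.mixing:
            # segregated blob: one class for the whole blob
            blob_cls = CellClass.TUMOR_POS if rng.random() < config.positivity else CellClass.TUMOR_NEG
            classes = [blob_cls] * config.cells_per_blob
        else:
            classes = [
                CellClass.TUMOR_POS if rng.random() < config.positivity else CellClass.TUMOR_NEG
                for _ in range(config.cells_per_blob)
            ]
        for (x, y), cls in zip(pts, classes):
            cells.append(CellRecord(x=float(x), y=float(y), cell_class=cls))

    n_tumor = len(cells)
    if config.nontumor_fraction > 0:
        n_nontumor = int(round(n_tumor * config.nontumor_fraction / (1 - config.nontumor_fraction))) \
            if config.nontumor_fraction < 1 else n_tumor
        lo, hi = centers.min(axis=0) - 3 * config.blob_sigma, centers.max(axis=0) + 3 * config.blob_sigma
        lo = np.maximum(lo, 0.0)
        for _ in range(n_nontumor):
            x, y = rng.uniform(lo, hi)
            cls = CellClass.NONTUMOR_POS if rng.random() < config.positivity else CellClass.NONTUMOR_NEG
            cells.append(CellRecord(x=float(x), y=float(y), cell_class=cls))

    regions: RegionSet | None = None
    if config.emit_regions:
        pad = 4 * config.blob_sigma
        xs = [c.x for c in cells] or [0.0]
        ys = [c.y for c in cells] or [0.0]
        tumor_box = box(max(min(xs) - pad, 0.0), max(min(ys) - pad, 0.0),
                        max(xs) + pad, max(ys) + pad)
        region_list = [Region(polygon=tumor_box, label="TUMOR")]
        if config.dcis_cells > 0:
            # disjoint DCIS pocket to the right of the tumor box
            x0 = max(xs) + pad + 2 * config.blob_spacing
            y0 = max(min(ys), 0.0)
            dcis_box = box(x0, y0, x0 + 6 * config.blob_sigma, y0 + 6 * config.blob_sigma)
            cx, cy = x0 + 3 * config.blob_sigma, y0 + 3 * config.blob_sigma
            pts = rng.normal([cx, cy], config.blob_sigma, size=(config.dcis_cells, 2))
            minx, miny, maxx, maxy = dcis_box.bounds
            pts = np.clip(pts, [minx, miny], [maxx, maxy])
            for x, y in pts:
                cls = CellClass.TUMOR_POS if rng.random() < config.positivity else CellClass.TUMOR_NEG
                cells.append(CellRecord(x=float(x), y=float(y), cell_class=cls))
            region_list.append(Region(polygon=dcis_box, label="DCIS"))
        regions = RegionSet(slide_id=slide_id, regions=region_list)

    return CellTable(slide_id=slide_id, cells=cells), regions


def simulate_cohort(
    slide_scores: list[float] | np.ndarray, config: CohortSimConfig
) -> list[SurvivalRecord]:
    """Survival records from a two-group exponential PH model on scores.

    Patients whose score exceeds ``score_threshold`` receive hazard
    baseline x hazard_ratio_high; others the baseline. Independent
    exponential censoring at ``censoring_rate`` plus an administrative
    follow-up cap determine the event indicator.
    """
    scores = np.asarray(slide_scores, dtype=float)
    if not np.all(np.isfinite(scores)):
        raise ValueError("scores must be finite")
    rng = np.random.default_rng(config.seed)
    records = []
    for i, s in enumerate(scores):
        hazard = config.baseline_hazard * (
            config.hazard_ratio_high if s > config.score_threshold else 1.0
        )
        t_event = rng.exponential(1.0 / hazard)
        t_cens = (
            rng.exponential(1.0 / config.censoring_rate)
            if config.censoring_rate > 0
            else np.inf
        )
        t_cens = min(t_cens, config.follow_up_cap)
        time = min(t_event, t_cens)
        records.append(SurvivalRecord(
            patient_id=f"P{i:05d}",
            time=float(max(time, 1e-9)),
            event=int(t_event <= t_cens),
            marker=float(s),
        ))
    return records


def simulate_probability_map(
    dots: list[DotSet],
    shape: tuple[int, int],
    sigma: float = 3.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> ProbabilityMap:
    """Probability maps from dot sets: Gaussian stamps plus clipped noise.

    With ``noise_sd`` = 0 each channel equals ``dots_to_density`` clipped
    to [0, 1]; otherwise i.i.d. Gaussian noise is added before clipping.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    rng = np.random.default_rng(seed)
    channels = {}
    for dotset in dots:
        grid = dots_to_density(dotset, shape, sigma)
        if noise_sd > 0:
            grid = grid + rng.normal(0.0, noise_sd, size=grid.shape)
        channels[dotset.channel] = np.clip(grid, 0.0, 1.0)
    return ProbabilityMap(height=shape[0], width=shape[1], channels=channels)
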