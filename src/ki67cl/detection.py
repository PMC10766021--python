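"""Deterministic pre- and post-processing around a dot-regression detector.

A detector of this family is trained to regress, per cell class, a map of
the probability that each pixel is a cell center. The training target is
built by stamping a peak-normalized Gaussian on every dot annotation; at
inference, cells are recovered by per-channel local-maxima extraction and
a cross-channel non-maximum suppression (local maxima closer than a merge
radius collapse to the most probable one). Everything here is independent
of the network itself and runs on plain arrays.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import maximum_filter

from .errors import DotOutOfBoundsError

__all__ = [
    "DotSet",
    "ProbabilityMap",
    "Detection",
    "tile_patches",
    "dots_to_density",
    "find_local_maxima",
    "merge_channels",
]

DEFAULT_PATCH = 252       # px, patch side used for tiling at x40
DEFAULT_MERGE_RADIUS = 15.0  # px, cross-channel suppression radius
DEFAULT_SIGMA = 3.0       # px, Gaussian stamp width (must stay well below
                          # half the merge radius so adjacent nuclei separate)
DEFAULT_MIN_PROBABILITY = 0.5


@dataclass
class DotSet:
    """Dot annotations of one class channel within a patch."""

    channel: str
    points: list[tuple[float, float]] = field(default_factory=list)


@dataclass
class ProbabilityMap:
    """Per-class grids of cell-center probability, values in [0, 1]."""

    height: int
    width: int
    channels: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, grid in self.channels.items():
            if grid.shape != (self.height, self.width):
                raise ValueError(f"channel {name!r} shape {grid.shape} != map shape")
            if not np.all(np.isfinite(grid)) or grid.min() < 0 or grid.max() > 1:
                raise ValueError(f"channel {name!r} values outside [0,1]")


@dataclass(frozen=True)
class Detection:
    """One detected cell center with its channel and map probability."""

    x: float
    y: float
    channel: str
    probability: float


def tile_patches(
    height: int, width: int, patch: int = DEFAULT_PATCH
) -> list[tuple[int, int, int, int]]:
    """Non-overlapping patch grid covering a (height, width) extent.

    Returns half-open windows (y0, y1, x0, x1); edge windows are clipped,
    so the union covers the extent exactly with empty pairwise overlap.
    """
    if patch <= 0:
        raise ValueError("patch size must be positive")
    if height <= 0 or width <= 0:
        raise ValueError("extent must be positive")
    windows = []
    for y0 in range(0, height, patch):
        for x0 in range(0, width, patch):
            windows.append((y0, min(y0 + patch, height), x0, min(x0 + patch, width)))
    return windows


def _gaussian_kernel(sigma: float, truncate: float = 4.0) -> np.ndarray:
    """Truncated, peak-normalized (max 1) 2-D Gaussian kernel."""
    radius = int(math.ceil(truncate * sigma))
    ax = np.arange(-radius, radius + 1, dtype=float)
    xx, yy = np.meshgrid(ax, ax)
    return np.exp(-(xx**2 + yy**2) / (2.0 * sigma**2))


def dots_to_density(
    dots: DotSet, shape: tuple[int, int], sigma: float = DEFAULT_SIGMA
) -> np.ndarray:
    """Convolve a binary dot image with a peak-normalized Gaussian.

    The peak at an isolated dot equals 1; contributions of nearby dots sum
    (plain convolution), so the output is a regression target rather than a
    bounded probability — callers who need [0, 1] clip afterwards.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    h, w = shape
    grid = np.zeros((h, w), dtype=float)
    kernel = _gaussian_kernel(sigma)
    radius = kernel.shape[0] // 2
    for x, y in dots.points:
        col, row = int(round(x)), int(round(y))
        if not (0 <= col < w and 0 <= row < h):
            raise DotOutOfBoundsError(f"dot ({x}, {y}) outside {h}x{w} grid")
        r0, r1 = max(row - radius, 0), min(row + radius + 1, h)
        c0, c1 = max(col - radius, 0), min(col + radius + 1, w)
        kr0 = r0 - (row - radius)
        kc0 = c0 - (col - radius)
        grid[r0:r1, c0:c1] += kernel[kr0 : kr0 + (r1 - r0), kc0 : kc0 + (c1 - c0)]
    return grid


def _disk_footprint(radius: float) -> np.ndarray:
    r = int(math.floor(radius))
    ax = np.arange(-r, r + 1)
    xx, yy = np.meshgrid(ax, ax)
    return (xx**2 + yy**2) <= radius**2


def find_local_maxima(
    map_channel: np.ndarray,
    min_probability: float = DEFAULT_MIN_PROBABILITY,
    min_distance: float = DEFAULT_MERGE_RADIUS,
) -> list[tuple[int, int, float]]:
    """Extract local maxima of one probability channel.

    A returned point (x, y, p) is at least ``min_probability``, is maximal
    within a Euclidean ``min_distance`` neighborhood, and all returned
    points are mutually >= ``min_distance`` apart. On plateaus the lowest
    row, then lowest column, pixel represents the plateau.
    """
    grid = np.asarray(map_channel, dtype=float)
    footprint = _disk_footprint(min_distance)
    is_peak = (grid == maximum_filter(grid, footprint=footprint, mode="nearest")) & (
        grid >= min_probability
    )
    rows, cols = np.nonzero(is_peak)
    if len(rows) == 0:
        return []
    order = np.lexsort((cols, rows, -grid[rows, cols]))  # prob desc, then row, col
    kept: list[tuple[int, int, float]] = []
    kept_rc: list[tuple[int, int]] = []
    for i in order:
        r, c = int(rows[i]), int(cols[i])
        if all((r - kr) ** 2 + (c - kc) ** 2 >= min_distance**2 for kr, kc in kept_rc):
            kept.append((c, r, float(grid[r, c])))
            kept_rc.append((r, c))
    kept.sort(key=lambda t: (t[1], t[0]))
    return kept


def merge_channels(
    per_channel: dict[str, list[tuple[float, float, float]]] | list[list["Detection"]],
    merge_radius: float = DEFAULT_MERGE_RADIUS,
    channel_order: list[str] | None = None,
) -> list[Detection]:
    """Cross-channel non-maximum suppression of detected maxima.

    Local maxima strictly closer than ``merge_radius`` (across any pair of
    channels) conflict; within each conflicting group only the detection
    with the highest probability survives. Equal probabilities break ties
    by channel order, then by (y, x) coordinates, so the result is
    deterministic. Accepts either a dict {channel: [(x, y, p), ...]} or a
    list of Detection lists.
    """
    if merge_radius <= 0:
        raise ValueError("merge_radius must be positive")

    dets: list[Detection] = []
    if isinstance(per_channel, dict):
        names = channel_order or list(per_channel)
        for name in names:
            for x, y, p in per_channel[name]:
                dets.append(Detection(x=float(x), y=float(y), channel=name, probability=float(p)))
    else:
        names = []
        for lst in per_channel:
            for d in lst:
                dets.append(d)
                if d.channel not in names:
                    names.append(d.channel)
        if channel_order:
            names = channel_order
    ch_rank = {name: i for i, name in enumerate(names)}

    dets.sort(key=lambda d: (-d.probability, ch_rank.get(d.channel, len(ch_rank)), d.y, d.x))
    kept: list[Detection] = []
    for d in dets:
        if all((d.x - k.x) ** 2 + (d.y - k.y) ** 2 >= merge_radius**2 for k in kept):
            kept.append(d)
    return kept
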