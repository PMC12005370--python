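"""Trajectory similarity: drift correction, occupancy grids, reach speed.

Tracked 2D paths (a paw digit during lever reaches, an ear point during
locomotion) are compared by projecting each path onto a binary occupancy
grid, smoothing with a 2D Gaussian, and taking the dot product of two
grids as their similarity. Condition-level similarity is the median over
all pairwise comparisons. The smoothing kernel is normalized to unit
sum, so absolute scores are an implementation scale; analyses use ratios
and orderings only.

Coordinates are pixels in analysis space (y up); the grid's row index 0
is the bottom row. Cross-session camera drift is removed by maximizing
the normalized 2D cross-correlation between a session image and the
reference (first prelesion) session image.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage, signal

from srtpipe.core_io import ParameterError, Trajectory, ValidationError

logger = logging.getLogger("srtpipe")


@dataclass(frozen=True)
class GridSpec:
    """Occupancy grid geometry: cells, physical cell size, smoothing sigma."""

    width: int = 800
    height: int = 700
    cell_size_cm: float = 0.4
    smoothing_sigma: float = 25.0  # pixels

    def __post_init__(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise ParameterError("grid dimensions must be positive")
        if self.cell_size_cm <= 0:
            raise ParameterError("cell size must be positive")
        if self.smoothing_sigma <= 0:
            raise ParameterError("smoothing sigma must be positive")


@dataclass
class OccupancyGrid:
    """Smoothed binary occupancy of one trajectory (rows = y, cols = x)."""

    values: np.ndarray  # height x width, >= 0
    spec: GridSpec
    n_clipped: int = 0


# ---------------------------------------------------------------------------
# Drift correction
# ---------------------------------------------------------------------------


def estimate_drift(
    reference_image: np.ndarray,
    session_image: np.ndarray,
    warn_below: float = 0.2,
) -> tuple[int, int]:
    """Integer (dx, dy) shift of the session view relative to the reference.

    Maximizes the normalized 2D cross-correlation; the returned shift is
    the translation that maps reference coordinates onto session
    coordinates, i.e. subtract it from session trajectories to undo the
    drift. A low peak correlation (featureless or unrelated images) is
    logged as a warning.
    """
    ref = np.asarray(reference_image, dtype=float)
    img = np.asarray(session_image, dtype=float)
    if ref.shape != img.shape:
        raise ValidationError("drift images must have equal shape")
    ref = ref - ref.mean()
    img = img - img.mean()
    denom = np.linalg.norm(ref) * np.linalg.norm(img)
    if denom == 0:
        raise ParameterError("estimate_drift: flat image (zero variance)")
    corr = signal.fftconvolve(img, ref[::-1, ::-1], mode="full")
    peak = np.unravel_index(int(np.argmax(corr)), corr.shape)
    dy = int(peak[0] - (ref.shape[0] - 1))
    dx = int(peak[1] - (ref.shape[1] - 1))
    peak_corr = float(corr[peak] / denom)
    if peak_corr < warn_below:
        logger.warning("estimate_drift: weak correlation peak %.3f at (%d, %d)", peak_corr, dx, dy)
    return dx, dy


def apply_drift(trajectories: list[Trajectory], dx: int, dy: int) -> list[Trajectory]:
    """Undo a session's field drift on all of its trajectories."""
    return [tr.translated(-dx, -dy) for tr in trajectories]


# ---------------------------------------------------------------------------
# Endpoint alignment (paw reaches only)
# ---------------------------------------------------------------------------


def align_endpoints(trajectories: list[Trajectory]) -> list[Trajectory]:
    """Translate each paw trajectory so its endpoint hits the set mean.

    Removes trial-to-trial scatter in where the paw lands on the lever,
    which would otherwise deflate trajectory correlations. Not applied to
    locomotor paths.
    """
    if not trajectories:
        raise ParameterError("align_endpoints: empty set")
    if any(tr.kind != "paw" for tr in trajectories):
        raise ParameterError("align_endpoints applies to paw trajectories only")
    ends = np.array([[tr.x[-1], tr.y[-1]] for tr in trajectories])
    mean_end = ends.mean(axis=0)
    return [
        tr.translated(mean_end[0] - tr.x[-1], mean_end[1] - tr.y[-1])
        for tr in trajectories
    ]


# ---------------------------------------------------------------------------
# Occupancy grids
# ---------------------------------------------------------------------------


def _supercover_cells(x0: float, y0: float, x1: float, y1: float):
    """Yield every (col, row) cell a segment passes through.

    Supercover grid traversal: unlike Bresenham it does not skip cells
    the segment merely clips at a corner, so a 50 Hz polyline marks a
    connected band of cells.
    """
    cx, cy = math.floor(x0), math.floor(y0)
    ex, ey = math.floor(x1), math.floor(y1)
    yield cx, cy
    dx, dy = x1 - x0, y1 - y0
    step_x = 1 if dx > 0 else -1
    step_y = 1 if dy > 0 else -1
    # parametric distance to the next vertical / horizontal cell boundary
    t_max_x = ((cx + (step_x > 0)) - x0) / dx if dx != 0 else math.inf
    t_max_y = ((cy + (step_y > 0)) - y0) / dy if dy != 0 else math.inf
    t_delta_x = abs(1.0 / dx) if dx != 0 else math.inf
    t_delta_y = abs(1.0 / dy) if dy != 0 else math.inf
    while (cx, cy) != (ex, ey):
        if abs(t_max_x - t_max_y) < 1e-12:
            # exact corner crossing: visit both adjacent cells
            yield cx + step_x, cy
            yield cx, cy + step_y
            cx += step_x
            cy += step_y
            t_max_x += t_delta_x
            t_max_y += t_delta_y
        elif t_max_x < t_max_y:
            cx += step_x
            t_max_x += t_delta_x
        else:
            cy += step_y
            t_max_y += t_delta_y
        yield cx, cy
        if min(t_max_x, t_max_y) > 1.0 + 1e-9:
            break
    yield ex, ey


def occupancy_grid(traj: Trajectory, spec: GridSpec) -> OccupancyGrid:
    """Rasterize a trajectory onto a binary grid and Gaussian-smooth it.

    Every cell crossed by the sampled polyline is marked 1 (supercover
    rasterization between consecutive samples); the binary matrix is then
    convolved with a unit-sum 2D Gaussian of the spec's smoothing sigma.
    Out-of-bounds cells are clipped and counted.
    """
    if len(traj) == 0:
        raise ParameterError("occupancy_grid: empty trajectory")
    binary = np.zeros((spec.height, spec.width))
    clipped = 0
    xs, ys = traj.x, traj.y
    cells: set[tuple[int, int]] = set()
    if len(traj) == 1:
        cells.add((math.floor(xs[0]), math.floor(ys[0])))
    for i in range(len(traj) - 1):
        for c in _supercover_cells(xs[i], ys[i], xs[i + 1], ys[i + 1]):
            cells.add(c)
    for col, row in cells:
        if 0 <= col < spec.width and 0 <= row < spec.height:
            binary[row, col] = 1.0
        else:
            clipped += 1
    if clipped:
        logger.warning("occupancy_grid: clipped %d out-of-bounds cells", clipped)
    smoothed = ndimage.gaussian_filter(binary, sigma=spec.smoothing_sigma, mode="constant")
    return OccupancyGrid(values=smoothed, spec=spec, n_clipped=clipped)


def grid_correlation(g1: OccupancyGrid, g2: OccupancyGrid) -> float:
    """Dot-product similarity of two smoothed occupancy grids."""
    if g1.spec != g2.spec:
        raise ValidationError("grid_correlation: mismatched GridSpecs")
    return float(np.vdot(g1.values, g2.values))


def condition_similarity(
    set_a: list[OccupancyGrid],
    set_b: list[OccupancyGrid] | None = None,
) -> float:
    """Median pairwise grid correlation within or between conditions.

    Within a condition: median over all unordered pairs (self-pairs
    excluded). Between conditions: median over all cross pairs.
    """
    if set_b is None:
        if len(set_a) < 2:
            raise ParameterError("condition_similarity: need >= 2 grids within a set")
        scores = [
            grid_correlation(set_a[i], set_a[j])
            for i in range(len(set_a))
            for j in range(i + 1, len(set_a))
        ]
    else:
        if not set_a or not set_b:
            raise ParameterError("condition_similarity: empty set")
        scores = [grid_correlation(a, b) for a in set_a for b in set_b]
    return float(np.median(scores))


# ---------------------------------------------------------------------------
# Reach speed
# ---------------------------------------------------------------------------


def reach_speed(traj: Trajectory) -> float:
    """Paw reach speed: path length from lift-off to apex over elapsed time.

    The apex is the sample of maximum height (y-up analysis space; ties
    broken by the earliest sample). Returns pixels per millisecond.
    """
    if traj.kind != "paw":
        raise ParameterError("reach_speed is defined for paw trajectories")
    if len(traj) < 2:
        raise ParameterError("reach_speed: need >= 2 samples")
    apex = int(np.argmax(traj.y))
    if apex == 0:
        raise ParameterError("reach_speed: apex at the first sample (zero elapsed time)")
    dx = np.diff(traj.x[: apex + 1])
    dy = np.diff(traj.y[: apex + 1])
    path_len = float(np.sum(np.hypot(dx, dy)))
    elapsed_ms = (traj.t[apex] - traj.t[0]) * 1000.0
    return path_len / elapsed_ms
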