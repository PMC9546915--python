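"""Translational cell activity: path distance, velocity, propagation
area and directional persistence.

All translational measures are built on the per-frame refined cell
vertex (see :mod:`cellactivity.morphology`): the path distance is the
arc length of the vertex polyline, the propagation area is the union of
the cell's occupied pixels over time, and directional persistence is
the anisotropy of either the per-step displacement distribution
(short-term) or the vertex-position cloud (long-term), summarized by a
principal-axis ratio.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

log = logging.getLogger(__name__)

ANGULAR_HIST_BINS = 16


@dataclass
class Trajectory:
    """Time-ordered refined-vertex track of one cell.

    vertices are (row, col) pixel positions, one per present frame;
    px_scale in um/pixel, frame_interval in minutes.
    """

    cell_id: int
    vertices: np.ndarray
    frame_interval: float = 1.0
    px_scale: float = 1.0

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 2:
            raise ValueError("vertices must be an (N, 2) array")


@dataclass
class DirectionalPersistence:
    """Principal-axis summary of a 2D point or displacement distribution.

    ``axis_minor``/``axis_major`` are the square-rooted eigenvalues of
    the covariance (RMS extent along each principal direction, in the
    input units); ``ratio`` = minor/major lies in (0, 1]: 1 for an
    isotropic cloud, toward 0 for persistent, directed motion.
    """

    axis_minor: float
    axis_major: float
    ratio: float
    major_direction: np.ndarray
    angular_hist: np.ndarray | None = None
    angular_edges: np.ndarray | None = None
    degenerate: bool = False


def path_distance(traj: Trajectory) -> tuple[float, np.ndarray, float]:
    """Arc length of the vertex track (um), per-step speeds (um/min) and
    the mean velocity (total distance over total time)."""
    if len(traj.vertices) < 2:
        raise ValueError("path distance needs at least 2 frames")
    steps = np.hypot(*np.diff(traj.vertices, axis=0).T) * traj.px_scale
    d_l = float(steps.sum())
    v_l = steps / traj.frame_interval
    mean_v = d_l / (traj.frame_interval * (len(traj.vertices) - 1))
    return d_l, v_l, mean_v


def propagation_area(stack, cell_id: int, px_scale: float) -> float:
    """Area (um^2) of the union over time of the cell's masks: every
    pixel the cell has occupied during the observation."""
    frames = stack.frames if hasattr(stack, "frames") else np.asarray(stack)
    union = np.any(frames == cell_id, axis=0)
    if not union.any():
        raise ValueError(f"cell id {cell_id} absent from the stack")
    return float(union.sum()) * px_scale ** 2


def _principal_axes(points: np.ndarray) -> tuple[float, float, np.ndarray]:
    """RMS extents along the principal directions of a 2D point set."""
    centered = points - points.mean(axis=0)
    cov = centered.T @ centered / max(len(points) - 1, 1)
    vals, vecs = np.linalg.eigh(cov)
    vals = np.clip(vals, 0.0, None)
    return float(np.sqrt(vals[0])), float(np.sqrt(vals[1])), vecs[:, 1]


def short_term_dp(traj: Trajectory,
                  n_bins: int = ANGULAR_HIST_BINS) -> DirectionalPersistence:
    """Short-term directional persistence from per-step displacements.

    The frame-to-frame displacement vectors are decomposed into
    principal axes; their minor/major RMS ratio measures how collinear
    consecutive steps are.  The polar form (step magnitude and heading)
    feeds the exported angular histogram.
    """
    if len(traj.vertices) < 3:
        raise ValueError("short-term persistence needs at least 3 frames")
    disp = np.diff(traj.vertices, axis=0)
    mags = np.hypot(disp[:, 0], disp[:, 1])
    if np.allclose(mags, 0):
        log.info("all displacements zero for cell %d: persistence "
                 "undefined", traj.cell_id)
        return DirectionalPersistence(0.0, 0.0, np.nan, np.zeros(2),
                                      degenerate=True)
    angles = np.arctan2(disp[:, 0], disp[:, 1])
    edges = np.linspace(-np.pi, np.pi, n_bins + 1)
    hist, _ = np.histogram(angles, bins=edges, weights=mags)
    # second moments about the origin, not the mean: a steady drift is
    # maximally persistent (ratio 0), not degenerate
    cov = disp.T @ disp / len(disp)
    vals, vecs = np.linalg.eigh(cov)
    vals = np.clip(vals, 0.0, None)
    minor, major = float(np.sqrt(vals[0])), float(np.sqrt(vals[1]))
    direction = vecs[:, 1]
    ratio = minor / major if major > 0 else np.nan
    return DirectionalPersistence(minor * traj.px_scale,
                                  major * traj.px_scale, float(ratio),
                                  direction, hist, edges)


def long_term_dp(traj: Trajectory) -> tuple[DirectionalPersistence, float]:
    """Long-term directional persistence from the vertex-position cloud
    plus the convex-hull area (um^2) of the visited positions."""
    pts = traj.vertices
    if len(pts) < 3:
        raise ValueError("long-term persistence needs at least 3 frames")
    if np.allclose(pts, pts[0]):
        log.info("cell %d never moved: long-term persistence degenerate",
                 traj.cell_id)
        return (DirectionalPersistence(0.0, 0.0, np.nan, np.zeros(2),
                                       degenerate=True), 0.0)
    minor, major, direction = _principal_axes(pts)
    ratio = minor / major if major > 0 else 0.0
    hull_area = 0.0
    try:
        from scipy.spatial import ConvexHull, QhullError
        hull_area = float(ConvexHull(pts).volume) * traj.px_scale ** 2
    except QhullError:
        log.info("cell %d: collinear vertex track, hull area 0",
                 traj.cell_id)
    dp = DirectionalPersistence(minor * traj.px_scale,
                                major * traj.px_scale, float(ratio),
                                direction, degenerate=major == 0)
    return dp, hull_area


def migration_table(stack, trajectories: dict[int, np.ndarray],
                    px_scale: float, frame_interval: float = 1.0):
    """Per-cell migration summary (one row per cell id)."""
    import pandas as pd

    rows = []
    for cid, path in sorted(trajectories.items()):
        ok = ~np.isnan(path[:, 0])
        pts = path[ok]
        if len(pts) < 3:
            continue
        traj = Trajectory(cid, pts, frame_interval, px_scale)
        d_l, _v_l, mean_v = path_distance(traj)
        p_a = propagation_area(stack, cid, px_scale)
        dps = short_term_dp(traj)
        dpl, hull = long_term_dp(traj)
        rows.append(dict(cell_id=cid, path_distance_um=d_l,
                         mean_velocity_um_min=mean_v,
                         mean_velocity_px_frame=mean_v * frame_interval / px_scale,
                         propagation_area_um2=p_a,
                         dp_short_ratio=dps.ratio,
                         dp_long_ratio=dpl.ratio,
                         hull_area_um2=hull))
    return pd.DataFrame(rows)
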