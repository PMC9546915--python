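"""Shared phantom fixtures.

Heavier scene-level fixtures are session-scoped so the tracking,
migration and acceptance tests reuse one render.
"""

import numpy as np
import pytest

from cellactivity.phantoms import (CellSpec, ContaminantSpec, PhantomConfig,
                                   generate_phantom_stack, render_cell_mask,
                                   truth_index_map)

GRID = (200, 200)
CENTER = (100.0, 100.0)


@pytest.fixture(scope="session")
def disk_mask():
    """Rasterized disk, radius 50 px."""
    return render_cell_mask(CellSpec(body_radius=50), CENTER, 0.0, GRID)


@pytest.fixture(scope="session")
def ellipse_mask():
    """80 x 40 px ellipse (semi-axes 40 and 20)."""
    return render_cell_mask(CellSpec(body_radius=40, axis_ratio=0.5),
                            CENTER, 0.0, GRID)


@pytest.fixture(scope="session")
def star_factory():
    """k-armed star with body radius 20 px and arm tips at twice that."""

    def make(k: int, phase: float = 0.2) -> np.ndarray:
        return render_cell_mask(
            CellSpec(body_radius=20, n_protrusions=k, protrusion_length=20),
            CENTER, phase, GRID)

    return make


def tracking_scene_config(n_frames: int = 50) -> PhantomConfig:
    """Three slow cells (displacement < radius/frame) and two contaminants
    at five times the fastest cell speed."""
    return PhantomConfig(
        n_frames=n_frames, image_size=(256, 256), noise_sd=2, seed=3,
        cells=[
            CellSpec(body_radius=16, center0=(60, 60),
                     motion=("linear", 1.5, 0.0)),
            CellSpec(body_radius=14, center0=(190, 70),
                     motion=("random_walk", 1.0)),
            CellSpec(body_radius=18, center0=(120, 190),
                     motion=("stationary",)),
        ],
        contaminants=[
            ContaminantSpec(radius=9, speed=7.5, center0=(40, 200),
                            heading=2.2),
            ContaminantSpec(radius=8, speed=7.5, center0=(220, 160),
                            heading=-0.9),
        ])


@pytest.fixture(scope="session")
def tracking_scene():
    cfg = tracking_scene_config()
    gray, labels, truth = generate_phantom_stack(cfg)
    index_maps = np.stack([truth_index_map(f, len(cfg.cells))
                           for f in labels])
    return cfg, gray, labels, truth, index_maps


def adhesion_config(n_frames: int = 40,
                    touch: tuple[int, int] = (10, 20)) -> PhantomConfig:
    """Two cells scripted to approach, touch during ``touch``, separate."""
    r = 15
    gap_far, gap_near = 50.0, 26.0  # touching when center gap < 2r
    t0, t1 = touch
    d = np.full(n_frames, gap_far)
    d[:t0] = np.linspace(gap_far, gap_near, t0)
    d[t0:t1 + 1] = gap_near
    d[t1 + 1:] = np.linspace(gap_near, gap_far, n_frames - t1 - 1)
    mid = 128.0
    pos_a = np.stack([np.full(n_frames, mid), mid - d / 2], axis=1)
    pos_b = np.stack([np.full(n_frames, mid), mid + d / 2], axis=1)
    cells = [CellSpec(body_radius=r, center0=tuple(pos_a[0]),
                      motion=("scripted", pos_a)),
             CellSpec(body_radius=r, center0=tuple(pos_b[0]),
                      motion=("scripted", pos_b))]
    return PhantomConfig(n_frames=n_frames, image_size=(256, 256),
                         cells=cells, noise_sd=2, seed=1)


@pytest.fixture(scope="session")
def adhesion_scene():
    cfg = adhesion_config()
    gray, labels, truth = generate_phantom_stack(cfg)
    index_maps = np.stack([truth_index_map(f, 2) for f in labels])
    return cfg, labels, index_maps
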