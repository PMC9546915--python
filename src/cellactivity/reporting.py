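"""Population-level aggregation and control-relative summaries.

A condition (e.g. one drug concentration) yields a per-cell-frame
morphology table and a per-cell migration table; this module collapses
them into per-property distributions (kept both per cell and pooled per
frame) and expresses treated conditions as ratios of population means
relative to a control condition — the values a radar chart of drug
response is drawn from.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

# The six headline properties of cell activity.
PROPERTIES = ("area", "shape", "eccentricity", "n_protrusions",
              "velocity", "directional_persistence")

_PROP_COLUMNS = {
    "area": ("props", "area_um2"),
    "shape": ("props", "shape_per_um"),
    "eccentricity": ("props", "eccentricity"),
    "n_protrusions": ("props", "n_protrusions"),
    "velocity": ("migration", "mean_velocity_um_min"),
    "directional_persistence": ("migration", "dp_long_ratio"),
}


@dataclass
class PopulationSummary:
    """Distributions of the six cell-activity properties for one
    condition: per-cell means, pooled per-frame values, and population
    mean/median/IQR for each property."""

    condition: str
    n_cells: int
    n_frames: int
    per_cell: dict[str, np.ndarray]
    per_frame: dict[str, np.ndarray]
    stats: dict[str, dict[str, float]]


@dataclass
class RelativeSummary:
    """Per-property ratio of treated to control population means
    (control/control is exactly 1 everywhere)."""

    condition: str
    control: str
    ratios: dict[str, float]


def aggregate_population(props: pd.DataFrame, migration: pd.DataFrame,
                         condition: str = "") -> PopulationSummary:
    """Collapse per-cell-frame property tables into one population
    summary.

    Per-cell distributions average each cell over its frames (migration
    measures are already per cell); pooled per-frame distributions keep
    every cell-frame observation.
    """
    if props.empty:
        raise ValueError("empty property table")
    per_cell: dict[str, np.ndarray] = {}
    per_frame: dict[str, np.ndarray] = {}
    stats: dict[str, dict[str, float]] = {}
    for prop in PROPERTIES:
        table_name, col = _PROP_COLUMNS[prop]
        table = props if table_name == "props" else migration
        if col not in table.columns:
            continue
        vals = table[col].to_numpy(dtype=float)
        if table_name == "props":
            cell_means = table.groupby("cell_id")[col].mean().to_numpy(float)
            per_frame[prop] = vals
        else:
            cell_means = vals
            per_frame[prop] = vals
        per_cell[prop] = cell_means
        finite = cell_means[np.isfinite(cell_means)]
        q1, q3 = (np.percentile(finite, [25, 75])
                  if len(finite) else (np.nan, np.nan))
        stats[prop] = dict(mean=float(np.mean(finite)) if len(finite) else np.nan,
                           median=float(np.median(finite)) if len(finite) else np.nan,
                           iqr=float(q3 - q1))
    return PopulationSummary(
        condition=condition,
        n_cells=int(props["cell_id"].nunique()),
        n_frames=int(props["frame"].nunique()),
        per_cell=per_cell, per_frame=per_frame, stats=stats)


def relative_summary(treated: PopulationSummary,
                     control: PopulationSummary) -> RelativeSummary:
    """Treated-over-control ratios of per-cell population means."""
    if set(treated.stats) != set(control.stats):
        raise ValueError("treated and control report different properties")
    ratios = {}
    for prop in treated.stats:
        c = control.stats[prop]["mean"]
        t = treated.stats[prop]["mean"]
        if not np.isfinite(c) or c == 0:
            log.info("property %r: control mean is zero/undefined; ratio "
                     "flagged NaN", prop)
            ratios[prop] = np.nan
        else:
            ratios[prop] = float(t / c)
    return RelativeSummary(treated.condition, control.condition, ratios)


# ---------------------------------------------------------------------------
# End-to-end pipeline


def process_stack(index_maps: np.ndarray, px_scale: float,
                  frame_interval: float = 1.0,
                  cell_classes=frozenset({2, 3, 4}),
                  filters: tuple[str, ...] = ("presence", "velocity", "border"),
                  velocity_factor: float = 3.0,
                  min_island_px: int = 30,
                  ) -> tuple:
    """Index maps -> tracked/filtered label stack + property tables.

    Returns (stack, props DataFrame, migration DataFrame).
    """
    from . import morphology, migration as mig, tracking

    labeled = [tracking.label_islands(m, cell_classes, min_island_px)
               for m in index_maps]
    stack = tracking.propagate_labels(labeled)
    stack = tracking.watershed_refine(stack)
    if "presence" in filters:
        stack = tracking.filter_full_presence(stack)
    if "velocity" in filters:
        stack = tracking.filter_by_velocity(stack, factor=velocity_factor)
    if "border" in filters:
        stack = tracking.filter_border(stack)

    props = morphology.measure_stack(stack, px_scale, frame_interval)
    # migration runs on the refined (sub-pixel) vertices from morphology
    traj = {}
    if not props.empty:
        for cid, grp in props.groupby("cell_id"):
            path = np.full((stack.n_frames, 2), np.nan)
            path[grp["frame"].to_numpy()] = grp[["vertex_row", "vertex_col"]].to_numpy()
            traj[int(cid)] = path
    migration_df = mig.migration_table(stack, traj, px_scale, frame_interval)
    return stack, props, migration_df


def run_pipeline(config: dict, outdir) -> Path:
    """Run the full analysis for a multi-condition experiment.

    ``config`` maps condition names to either phantom configurations
    (key "phantom") or paths to index-map TIFF stacks (key "index_maps");
    optional keys: px_scale_um, frame_interval_min, control, filters,
    velocity_factor, cell_classes.  Writes props.csv, migration.csv,
    summary.json and radar.csv to ``outdir``.
    """
    from . import phantoms
    from .io import read_stack

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    px_scale = float(config.get("px_scale_um", 640.0 / 1608.0))
    dt = float(config.get("frame_interval_min", 1.0))
    filters = tuple(config.get("filters", ("presence", "velocity", "border")))
    cell_classes = frozenset(config.get("cell_classes", (2, 3, 4)))
    control_name = config.get("control")

    summaries: dict[str, PopulationSummary] = {}
    all_props, all_migration = [], []
    for name, cond in config["conditions"].items():
        if "phantom" in cond:
            pc = cond["phantom"]
            if isinstance(pc, dict):
                pc = phantoms.PhantomConfig(**pc)
            _gray, labels, _truth = phantoms.generate_phantom_stack(pc)
            index_maps = np.stack([
                phantoms.truth_index_map(f, len(pc.cells)) for f in labels])
            # phantom truth maps label contaminants class 1; track both
            # classes so the velocity/presence filters do the rejection
            classes = frozenset(cond.get("cell_classes", (1, 2)))
            px, fi = pc.px_scale, pc.frame_interval
        elif "index_maps" in cond:
            index_maps = read_stack(cond["index_maps"])
            classes = cell_classes
            px, fi = px_scale, dt
        else:
            raise ValueError(f"condition {name!r} names no input")
        _stack, props, migration_df = process_stack(
            index_maps, px, fi, classes, filters,
            float(config.get("velocity_factor", 3.0)))
        if props.empty:
            raise RuntimeError(f"condition {name!r}: no cells survive "
                               "tracking and filtering")
        props.insert(0, "condition", name)
        migration_df.insert(0, "condition", name)
        all_props.append(props)
        all_migration.append(migration_df)
        summaries[name] = aggregate_population(props, migration_df, name)

    pd.concat(all_props).to_csv(outdir / "props.csv", index=False)
    pd.concat(all_migration).to_csv(outdir / "migration.csv", index=False)

    summary_json = {
        name: dict(n_cells=s.n_cells, n_frames=s.n_frames, stats=s.stats)
        for name, s in summaries.items()
    }
    radar_rows = []
    if control_name is None or control_name not in summaries:
        warnings.warn("no control condition configured; relative summary "
                      "skipped", stacklevel=2)
    else:
        control = summaries[control_name]
        for name, s in summaries.items():
            rel = relative_summary(s, control)
            summary_json[name]["relative_to_control"] = rel.ratios
            for prop, r in rel.ratios.items():
                radar_rows.append(dict(condition=name, property=prop,
                                       ratio=r))
    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary_json, fh, indent=2)
    pd.DataFrame(radar_rows).to_csv(outdir / "radar.csv", index=False)
    return outdir
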