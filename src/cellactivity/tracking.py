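"""Temporal label propagation and track filtering.

Turns per-frame semantic index maps into a temporally consistent label
stack: connected components ("islands") are labeled by decreasing pixel
area, ids are propagated between neighboring frames by maximal pixel
overlap, adhesion events are resolved by watershed splitting seeded at
distance-map nucleus candidates, and tracks are filtered by full
presence, velocity and border contact.  The premise is that the frame
interval is short relative to cell motion, so a cell's masks in
consecutive frames overlap.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.optimize import linear_sum_assignment
from skimage.feature import peak_local_max
from skimage.measure import label as cc_label
from skimage.segmentation import watershed

log = logging.getLogger(__name__)

DEFAULT_CELL_CLASSES = frozenset({2, 3, 4})  # cell, overlap, cell edge
MIN_ISLAND_PX = 30  # sub-cellular fragments are noise at ~0.4 um/px


@dataclass
class NucleusCandidate:
    """A putative cell center: a local maximum of an island's Euclidean
    distance map."""

    frame: int
    position: tuple[int, int]
    peak_distance: float


@dataclass
class LabelStack:
    """Per-frame integer label grids with persistent positive cell ids.

    0 is background; a given positive id denotes the same physical cell
    in every frame where it is present.  ``events`` records merges
    (several ids collapsing onto one island) and splits (one id's island
    separating) for the watershed-refinement stage.
    """

    frames: np.ndarray  # (T, H, W) integer
    events: list[dict] = field(default_factory=list)

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def ids(self) -> list[int]:
        u = np.unique(self.frames)
        return [int(i) for i in u if i > 0]

    @property
    def id_registry(self) -> dict[int, np.ndarray]:
        """id -> boolean per-frame presence flags."""
        reg = {}
        for i in self.ids:
            reg[i] = np.array([(f == i).any() for f in self.frames])
        return reg

    def copy(self) -> "LabelStack":
        return LabelStack(self.frames.copy(), [dict(e) for e in self.events])


def label_islands(index_map: np.ndarray,
                  cell_classes: frozenset | set = DEFAULT_CELL_CLASSES,
                  min_size: int = MIN_ISLAND_PX) -> np.ndarray:
    """Label connected components of the requested classes 1..K in
    decreasing pixel-area order (8-connectivity)."""
    fg = np.isin(index_map, list(cell_classes))
    raw = cc_label(fg, connectivity=2)
    if raw.max() == 0:
        return np.zeros_like(raw)
    areas = np.bincount(raw.ravel())[1:]
    keep = [i + 1 for i, a in enumerate(areas) if a >= min_size]
    order = sorted(keep, key=lambda i: -areas[i - 1])
    out = np.zeros_like(raw)
    for new, old in enumerate(order, start=1):
        out[raw == old] = new
    return out


def _overlap_table(prev: np.ndarray, cur: np.ndarray) -> dict:
    """(prev_id, cur_label) -> overlap pixel count, for positive labels."""
    both = (prev > 0) & (cur > 0)
    if not both.any():
        return {}
    pairs = np.stack([prev[both], cur[both]])
    uniq, counts = np.unique(pairs, axis=1, return_counts=True)
    return {(int(p), int(c)): int(n)
            for (p, c), n in zip(uniq.T, counts)}


def propagate_labels(labeled_frames: list[np.ndarray] | np.ndarray) -> LabelStack:
    """Propagate island ids through time by maximal pixel overlap.

    An island in frame t+1 inherits the id of the frame-t island it
    overlaps most (ties: larger overlap, then larger island area, then
    lower id); islands without overlap get fresh ids.  Many-to-one
    overlaps are recorded as merge events, one-to-many as split events.
    """
    frames = [np.asarray(f) for f in labeled_frames]
    out = np.zeros((len(frames), *frames[0].shape), dtype=np.int32)
    events: list[dict] = []

    out[0] = frames[0]
    next_id = int(frames[0].max()) + 1

    for t in range(1, len(frames)):
        cur = frames[t]
        prev = out[t - 1]
        table = _overlap_table(prev, cur)
        prev_areas = {int(i): int((prev == i).sum()) for i in np.unique(prev) if i > 0}

        cur_labels = [int(i) for i in np.unique(cur) if i > 0]
        # argmax parent per current island
        want: dict[int, int] = {}
        for c in cur_labels:
            cands = [(n, prev_areas[p], -p, p) for (p, cc), n in table.items()
                     if cc == c]
            if cands:
                want[c] = max(cands)[3]

        # resolve several islands claiming one parent: best overlap keeps it
        assigned: dict[int, int] = {}
        by_parent: dict[int, list[int]] = {}
        for c, p in want.items():
            by_parent.setdefault(p, []).append(c)
        for p, cs in by_parent.items():
            cs_sorted = sorted(cs, key=lambda c: (-table[(p, c)], c))
            winner = cs_sorted[0]
            assigned[winner] = p
            if len(cs_sorted) > 1:
                new_ids = []
                for c in cs_sorted[1:]:
                    assigned[c] = next_id
                    new_ids.append(next_id)
                    next_id += 1
                events.append(dict(type="split", frame=t, parent=p,
                                   new_ids=new_ids))
        for c in cur_labels:
            if c not in assigned:
                assigned[c] = next_id
                next_id += 1

        for c, gid in assigned.items():
            out[t][cur == c] = gid

        # merge detection: prev ids that overlap an island but won nothing
        taken = set(assigned.values())
        lost_by_island: dict[int, list[int]] = {}
        for (p, c), _n in table.items():
            if p not in taken:
                best = max(((n2, c2) for (p2, c2), n2 in table.items() if p2 == p))
                if best[1] == c:
                    lost_by_island.setdefault(c, []).append(p)
        for c, lost in lost_by_island.items():
            events.append(dict(type="merge", frame=t, survivor=assigned[c],
                               lost=sorted(set(lost))))

    return LabelStack(out, events)


def nucleus_candidates(mask: np.ndarray, frame: int = -1,
                       min_separation: int | None = None,
                       ) -> list[NucleusCandidate]:
    """Local maxima of an island's Euclidean distance map, candidate cell
    centers inside a (possibly multi-cell) island.

    Minimum peak separation defaults to half the island's body radius
    (half the distance-map maximum); candidates come back sorted by peak
    distance, descending.
    """
    mask = np.asarray(mask, bool)
    if not mask.any():
        return []
    dmap = ndimage.distance_transform_edt(mask)
    if min_separation is None:
        min_separation = max(1, int(round(dmap.max() / 2)))
    peaks = peak_local_max(dmap, min_distance=min_separation,
                           exclude_border=False, labels=mask)
    cands = [NucleusCandidate(frame, (int(r), int(c)), float(dmap[r, c]))
             for r, c in peaks]
    cands.sort(key=lambda nc: -nc.peak_distance)
    return cands


def _vertex(mask: np.ndarray) -> tuple[int, int]:
    dmap = ndimage.distance_transform_edt(mask)
    idx = np.unravel_index(int(np.argmax(dmap)), dmap.shape)
    return (int(idx[0]), int(idx[1]))


def _match(refs: dict[int, tuple[int, int]],
           cands: list[NucleusCandidate]) -> dict[int, NucleusCandidate]:
    """Nearest-neighbor assignment of reference vertices to candidates
    (Hungarian, so no candidate is used twice)."""
    ids = list(refs)
    if not ids or not cands:
        return {}
    cost = np.array([[np.hypot(refs[i][0] - c.position[0],
                               refs[i][1] - c.position[1])
                      for c in cands] for i in ids])
    ri, ci = linear_sum_assignment(cost)
    return {ids[r]: cands[c] for r, c in zip(ri, ci)}


def _split_island(frame_grid: np.ndarray, island_mask: np.ndarray,
                  refs: dict[int, tuple[int, int]]) -> dict[int, tuple[int, int]] | None:
    """Watershed-split one island between the ids in ``refs``.

    Seeds are nucleus candidates matched to the ids' reference vertices;
    the inverted distance map is flooded from them so the partition
    follows the necks between lobes.  Returns updated per-id vertices, or
    None when there are fewer candidates than ids (island left merged).
    """
    cands = nucleus_candidates(island_mask)
    if len(cands) < len(refs):
        return None
    assign = _match(refs, cands)
    if len(assign) < len(refs):
        return None
    dmap = ndimage.distance_transform_edt(island_mask)
    markers = np.zeros(island_mask.shape, dtype=np.int32)
    for i, cand in assign.items():
        markers[cand.position] = i
    parts = watershed(-dmap, markers=markers, mask=island_mask)
    new_refs = {}
    for i in refs:
        part = parts == i
        if not part.any():
            return None
        frame_grid[part] = i
        new_refs[i] = _vertex(part)
    return new_refs


def watershed_refine(stack: LabelStack) -> LabelStack:
    """Resolve recorded adhesion events so each cell keeps its id while
    merged.

    For every merge, the matching later split re-identifies the lost ids
    (nearest-neighbor on vertices) and the merged interval is re-split
    per frame by marker-based watershed; merges that never separate again
    are resolved forward to the end of the stack, and splits with no
    preceding merge (adhesion from the first frame) are resolved
    backward.  When an island offers fewer nucleus candidates than merged
    ids it is left merged and a warning is logged.
    """
    out = stack.copy()
    frames = out.frames
    merges = [e for e in out.events if e["type"] == "merge"]
    splits = [e for e in out.events if e["type"] == "split"]
    used_split_ids: set[int] = set()

    for ev in merges:
        tm, survivor, lost = ev["frame"], ev["survivor"], list(ev["lost"])
        # pair with the next split of the survivor
        nxt = next((s for s in splits if s["parent"] == survivor
                    and s["frame"] >= tm
                    and not set(s["new_ids"]) <= used_split_ids), None)
        if nxt is not None:
            ts = int(nxt["frame"])
            fresh = [i for i in nxt["new_ids"] if i not in used_split_ids]
            lost_refs = {i: _vertex(frames[tm - 1] == i) for i in lost
                         if (frames[tm - 1] == i).any()}
            fresh_refs = {i: _vertex(frames[ts] == i) for i in fresh}
            pairing = _match(lost_refs, [
                NucleusCandidate(ts, fresh_refs[i], i) for i in fresh])
            # candidate.peak_distance abused to carry the fresh id
            relabel = {int(c.peak_distance): i for i, c in pairing.items()}
            for f_id, l_id in relabel.items():
                frames[ts:][frames[ts:] == f_id] = l_id
                used_split_ids.add(f_id)
            end = ts
        else:
            end = out.n_frames
            log.info("merge at frame %d never separates; resolving forward "
                     "to the end of the stack", tm)

        refs = {i: _vertex(frames[tm - 1] == i) for i in lost + [survivor]
                if (frames[tm - 1] == i).any()}
        for t in range(tm, end):
            island = frames[t] == survivor
            if not island.any():
                break
            new_refs = _split_island(frames[t], island, refs)
            if new_refs is None:
                warnings.warn(
                    f"frame {t}: fewer nucleus candidates than merged ids; "
                    "island left merged", stacklevel=2)
                break
            refs = new_refs

    # splits that were not explained by a merge: adhesion present from the
    # start -> resolve backward from the separation frame
    for ev in splits:
        fresh = [i for i in ev["new_ids"] if i not in used_split_ids]
        if not fresh:
            continue
        ts, parent = int(ev["frame"]), ev["parent"]
        refs = {i: _vertex(frames[ts] == i) for i in fresh + [parent]
                if (frames[ts] == i).any()}
        for t in range(ts - 1, -1, -1):
            island = frames[t] == parent
            if not island.any():
                break
            new_refs = _split_island(frames[t], island, refs)
            if new_refs is None:
                warnings.warn(
                    f"frame {t}: fewer nucleus candidates than merged ids; "
                    "island left merged", stacklevel=2)
                break
            refs = new_refs

    return out


# ---------------------------------------------------------------------------
# Track filters


def filter_full_presence(stack: LabelStack) -> LabelStack:
    """Keep only ids present in every frame of the observation."""
    out = stack.copy()
    reg = out.id_registry
    for i, present in reg.items():
        if not present.all():
            first, last = (np.nonzero(present)[0][[0, -1]]
                           if present.any() else (-1, -1))
            log.info("id %d removed: present frames %s..%s only",
                     i, first, last)
            out.frames[out.frames == i] = 0
    if not out.ids:
        warnings.warn("no ids survive the full-presence filter",
                      stacklevel=2)
    return out


def vertex_trajectories(stack: LabelStack) -> dict[int, np.ndarray]:
    """Per-id (T, 2) vertex (distance-map maximum) trajectories; NaN rows
    where the id is absent."""
    traj = {i: np.full((stack.n_frames, 2), np.nan) for i in stack.ids}
    for t, frame in enumerate(stack.frames):
        for i in np.unique(frame):
            if i > 0:
                traj[int(i)][t] = _vertex(frame == i)
    return traj


def mean_speeds(traj: dict[int, np.ndarray]) -> dict[int, float]:
    """Mean frame-to-frame vertex step length (px/frame) per id."""
    out = {}
    for i, path in traj.items():
        ok = ~np.isnan(path[:, 0])
        pts = path[ok]
        if len(pts) < 2:
            out[i] = 0.0
        else:
            out[i] = float(np.mean(np.hypot(*np.diff(pts, axis=0).T)))
    return out


def filter_by_velocity(stack: LabelStack,
                       trajectories: dict[int, np.ndarray] | None = None,
                       factor: float = 3.0) -> LabelStack:
    """Drop ids whose mean vertex speed exceeds ``factor`` times the
    population median speed (contaminants move much faster than cells)."""
    out = stack.copy()
    if trajectories is None:
        trajectories = vertex_trajectories(stack)
    speeds = mean_speeds(trajectories)
    if len(speeds) < 2:
        warnings.warn("velocity filter needs a population; no-op",
                      stacklevel=2)
        return out
    if not np.isfinite(factor):
        return out
    median = float(np.median(list(speeds.values())))
    for i, s in speeds.items():
        if s > factor * median:
            log.info("id %d removed by velocity filter: %.2f px/frame "
                     "(median %.2f)", i, s, median)
            out.frames[out.frames == i] = 0
    return out


def filter_border(stack: LabelStack) -> LabelStack:
    """Drop ids whose mask touches the image border in any frame (cells
    entering or leaving the field of view)."""
    out = stack.copy()
    border_ids: set[int] = set()
    for frame in out.frames:
        edge = np.concatenate([frame[0], frame[-1], frame[:, 0], frame[:, -1]])
        border_ids |= {int(i) for i in np.unique(edge) if i > 0}
    for i in border_ids:
        log.info("id %d removed: touches the field-of-view border", i)
        out.frames[out.frames == i] = 0
    return out


# ---------------------------------------------------------------------------
# Detection quality


def _instances(frame: np.ndarray) -> list[np.ndarray]:
    return [frame == i for i in np.unique(frame) if i > 0]


def _frame_ap(pred: np.ndarray, truth: np.ndarray, thr: float) -> float:
    p_inst = _instances(pred)
    t_inst = _instances(truth)
    if not p_inst and not t_inst:
        log.info("empty prediction and truth: AP 1.0 by convention")
        return 1.0
    ious = np.zeros((len(p_inst), len(t_inst)))
    for a, pm in enumerate(p_inst):
        for b, tm in enumerate(t_inst):
            inter = np.logical_and(pm, tm).sum()
            if inter:
                ious[a, b] = inter / np.logical_or(pm, tm).sum()
    # greedy matching, best IoU first
    tp = 0
    used_p: set[int] = set()
    used_t: set[int] = set()
    order = np.dstack(np.unravel_index(np.argsort(-ious, axis=None),
                                       ious.shape))[0]
    for a, b in order:
        if ious[a, b] < thr:
            break
        if a in used_p or b in used_t:
            continue
        used_p.add(a)
        used_t.add(b)
        tp += 1
    fp = len(p_inst) - tp
    fn = len(t_inst) - tp
    return tp / (tp + fp + fn)


def evaluate_detection(pred, truth, iou_threshold: float = 0.8) -> float:
    """Instance-detection average precision at one IoU threshold.

    Accepts single label frames (2D) or stacks (3D; the mean over frames
    is returned).  Per frame, predictions are greedily matched to truth
    instances at the threshold and AP = TP / (TP + FP + FN).
    """
    pred = pred.frames if isinstance(pred, LabelStack) else np.asarray(pred)
    truth = truth.frames if isinstance(truth, LabelStack) else np.asarray(truth)
    if pred.shape != truth.shape:
        raise ValueError("prediction and truth must share a shape")
    if pred.ndim == 2:
        return _frame_ap(pred, truth, iou_threshold)
    return float(np.mean([_frame_ap(p, t, iou_threshold)
                          for p, t in zip(pred, truth)]))
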