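"""Classical segmentation baseline and training-support functions.

The semantic segmenter proper is pluggable: any callable mapping a gray
frame to a stack of per-class probability grids can drive the pipeline
(``probabilities_to_index_map`` turns its output into an index map).
This module ships everything around that plug point: display
preprocessing (Fourier background removal + CLAHE), a Sobel baseline,
consolidation of layered annotations into a single index map, the
edge-weighted loss map used to train boundary-aware segmenters, and
paired geometric augmentation.

Index-map legend (class codes used throughout the package):
    0 background, 1 contaminant, 2 cell, 3 cell-contaminant overlap,
    4 cell edge.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import exposure, filters, morphology, transform

log = logging.getLogger(__name__)

CLASS_BACKGROUND = 0
CLASS_CONTAMINANT = 1
CLASS_CELL = 2
CLASS_OVERLAP = 3
CLASS_EDGE = 4

INDEX_LEGEND = {
    CLASS_BACKGROUND: "background",
    CLASS_CONTAMINANT: "contaminant",
    CLASS_CELL: "cell",
    CLASS_OVERLAP: "cell-contaminant overlap",
    CLASS_EDGE: "cell edge",
}

EDGE_WIDTH_PX = 2  # annotated cell contours are two pixels wide


@dataclass
class PreprocessParams:
    """Display/baseline preprocessing parameters.

    clip_limit: CLAHE clipping limit (fraction, 0..1).
    kernel_frac: CLAHE kernel size as a fraction of each image dimension.
    fourier_cutoff: radius (cycles/image) below which spatial frequencies
        are treated as background and removed (DC is kept).
    """

    clip_limit: float = 0.02
    kernel_frac: float = 1.0 / 8.0
    fourier_cutoff: float = 4.0

    def __post_init__(self) -> None:
        if not 0 < self.clip_limit < 1:
            raise ValueError("clip_limit must be in (0, 1)")
        if not 0 < self.kernel_frac <= 1:
            raise ValueError("kernel_frac must be in (0, 1]")


@dataclass
class WeightMapParams:
    """Parameters of the exponential edge-weight map: w0 scales the
    amplification, sigma (pixels) its spatial decay."""

    w0: float = 10.0
    sigma: float = 5.0

    def __post_init__(self) -> None:
        if self.w0 < 0:
            raise ValueError("w0 must be >= 0")
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")


def remove_background(img: np.ndarray, cutoff: float = 4.0) -> np.ndarray:
    """Fourier background removal: drop every spatial frequency whose
    radial index (cycles/image) is below ``cutoff``, keeping the DC term
    so the mean survives.  A mirror pad suppresses the spectral leakage
    of non-periodic trends at the image borders."""
    img = np.asarray(img, dtype=float)
    h, w = img.shape
    padded = np.pad(img, ((0, h), (0, w)), mode="symmetric")
    f = np.fft.fft2(padded)
    fr = np.fft.fftfreq(2 * h)[:, None] * h  # cycles per original image
    fc = np.fft.fftfreq(2 * w)[None, :] * w
    radius = np.hypot(fr, fc)
    mask = (radius >= cutoff) | (radius == 0)
    return np.real(np.fft.ifft2(f * mask))[:h, :w]


def preprocess_frame(frame: np.ndarray,
                     params: PreprocessParams | None = None) -> np.ndarray:
    """Remove the low-frequency background and equalize local contrast.

    Intended for display and for the classical baseline only; learned
    segmenters are expected to consume raw frames.  Output is rescaled to
    the input's value range and dtype.
    """
    params = params or PreprocessParams()
    if frame.ndim != 2:
        raise ValueError("preprocess_frame expects a single 2D frame")
    img = frame.astype(float)
    lo, hi = img.min(), img.max()
    if hi == lo:
        return frame.copy()

    img = remove_background(img, params.fourier_cutoff)

    span = img.max() - img.min()
    if span > 0:
        norm = (img - img.min()) / span
        kernel = (max(1, int(round(frame.shape[0] * params.kernel_frac))),
                  max(1, int(round(frame.shape[1] * params.kernel_frac))))
        norm = exposure.equalize_adapthist(norm, kernel_size=kernel,
                                           clip_limit=params.clip_limit)
        img = norm * (hi - lo) + lo
    return img.astype(frame.dtype) if np.issubdtype(frame.dtype, np.integer) \
        else img


def sobel_segment(frame: np.ndarray, min_object_px: int = 30) -> np.ndarray:
    """Gradient-based foreground mask: Sobel magnitude, Otsu threshold,
    morphological closing, hole filling, small-object removal.

    This is the classical baseline: it finds isolated objects but cannot
    separate touching cells nor tell contaminants from cells, which is
    what motivates a learned segmenter upstream.
    """
    if frame.ndim != 2:
        raise ValueError("sobel_segment expects a single 2D frame")
    grad = filters.sobel(frame.astype(float))
    thr = filters.threshold_otsu(grad)
    edges = grad > thr
    # A texture-free frame has no coherent edges; Otsu then splits the
    # noise floor in half.  Treat a majority-foreground split as "no
    # objects" rather than closing noise into fake blobs.
    if edges.mean() > 0.25:
        return np.zeros_like(edges)
    closed = ndimage.binary_closing(edges, structure=morphology.disk(3))
    filled = ndimage.binary_fill_holes(closed)
    lab, _n = ndimage.label(filled)
    sizes = np.bincount(lab.ravel())
    keep = sizes >= min_object_px
    keep[0] = False
    return keep[lab]


def consolidate_annotations(
    layers: list[tuple[str, np.ndarray]],
) -> np.ndarray:
    """Merge tagged binary annotation layers into a single index map.

    ``layers`` is a list of (tag, mask) pairs with tag in {"cell",
    "contaminant"}; several layers may share a tag (one layer per
    annotated cell is common).  Precedence: overlap > cell > contaminant
    > background; the cell-edge class is a two-pixel-wide inner contour
    band of the cell union.  A pixel claimed by two disjoint cell layers
    goes to the smaller-area claimant (logged).
    """
    if not layers:
        raise ValueError("no annotation layers given")
    shape = layers[0][1].shape
    for tag, mask in layers:
        if mask.shape != shape:
            raise ValueError("annotation layers must share one shape")
        if tag not in ("cell", "contaminant"):
            raise ValueError(f"unknown layer tag {tag!r}")

    cell_layers = [np.asarray(m, bool) for t, m in layers if t == "cell"]
    cont_layers = [np.asarray(m, bool) for t, m in layers if t == "contaminant"]

    # Resolve double-claimed cell pixels toward the smaller claimant.
    if len(cell_layers) > 1:
        areas = [m.sum() for m in cell_layers]
        order = np.argsort(areas)  # smaller first keeps its pixels
        claimed = np.zeros(shape, bool)
        resolved = []
        for idx in order:
            m = cell_layers[idx] & ~claimed
            lost = cell_layers[idx].sum() - m.sum()
            if lost:
                log.info("cell layer %d: %d px reassigned to a smaller "
                         "claimant", idx, lost)
            claimed |= m
            resolved.append((idx, m))
        cell_layers = [m for _, m in sorted(resolved)]

    cells = np.zeros(shape, bool)
    for m in cell_layers:
        cells |= m
    conts = np.zeros(shape, bool)
    for m in cont_layers:
        conts |= m

    out = np.zeros(shape, dtype=np.uint8)
    out[conts] = CLASS_CONTAMINANT
    out[cells] = CLASS_CELL
    out[cells & conts] = CLASS_OVERLAP
    edge = cells & ~ndimage.binary_erosion(cells, iterations=EDGE_WIDTH_PX)
    out[edge & (out == CLASS_CELL)] = CLASS_EDGE
    return out


def make_weight_map(cell_labels: np.ndarray,
                    params: WeightMapParams | None = None) -> np.ndarray:
    """Edge-amplified loss-weight map.

    Base weight 1 everywhere plus ``w0 * exp(-D^2 / sigma^2)`` where D is
    the Euclidean distance to the nearest cell-edge pixel; the edge set is
    the full boundary of every cell mask, not just contact zones, which
    sharpens the learned boundary between adjacent cells.
    """
    params = params or WeightMapParams()
    labels = np.asarray(cell_labels)
    if not np.any(labels > 0):
        warnings.warn("weight map requested for a frame with no cells; "
                      "returning uniform weights", stacklevel=2)
        return np.ones(labels.shape, dtype=float)
    edge = np.zeros(labels.shape, bool)
    for lab in np.unique(labels):
        if lab == 0:
            continue
        m = labels == lab
        edge |= m & ~ndimage.binary_erosion(m)
    dist = ndimage.distance_transform_edt(~edge)
    return 1.0 + params.w0 * np.exp(-(dist ** 2) / params.sigma ** 2)


# ---------------------------------------------------------------------------
# Paired geometric augmentation


def _swirl_pair(gray, ann, rng):
    strength = rng.uniform(1.0, 3.0)
    radius = min(gray.shape) * rng.uniform(0.4, 0.9)
    center = (rng.uniform(0.3, 0.7) * gray.shape[1],
              rng.uniform(0.3, 0.7) * gray.shape[0])
    kw = dict(center=center, strength=strength, radius=radius,
              preserve_range=True)
    g = transform.swirl(gray.astype(float), order=1, **kw)
    a = transform.swirl(ann.astype(float), order=0, **kw)
    return g, a


def _warp_pair(gray, ann, rng):
    """Smooth random displacement field, order-1 for gray / order-0 for
    annotations so class labels never blend."""
    shape = gray.shape
    coarse = rng.normal(0, 1, size=(2, 5, 5))
    disp = np.stack([
        transform.resize(coarse[i], shape, order=3, mode="reflect")
        for i in range(2)
    ]) * 0.03 * min(shape)
    rr, cc = np.mgrid[0:shape[0], 0:shape[1]].astype(float)
    coords = np.stack([rr + disp[0], cc + disp[1]])
    g = ndimage.map_coordinates(gray.astype(float), coords, order=1,
                                mode="reflect")
    a = ndimage.map_coordinates(ann, coords, order=0, mode="reflect")
    return g, a


def augment_pair(gray: np.ndarray, annotation: np.ndarray,
                 ops: set[str] | list[str] = ("crop", "rotation", "reflection"),
                 seed: int = 0,
                 crop_frac: float = 0.75) -> tuple[np.ndarray, np.ndarray]:
    """Apply one random geometric transform per requested op to the
    image/annotation pair, identically to both.

    Annotations are always resampled nearest-neighbor.  Rotations are
    drawn from {90, 180, 270} degrees so they are lossless on the class
    grid; warp and swirl provide the continuous distortions.
    Deterministic under ``seed``.
    """
    if gray.shape != annotation.shape:
        raise ValueError("image and annotation must share a shape")
    rng = np.random.default_rng(seed)
    g = gray.copy()
    a = annotation.copy()
    for op in ("crop", "rotation", "reflection", "warp", "swirl"):
        if op not in ops:
            continue
        if op == "crop":
            ch = int(round(g.shape[0] * crop_frac))
            cw = int(round(g.shape[1] * crop_frac))
            if ch > g.shape[0] or cw > g.shape[1] or ch < 1 or cw < 1:
                raise ValueError("crop window larger than image")
            r0 = rng.integers(0, g.shape[0] - ch + 1)
            c0 = rng.integers(0, g.shape[1] - cw + 1)
            g = g[r0:r0 + ch, c0:c0 + cw]
            a = a[r0:r0 + ch, c0:c0 + cw]
        elif op == "rotation":
            k = int(rng.integers(1, 4))
            g = np.rot90(g, k)
            a = np.rot90(a, k)
        elif op == "reflection":
            axis = int(rng.integers(0, 2))
            g = np.flip(g, axis=axis)
            a = np.flip(a, axis=axis)
        elif op == "warp":
            gf, a = _warp_pair(g, a, rng)
            g = gf.astype(gray.dtype) if np.issubdtype(gray.dtype, np.integer) else gf
        elif op == "swirl":
            gf, a = _swirl_pair(g, a, rng)
            g = gf.astype(gray.dtype) if np.issubdtype(gray.dtype, np.integer) else gf
    return np.ascontiguousarray(g), np.ascontiguousarray(a).astype(annotation.dtype)


def probabilities_to_index_map(prob_stack: np.ndarray) -> np.ndarray:
    """Per-pixel argmax over a (n_classes, H, W) probability stack.

    Ties go to the lower class index, which favors background (class 0)
    on fully ambiguous pixels.
    """
    probs = np.asarray(prob_stack, dtype=float)
    if probs.ndim != 3 or probs.shape[0] == 0:
        raise ValueError("expected a non-empty (n_classes, H, W) stack")
    if not np.all(np.isfinite(probs)):
        raise ValueError("probabilities must be finite")
    return np.argmax(probs, axis=0).astype(np.uint8)
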