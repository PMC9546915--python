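"""Reading and writing the package's on-disk formats.

Image stacks travel as multi-page TIFF (gray frames 8/16-bit, label
stacks 16-bit integer); index-map legends as JSON sidecars; property
tables as CSV.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import tifffile


def read_stack(path) -> np.ndarray:
    """Read a multi-page TIFF (or a directory of single-page TIFFs in
    name order) as a (T, H, W) array."""
    path = Path(path)
    if path.is_dir():
        frames = [tifffile.imread(p) for p in sorted(path.glob("*.tif*"))]
        if not frames:
            raise FileNotFoundError(f"no TIFF frames in {path}")
        return np.stack(frames)
    arr = tifffile.imread(path)
    if arr.ndim == 2:
        arr = arr[None]
    return arr


def write_stack(path, stack: np.ndarray, as_labels: bool = False) -> None:
    """Write a (T, H, W) stack as multi-page TIFF; label stacks are
    stored 16-bit."""
    stack = np.asarray(stack)
    if as_labels:
        if stack.max() > np.iinfo(np.uint16).max:
            raise ValueError("label values exceed 16-bit range")
        stack = stack.astype(np.uint16)
    tifffile.imwrite(Path(path), stack)


def write_index_map(path, index_map: np.ndarray, legend: dict) -> None:
    """Write an index map as 8-bit TIFF with its legend in a JSON
    sidecar next to it."""
    path = Path(path)
    tifffile.imwrite(path, index_map.astype(np.uint8))
    sidecar = path.with_suffix(".json")
    with open(sidecar, "w") as fh:
        json.dump({str(k): v for k, v in legend.items()}, fh, indent=2)


def read_index_map(path) -> tuple[np.ndarray, dict]:
    path = Path(path)
    grid = tifffile.imread(path)
    sidecar = path.with_suffix(".json")
    legend = {}
    if sidecar.exists():
        with open(sidecar) as fh:
            legend = {int(k): v for k, v in json.load(fh).items()}
    return grid, legend
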