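"""Vessel centerline extraction from a binary segmentation mask.

A binary vessel mask is thinned to a one-pixel skeleton, bifurcation and
crossover pixels are removed by counting 8-neighbors, and the remaining
connected components are traced into ordered, junction-free centerline
segments. Short spurs left over from thinning are pruned.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.morphology import skeletonize as _thin

__all__ = [
    "CenterlineSegment",
    "skeletonize",
    "split_at_junctions",
    "extract_segments",
    "prune_short_segments",
    "extract_centerline_segments",
    "neighbor_counts",
]

# 3x3 kernel counting 8-neighbors (center excluded)
_NEIGHBOR_KERNEL = np.array([[1, 1, 1], [1, 0, 1], [1, 1, 1]], dtype=np.uint8)
_CONN8 = np.ones((3, 3), dtype=int)


@dataclass(frozen=True)
class CenterlineSegment:
    """Ordered 8-connected pixel path between two endpoints.

    ``points`` is an (n, 2) integer array of (row, col) coordinates, ordered
    from one endpoint to the other; consecutive points are 8-adjacent.
    """

    id: int
    points: np.ndarray = field(repr=False)

    def __len__(self) -> int:
        return len(self.points)


def _validate_mask(mask: np.ndarray) -> np.ndarray:
    arr = np.asarray(mask)
    if arr.ndim != 2:
        raise ValueError(f"mask must be 2D, got {arr.ndim}D")
    if arr.dtype == bool:
        return arr
    if np.issubdtype(arr.dtype, np.integer) and np.isin(arr, (0, 1)).all():
        return arr.astype(bool)
    raise ValueError("mask must be boolean (or 0/1 integer)")


def neighbor_counts(grid: np.ndarray) -> np.ndarray:
    """Number of true 8-neighbors of every pixel (0 outside the grid)."""
    return ndimage.convolve(
        grid.astype(np.uint8), _NEIGHBOR_KERNEL, mode="constant", cval=0
    ) * grid


def skeletonize(mask: np.ndarray) -> np.ndarray:
    """Thin a binary vessel mask to a one-pixel-wide, 8-connected skeleton.

    Uses morphological thinning of the Zhang-Suen family; every skeleton
    pixel lies inside the mask and the connectivity of each mask component
    is preserved.
    """
    mask = _validate_mask(mask)
    if not mask.any():
        return np.zeros_like(mask, dtype=bool)
    return _thin(mask).astype(bool)


def split_at_junctions(skel: np.ndarray) -> np.ndarray:
    """Remove bifurcation/crossover pixels (>= 3 true 8-neighbors).

    After removal every remaining pixel has at most 2 neighbors, so each
    connected component is a simple path or a closed loop. Idempotent.
    """
    skel = _validate_mask(skel)
    return skel & (neighbor_counts(skel) < 3)


def _trace_path(component_points: np.ndarray) -> np.ndarray | None:
    """Order the pixels of a degree-<=2 component from endpoint to endpoint.

    Returns None for closed loops (no endpoint) or isolated pixels.
    """
    pts = [tuple(p) for p in component_points]
    if len(pts) < 2:
        return None
    ptset = set(pts)
    adj = {}
    for r, c in pts:
        nb = []
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                if dr == 0 and dc == 0:
                    continue
                q = (r + dr, c + dc)
                if q in ptset:
                    nb.append(q)
        adj[(r, c)] = nb
    endpoints = sorted(p for p, nb in adj.items() if len(nb) == 1)
    if not endpoints:
        return None  # closed loop
    start = endpoints[0]
    path = [start]
    prev = None
    cur = start
    while True:
        nxt = [q for q in adj[cur] if q != prev]
        if not nxt:
            break
        prev, cur = cur, nxt[0]
        path.append(cur)
    if len(path) != len(pts):  # not a simple path (should not occur)
        return None
    return np.array(path, dtype=int)


def extract_segments(skel: np.ndarray) -> list[CenterlineSegment]:
    """Trace each junction-free skeleton component into an ordered segment.

    Isolated single pixels and closed loops are discarded (loops with a
    warning): only endpoint-bounded simple paths constitute vessel segments.
    """
    skel = _validate_mask(skel)
    labels, n = ndimage.label(skel, structure=_CONN8)
    segments: list[CenterlineSegment] = []
    seg_id = 0
    for lab in range(1, n + 1):
        component = np.argwhere(labels == lab)
        if len(component) < 2:
            continue
        path = _trace_path(component)
        if path is None:
            warnings.warn(
                f"discarding non-path skeleton component of {len(component)} "
                "pixels (closed loop)",
                stacklevel=2,
            )
            continue
        segments.append(CenterlineSegment(id=seg_id, points=path))
        seg_id += 1
    return segments


def prune_short_segments(
    segments: list[CenterlineSegment], min_len: int = 10
) -> list[CenterlineSegment]:
    """Drop spur segments shorter than ``min_len`` pixels (strict)."""
    return [s for s in segments if len(s) >= min_len]


def extract_centerline_segments(
    mask: np.ndarray, min_len: int = 10
) -> list[CenterlineSegment]:
    """Full centerline stage: thin, remove junctions, trace, prune."""
    return prune_short_segments(
        extract_segments(split_at_junctions(skeletonize(mask))), min_len
    )
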