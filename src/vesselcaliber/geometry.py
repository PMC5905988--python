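"""Centerline segment smoothing by least-squares cubic splines.

Pixel-discrete centerlines give unreliable derivatives, so each segment is
approximated by a planar least-squares cubic spline under centripetal
parametrization. The spline's first derivative supplies the vessel tangent
and, rotated by +90 degrees, the normal along which cross-section profiles
are sampled.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import make_lsq_spline

from .centerline import CenterlineSegment

__all__ = ["SmoothedSegment", "fit_spline", "normals_at"]

#: spline pieces are sized so each covers about this many centerline pixels
PIXELS_PER_PIECE = 20


@dataclass(frozen=True)
class SmoothedSegment:
    """Spline-smoothed centerline with per-sample tangents and normals.

    ``samples`` is an (n, 2) float array of (x, y) positions (x = column,
    y = row); ``tangents`` and ``normals`` are unit (x, y) vectors. One
    sample per original centerline point.
    """

    segment_id: int
    samples: np.ndarray = field(repr=False)
    tangents: np.ndarray = field(repr=False)
    normals: np.ndarray = field(repr=False)
    n_pieces: int = 1

    def __len__(self) -> int:
        return len(self.samples)


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def n_spline_pieces(n_points: int, pixels_per_piece: int = PIXELS_PER_PIECE) -> int:
    """Number of cubic pieces: segment length / 20 px, rounded, floor 1."""
    return max(1, _round_half_up(n_points / pixels_per_piece))


def fit_spline(segment: CenterlineSegment) -> SmoothedSegment:
    """Least-squares cubic spline approximation of a centerline segment.

    The ordered (row, col) points are parametrized with the centripetal
    scheme (parameter increments proportional to the square root of chord
    length) and fitted by a piecewise cubic with interior knots at parameter
    quantiles; the piece count is the point count divided by 20 px, rounded
    (minimum 1). Exact duplicate consecutive points are dropped before
    parametrization. Raises ValueError for segments of fewer than 4 points.
    """
    pts = np.asarray(segment.points, dtype=float)
    # (row, col) -> (x, y)
    xy = pts[:, ::-1].copy()
    keep = np.ones(len(xy), dtype=bool)
    keep[1:] = (np.diff(xy, axis=0) != 0).any(axis=1)
    xy = xy[keep]
    n = len(xy)
    if n < 4:
        raise ValueError(f"segment {segment.id}: need >= 4 distinct points, got {n}")

    chords = np.linalg.norm(np.diff(xy, axis=0), axis=1)
    t = np.concatenate([[0.0], np.cumsum(np.sqrt(chords))])

    n_pieces = n_spline_pieces(n)
    # cubic LSQ needs at least n_pieces + 3 data sites
    n_pieces = min(n_pieces, n - 3)
    interior = np.quantile(t, np.linspace(0, 1, n_pieces + 1))[1:-1]
    knots = np.concatenate([[t[0]] * 4, interior, [t[-1]] * 4])
    spline = make_lsq_spline(t, xy, knots, k=3)

    samples = spline(t)
    deriv = spline.derivative()(t)
    norms = np.linalg.norm(deriv, axis=1)
    # guard against a vanishing derivative (degenerate fit): fall back to
    # finite differences of the sampled curve
    bad = norms < 1e-12
    if bad.any():
        fd = np.gradient(samples, axis=0)
        deriv[bad] = fd[bad]
        norms = np.linalg.norm(deriv, axis=1)
        norms[norms < 1e-12] = 1.0
    tangents = deriv / norms[:, None]
    normals = np.column_stack([-tangents[:, 1], tangents[:, 0]])
    return SmoothedSegment(
        segment_id=segment.id,
        samples=samples,
        tangents=tangents,
        normals=normals,
        n_pieces=n_pieces,
    )


def normals_at(smoothed: SmoothedSegment) -> list[tuple[np.ndarray, np.ndarray]]:
    """Per-sample (point, unit normal) pairs.

    The normal is the tangent rotated by +90 degrees ((tx, ty) -> (-ty, tx));
    profiles are sampled symmetrically so the sign convention is immaterial
    to the measurements.
    """
    return [(p, n) for p, n in zip(smoothed.samples, smoothed.normals)]
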