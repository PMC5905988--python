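"""Cross-section intensity profiles and vessel-extent determination.

Profiles are sampled on the green channel along the centerline normals at
1 px spacing with bilinear interpolation, stacked into a straightened
vessel image, and their useful extent (the vessel region) is found by peak
search on smoothed mean profiles. The search is central-light-reflex (CLR)
aware: a vessel with CLR shows a W-shaped profile (central maximum flanked
by two minima and two limiting maxima) instead of a single dip, and a set
of validity rules guards against false CLR detections. Finally the
straightened segment is smoothed with an anisotropic Gaussian whose spreads
scale with the determined profile length.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage, signal

__all__ = [
    "IntensityProfile",
    "StraightenedSegment",
    "ProfileLimits",
    "ClrRuleConfig",
    "sample_profile",
    "initial_half_length",
    "smoothed_mean_profile",
    "find_extrema",
    "determine_limits",
    "segment_profile_length",
    "cut_profiles",
    "smooth_straightened",
]


@dataclass(frozen=True)
class IntensityProfile:
    """1D cross-section of intensities at 1 px spacing, centered on the
    centerline point (odd sample count, center at index (len-1)/2)."""

    values: np.ndarray = field(repr=False)
    center_index: int = 0
    segment_id: int = -1
    point_index: int = -1
    outside: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if len(v) % 2 == 1 and self.center_index != (len(v) - 1) // 2:
            raise ValueError("center_index must be (len-1)/2 for odd profiles")

    def __len__(self) -> int:
        return len(self.values)

    @property
    def outside_fraction(self) -> float:
        if self.outside is None:
            return 0.0
        return float(np.mean(self.outside))


@dataclass(frozen=True)
class StraightenedSegment:
    """Stack of a segment's profiles, one row per centerline point,
    aligned by their center indices (a straightened vessel image)."""

    rows: list[IntensityProfile]

    def __post_init__(self):
        lengths = {len(r) for r in self.rows}
        if len(lengths) > 1:
            raise ValueError("all profile rows must have the same length")

    def __len__(self) -> int:
        return len(self.rows)

    @property
    def center_index(self) -> int:
        return self.rows[0].center_index

    def as_array(self) -> np.ndarray:
        return np.vstack([r.values for r in self.rows])


@dataclass(frozen=True)
class ProfileLimits:
    """Detected vessel extent on one profile.

    ``x_maxL``/``x_maxR`` are the positions (sample-index units) of the
    limiting maxima, ``x_center`` the central extremum (the CLR peak when
    ``is_clr``, otherwise the central minimum), and ``prof_length`` the
    vessel extent 2 * mean(|x_maxL - x_center|, |x_maxR - x_center|).
    """

    is_clr: bool
    x_maxL: float
    x_maxR: float
    x_center: float
    prof_length: float
    fallback: bool = False

    def __post_init__(self):
        if not (self.x_maxL < self.x_center < self.x_maxR):
            raise ValueError("limits must straddle the central extremum")
        if self.prof_length <= 0:
            raise ValueError("prof_length must be positive")


@dataclass(frozen=True)
class ClrRuleConfig:
    """Thresholds of the CLR / non-CLR validity rules.

    The rules were tuned by experimentation in the original method and the
    exact values are unpublished; these defaults are engineering choices and
    every one is overridable.
    """

    #: minimum separation (px) of the two CLR minima
    min_minima_separation: float = 3.0
    #: max relative difference of the two CLR bump depths
    max_bump_depth_ratio: float = 0.5
    #: max relative difference of the two center-to-limit distances
    max_limit_distance_difference: float = 0.5
    #: limits may be at most this fraction of the initial half-length out
    max_limit_distance: float = 0.8
    #: CLR-center override: "close in value to the lowest maximum", as a
    #: fraction of the profile dynamic range
    center_value_tolerance: float = 0.1
    #: CLR-center override: "not too far from the profile center", as a
    #: fraction of the profile length
    max_center_offset_fraction: float = 0.25
    #: non-CLR limits closer than this (px) to the center are "too close"
    min_limit_center_distance: float = 1.5

    def __post_init__(self):
        for f in (
            "min_minima_separation",
            "max_bump_depth_ratio",
            "max_limit_distance_difference",
            "max_limit_distance",
            "center_value_tolerance",
            "max_center_offset_fraction",
            "min_limit_center_distance",
        ):
            if getattr(self, f) <= 0:
                raise ValueError(f"{f} must be strictly positive")


def sample_profile(
    green: np.ndarray,
    point: tuple[float, float],
    normal: np.ndarray,
    half_len: int,
    segment_id: int = -1,
    point_index: int = -1,
) -> IntensityProfile:
    """Sample ``2*half_len + 1`` intensities along the normal at 1 px spacing.

    ``point`` is (x, y); sampling positions are point + k*normal for
    k = -half_len..half_len, bilinearly interpolated. Samples outside the
    image take the nearest-edge value and are flagged in ``outside``.
    """
    green = np.asarray(green, dtype=float)
    x0, y0 = float(point[0]), float(point[1])
    nrows, ncols = green.shape
    if not (0 <= x0 <= ncols - 1 and 0 <= y0 <= nrows - 1):
        raise ValueError(f"profile center ({x0}, {y0}) outside image")
    if half_len < 1:
        raise ValueError("half_len must be >= 1")
    k = np.arange(-half_len, half_len + 1, dtype=float)
    xs = x0 + k * float(normal[0])
    ys = y0 + k * float(normal[1])
    values = ndimage.map_coordinates(green, [ys, xs], order=1, mode="nearest")
    outside = (xs < 0) | (xs > ncols - 1) | (ys < 0) | (ys > nrows - 1)
    return IntensityProfile(
        values=values,
        center_index=half_len,
        segment_id=segment_id,
        point_index=point_index,
        outside=outside,
    )


def initial_half_length(mask: np.ndarray) -> int:
    """Initial profile half-length guaranteed to span the widest vessel.

    1.5 times the maximum of the mask's Euclidean distance transform (the
    largest inscribed radius), rounded up.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("mask has no foreground pixels")
    edt = ndimage.distance_transform_edt(mask)
    return int(np.ceil(1.5 * edt.max()))


def _savgol_window(n: int) -> int:
    w = max(5, int(np.ceil(n / 4)))
    if w % 2 == 0:
        w += 1
    return min(w, n if n % 2 == 1 else n - 1)


def smoothed_mean_profile(
    straight: StraightenedSegment, row: int, window: int = 11
) -> np.ndarray:
    """Mean profile over up to ``window`` adjacent rows, Savitzky-Golay
    smoothed.

    The mean runs over ``window//2`` rows on each side of ``row`` (truncated
    at segment ends); smoothing uses polynomial order 2 and a window of the
    smallest odd integer >= max(5, profile length / 4).
    """
    nrows = len(straight)
    if not 0 <= row < nrows:
        raise IndexError(f"row {row} out of range [0, {nrows})")
    half = window // 2
    lo, hi = max(0, row - half), min(nrows, row + half + 1)
    mean = np.mean([straight.rows[i].values for i in range(lo, hi)], axis=0)
    w = _savgol_window(len(mean))
    if w <= 2:
        return mean
    return signal.savgol_filter(mean, window_length=w, polyorder=2)


def find_extrema(profile: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Interior local minima and maxima positions; plateaus report their
    midpoint (possibly half-integer)."""
    x = np.asarray(profile, dtype=float)
    if len(x) < 3:
        raise ValueError("profile must have at least 3 samples")

    def _peaks(v):
        idx, props = signal.find_peaks(v, plateau_size=1)
        if len(idx) == 0:
            return np.array([])
        return (props["left_edges"] + props["right_edges"]) / 2.0

    return _peaks(-x), _peaks(x)


def _value_at(profile: np.ndarray, pos: float) -> float:
    # plateau midpoints are half-integers on a constant run, so the floor
    # sample carries the plateau value
    return float(profile[int(np.floor(pos))])


def _try_clr(
    profile: np.ndarray,
    minima: np.ndarray,
    maxima: np.ndarray,
    center: float,
    half_len: float,
    rules: ClrRuleConfig,
) -> ProfileLimits | None:
    """CLR-region search; None if no valid CLR region contains the center."""
    if len(maxima) == 0 or len(minima) < 2:
        return None
    vals = np.array([_value_at(profile, p) for p in maxima])
    dyn = float(profile.max() - profile.min())

    # CLR center: the lowest maximum (vessel maxima sit below background
    # maxima), unless the maximum closest to the profile center is near in
    # value and not too far away, in which case that one wins
    lowest = maxima[int(np.argmin(vals))]
    closest = maxima[int(np.argmin(np.abs(maxima - center)))]
    x_maxC = lowest
    if closest != lowest:
        near = abs(closest - center) <= rules.max_center_offset_fraction * len(profile)
        close_val = (
            _value_at(profile, closest) - _value_at(profile, lowest)
            <= rules.center_value_tolerance * dyn
        )
        if near and close_val:
            x_maxC = closest

    left_minima = minima[minima < x_maxC]
    right_minima = minima[minima > x_maxC]
    if len(left_minima) == 0 or len(right_minima) == 0:
        return None
    x_minL = left_minima[-1]
    x_minR = right_minima[0]

    # rule: the two minima must not be too close together
    if x_minR - x_minL < rules.min_minima_separation:
        return None

    left_maxima = maxima[maxima < x_minL]
    right_maxima = maxima[maxima > x_minR]
    x_maxL = left_maxima[-1] if len(left_maxima) else None
    x_maxR = right_maxima[0] if len(right_maxima) else None

    # rule: limits must not be too far from the vessel center; a one-sided
    # failure (or a missing one-sided maximum) is repaired by mirroring the
    # valid side symmetrically about the CLR center
    max_d = rules.max_limit_distance * half_len
    ok_l = x_maxL is not None and (x_maxC - x_maxL) <= max_d
    ok_r = x_maxR is not None and (x_maxR - x_maxC) <= max_d
    mirrored_l = mirrored_r = False
    if ok_l and not ok_r:
        x_maxR = 2 * x_maxC - x_maxL
        mirrored_r = True
    elif ok_r and not ok_l:
        x_maxL = 2 * x_maxC - x_maxR
        mirrored_l = True
    elif not (ok_l or ok_r):
        return None

    # the region must contain the profile center
    if not (x_maxL < center < x_maxR):
        return None

    # a mirrored limit has no observed value: it inherits the real side's
    v_maxL = _value_at(profile, x_maxR if mirrored_l else x_maxL)
    v_maxR = _value_at(profile, x_maxL if mirrored_r else x_maxR)

    # rule: the depths of the two CLR bumps must not differ too much
    depth_l = v_maxL - _value_at(profile, x_minL)
    depth_r = v_maxR - _value_at(profile, x_minR)
    if depth_l <= 0 or depth_r <= 0:
        return None
    if abs(depth_l - depth_r) / max(depth_l, depth_r) > rules.max_bump_depth_ratio:
        return None

    # rule: the center-to-limit distances must be similar
    d_l = x_maxC - x_maxL
    d_r = x_maxR - x_maxC
    if abs(d_l - d_r) / max(d_l, d_r) > rules.max_limit_distance_difference:
        return None

    # rule: the CLR elevation must not surpass the vessel limits
    if _value_at(profile, x_maxC) > min(v_maxL, v_maxR):
        return None

    prof_length = 2 * np.mean([d_l, d_r])
    return ProfileLimits(
        is_clr=True,
        x_maxL=float(x_maxL),
        x_maxR=float(x_maxR),
        x_center=float(x_maxC),
        prof_length=float(prof_length),
    )


def _try_non_clr(
    profile: np.ndarray,
    minima: np.ndarray,
    maxima: np.ndarray,
    center: float,
    rules: ClrRuleConfig,
) -> ProfileLimits | None:
    """Plain-vessel search: central minimum with an adjacent maximum on
    each side; missing or too-close maxima are mirrored / searched outward."""
    if len(minima) == 0:
        return None
    x_minC = minima[int(np.argmin(np.abs(minima - center)))]

    def _outward(side_maxima, sign):
        """First maximum, walking outward, at a valid distance from x_minC."""
        for m in side_maxima:
            if sign * (m - x_minC) >= rules.min_limit_center_distance:
                return m
        return None

    left = maxima[maxima < x_minC][::-1]  # nearest first, walking left
    right = maxima[maxima > x_minC]  # nearest first, walking right
    x_maxL = _outward(left, -1)
    x_maxR = _outward(right, +1)
    if x_maxL is None and x_maxR is None:
        return None
    if x_maxL is None:
        x_maxL = 2 * x_minC - x_maxR
    elif x_maxR is None:
        x_maxR = 2 * x_minC - x_maxL
    if not (x_maxL < x_minC < x_maxR):
        return None
    prof_length = 2 * np.mean([x_minC - x_maxL, x_maxR - x_minC])
    return ProfileLimits(
        is_clr=False,
        x_maxL=float(x_maxL),
        x_maxR=float(x_maxR),
        x_center=float(x_minC),
        prof_length=float(prof_length),
    )


def determine_limits(
    profile: np.ndarray,
    rules: ClrRuleConfig | None = None,
    initial_half_len: float | None = None,
) -> ProfileLimits:
    """Detect the vessel extent on a (smoothed mean) profile.

    CLR regions are searched first; if none containing the profile center
    passes the validity rules, a plain vessel region (two maxima adjacent
    to a central minimum) is searched. If neither is found the full profile
    stands in (``fallback=True``) with limits at the profile ends —
    overestimating the extent loses nothing, while underestimating would
    discard vessel information.
    """
    profile = np.asarray(profile, dtype=float)
    rules = rules or ClrRuleConfig()
    n = len(profile)
    center = (n - 1) / 2.0
    half_len = float(initial_half_len) if initial_half_len is not None else center

    if n >= 3 and np.ptp(profile) > 0:
        minima, maxima = find_extrema(profile)
        limits = _try_clr(profile, minima, maxima, center, half_len, rules)
        if limits is not None:
            return limits
        limits = _try_non_clr(profile, minima, maxima, center, rules)
        if limits is not None:
            return limits

    # fallback: limits at the profile ends; 2 * mean of the center-to-end
    # distances equals the sample span n - 1
    return ProfileLimits(
        is_clr=False,
        x_maxL=0.0,
        x_maxR=float(n - 1),
        x_center=center,
        prof_length=float(n - 1),
        fallback=True,
    )


def segment_profile_length(limits: list[ProfileLimits] | np.ndarray) -> float:
    """Per-segment profile length: median of the per-profile lengths
    (mean of the middle two for even counts)."""
    if isinstance(limits, (list, tuple)):
        values = [l.prof_length if isinstance(l, ProfileLimits) else float(l) for l in limits]
    else:
        values = np.asarray(limits, dtype=float)
    if len(values) == 0:
        raise ValueError("no profile lengths to take the median of")
    return float(np.median(values))


def cut_profiles(straight: StraightenedSegment, length: float) -> StraightenedSegment:
    """Cut every row symmetrically about the center to the given length.

    Keeps samples within round(length/2) of the center index, i.e.
    2*round(length/2) + 1 samples per row.
    """
    if length <= 0:
        raise ValueError("cut length must be positive")
    c = straight.center_index
    n = len(straight.rows[0])
    half = int(np.floor(length / 2 + 0.5))  # round half up
    if half > c or c + half > n - 1:
        raise ValueError(
            f"cut length {length} exceeds current profile extent {n - 1}"
        )
    rows = [
        replace(
            r,
            values=r.values[c - half : c + half + 1],
            center_index=half,
            outside=None if r.outside is None else r.outside[c - half : c + half + 1],
        )
        for r in straight.rows
    ]
    return StraightenedSegment(rows=rows)


def smooth_straightened(
    straight: StraightenedSegment,
    prof_length: float,
    sigma_across_factor: float = 0.1,
    sigma_along_factor: float = 1.5,
) -> StraightenedSegment:
    """Anisotropic Gaussian smoothing of the straightened vessel image.

    Spreads scale with the determined profile length so wider vessels are
    smoothed more: sigma = 0.1 * prof_length across the profiles (x) and
    1.5 * prof_length along the vessel (y). Edges are handled by reflection.
    """
    if len(straight) == 0:
        raise ValueError("empty straightened segment")
    arr = straight.as_array()
    smoothed = ndimage.gaussian_filter(
        arr,
        sigma=(sigma_along_factor * prof_length, sigma_across_factor * prof_length),
        mode="reflect",
    )
    rows = [
        replace(r, values=smoothed[i]) for i, r in enumerate(straight.rows)
    ]
    return StraightenedSegment(rows=rows)
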