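"""Home-range estimation and exploration/settling profiling.

Post-release movement is profiled with 100% minimum-convex-polygon areas
over 10-day windows shifted by one day, plus a progressive (cumulative)
MCP series; a range is considered settled on the first day after which
the progressive area stops growing by more than a relative threshold over
a lookahead window.  Settled ranges are summarized as 100%/50% MCPs and
50/95% isopleths of a path-interpolated Gaussian kernel density.
All areas are planar km^2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats
from scipy.spatial import ConvexHull, QhullError

from .telemetry import Track


@dataclass
class RangeProfile:
    """Sliding-window and progressive MCP series for one track."""

    window_areas: list[tuple[int, float]]  # (window start day, 100% MCP km^2)
    progressive_areas: list[tuple[int, float]]  # (day, cumulative 100% MCP km^2)
    settled: Optional[bool] = None
    settling_day: Optional[int] = None
    window_days: int = 10


@dataclass
class RangeEstimate:
    """MCP and kernel areas plus the geometric range centre."""

    mcp100_km2: float
    mcp50_km2: float
    kde95_km2: Optional[float]
    kde50_km2: Optional[float]
    centroid: tuple[float, float]
    n_fixes: int
    insufficient_data: bool = False
    centroid_to_release_km: Optional[float] = None
    last_to_release_km: Optional[float] = None
    unsettled_flag: bool = False


def mcp_area(points: np.ndarray, percent: float = 100.0) -> float:
    """Area (km^2) of the minimum convex polygon of ``points``.

    For ``percent`` < 100 the that fraction of points closest to the
    centroid of all points is retained before the hull is taken.
    Fewer than three distinct/non-collinear points give area 0
    (degenerate case).
    """
    if not (0.0 < percent <= 100.0):
        raise ValueError("percent must be in (0, 100]")
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be (n, 2)")
    if percent < 100.0 and len(pts) > 0:
        centroid = pts.mean(axis=0)
        d = np.hypot(*(pts - centroid).T)
        k = max(1, int(math.ceil(len(pts) * percent / 100.0)))
        pts = pts[np.argsort(d, kind="stable")[:k]]
    if len(pts) < 3:
        return 0.0
    try:
        hull = ConvexHull(pts)
    except QhullError:  # collinear / duplicate points
        return 0.0
    return float(hull.volume)  # 2-D: volume is the polygon area


def range_profile(
    track: Track, window_days: int = 10, min_fixes_per_window: int = 5
) -> RangeProfile:
    """Window and progressive 100% MCP series over the first year.

    Windows [d, d+window) shift by one day; a window enters the series only
    when it holds at least ``min_fixes_per_window`` daily fixes.  The
    progressive series gives, for each fix day, the MCP of all fixes to
    date; it is non-decreasing by construction.
    """
    if len(track) == 0:
        raise ValueError("empty track")
    days = track.day_index
    xy = track.xy
    order = np.argsort(days, kind="stable")
    days, xy = days[order], xy[order]

    last_day = int(days.max())
    window_areas: list[tuple[int, float]] = []
    for start in range(0, min(last_day, 365) - window_days + 2):
        sel = (days >= start) & (days < start + window_days)
        if int(sel.sum()) >= min_fixes_per_window:
            window_areas.append((start, mcp_area(xy[sel])))

    progressive: list[tuple[int, float]] = []
    for i, d in enumerate(days):
        progressive.append((int(d), mcp_area(xy[: i + 1])))
    # one entry per day (the last, i.e. all fixes through that day)
    dedup: dict[int, float] = {}
    for d, a in progressive:
        dedup[d] = a
    progressive = sorted(dedup.items())
    return RangeProfile(window_areas, progressive, window_days=window_days)


def _progressive_at(progressive: Sequence[tuple[int, float]], day: int) -> float:
    """Step-function evaluation of the progressive series at ``day``."""
    area = 0.0
    for d, a in progressive:
        if d <= day:
            area = a
        else:
            break
    return area


def detect_settling(
    profile: RangeProfile,
    lookahead_days: int = 30,
    rel_increase_threshold: float = 0.05,
) -> tuple[Optional[bool], Optional[int]]:
    """First day whose progressive MCP has stopped growing appreciably.

    The settling day is the first fix day d with positive progressive area
    whose area at d + lookahead exceeds the area at d by less than the
    relative threshold.  Returns (False, None) if no such day exists before
    the track end minus the lookahead, and (None, None) — unknown — when
    the track is too short to evaluate any day.
    """
    prog = profile.progressive_areas
    if not prog:
        return None, None
    last_day = prog[-1][0]
    evaluable = [d for d, _ in prog if d + lookahead_days <= last_day]
    if not evaluable:
        return None, None
    for d in evaluable:
        a_now = _progressive_at(prog, d)
        a_later = _progressive_at(prog, d + lookahead_days)
        # inclusive: a zero-growth (e.g. stationary) track settles immediately
        if (a_later - a_now) <= rel_increase_threshold * a_now:
            return True, int(d)
    return False, None


def kernel_home_range(
    track: Track,
    isopleths: Sequence[float] = (50.0, 95.0),
    grid_cells: int = 256,
    min_fixes: int = 30,
    interp_step_km: Optional[float] = None,
    bw_method: str | float = "scott",
) -> dict[float, float]:
    """Isopleth areas (km^2) of a path-interpolated Gaussian kernel density.

    The daily fix sequence is linearly interpolated at a fixed spatial step
    so that the density follows the movement path rather than the point
    cloud alone; isopleth areas are obtained by grid integration, taking
    the smallest set of cells containing the stated probability mass.
    Returns ``{}``-valued ``None`` entries via raising if data are
    insufficient — callers wanting the printed "insufficient data"
    behaviour should catch ``InsufficientDataError``.
    """
    if len(track) < min_fixes:
        raise InsufficientDataError(
            f"{track.individual_id}: {len(track)} fixes < minimum {min_fixes}"
        )
    xy = track.xy
    span = max(np.ptp(xy[:, 0]), np.ptp(xy[:, 1]))
    if span == 0:
        # all fixes identical: both isopleths collapse to (at most) one cell
        return {p: 0.0 for p in isopleths}
    if interp_step_km is None:
        interp_step_km = span / grid_cells

    # subdivide consecutive segments at the fixed step
    pts = [xy[0]]
    for a, b in zip(xy[:-1], xy[1:]):
        seg = np.hypot(*(b - a))
        n = max(1, int(math.ceil(seg / interp_step_km)))
        for k in range(1, n + 1):
            pts.append(a + (b - a) * (k / n))
    path = np.asarray(pts)

    kde = stats.gaussian_kde(path.T, bw_method=bw_method)
    pad = 0.25 * span
    gx = np.linspace(xy[:, 0].min() - pad, xy[:, 0].max() + pad, grid_cells)
    gy = np.linspace(xy[:, 1].min() - pad, xy[:, 1].max() + pad, grid_cells)
    cell_area = (gx[1] - gx[0]) * (gy[1] - gy[0])
    xx, yy = np.meshgrid(gx, gy)
    dens = kde(np.vstack([xx.ravel(), yy.ravel()]))
    mass = dens * cell_area
    mass = mass / mass.sum()

    order = np.argsort(mass)[::-1]
    cum = np.cumsum(mass[order])
    out: dict[float, float] = {}
    for p in isopleths:
        k = int(np.searchsorted(cum, p / 100.0)) + 1
        out[float(p)] = float(k * cell_area)
    return out


class InsufficientDataError(ValueError):
    """Too few fixes for a kernel range (mirrors an 'insufficient data' cell)."""


def summarize_ranges(
    track: Track,
    settling_day: Optional[int],
    release_site: Optional[tuple[float, float]] = None,
    kde_min_fixes: int = 30,
) -> RangeEstimate:
    """Range metrics over the settled portion of a track.

    Range data are the daily fixes after ``settling_day``; when the track
    never settled (``settling_day`` None) all data are used and the result
    is flagged.  The centroid is the mean x,y of the range data; distances
    (centroid -> release, last fix -> release) are planar km.
    """
    days = track.day_index
    xy = track.xy
    if settling_day is not None:
        sel = days >= settling_day
        unsettled = False
    else:
        sel = np.ones(len(days), dtype=bool)
        unsettled = True
    sub = xy[sel]
    if len(sub) == 0:
        raise ValueError("no fixes in range period")
    centroid = (float(sub[:, 0].mean()), float(sub[:, 1].mean()))
    mcp100 = mcp_area(sub, 100.0)
    mcp50 = mcp_area(sub, 50.0)
    sub_track = Track(track.individual_id, track.fixes[sel].reset_index(drop=True),
                      track.release_time)
    try:
        kde = kernel_home_range(sub_track, min_fixes=kde_min_fixes)
        kde50, kde95 = kde.get(50.0), kde.get(95.0)
        insufficient = False
    except InsufficientDataError:
        kde50 = kde95 = None
        insufficient = True

    c2r = l2r = None
    if release_site is not None:
        rx, ry = release_site
        c2r = float(math.hypot(centroid[0] - rx, centroid[1] - ry))
        last = xy[np.argmax(days)]
        l2r = float(math.hypot(last[0] - rx, last[1] - ry))
    return RangeEstimate(
        mcp100_km2=mcp100,
        mcp50_km2=mcp50,
        kde95_km2=kde95,
        kde50_km2=kde50,
        centroid=centroid,
        n_fixes=int(len(sub)),
        insufficient_data=insufficient,
        centroid_to_release_km=c2r,
        last_to_release_km=l2r,
        unsettled_flag=unsettled,
    )
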