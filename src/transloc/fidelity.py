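"""Site fidelity: overlap of daily locations with protected areas.

Fidelity is the percentage of an individual's daily locations in a time
window (default the first 365 days) falling inside the recipient reserve
and inside the union of all protected areas; points on a polygon boundary
count as inside.  Detection bias between sparse VHF and near-daily GPS
monitoring is reported (location counts, gap statistics) rather than
corrected.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import shapely
from shapely.geometry import Point, Polygon

from .telemetry import Track


@dataclass
class FidelityResult:
    pct_reserve: Optional[float]
    pct_all_pa: Optional[float]
    days_within_10km: int
    n_locations: int
    window_days: int
    undefined: bool = False


def _containment_pct(xy: np.ndarray, polygons: Sequence[Polygon]) -> float:
    pts = shapely.points(xy[:, 0], xy[:, 1])
    inside = np.zeros(len(xy), dtype=bool)
    for poly in polygons:
        inside |= shapely.covers(poly, pts)  # covers: boundary counts as inside
    return 100.0 * float(inside.sum()) / len(xy)


def site_fidelity(
    track: Track,
    reserve_polygon: Polygon,
    pa_polygons: Sequence[Polygon] = (),
    window_days: int = 365,
    release_site: Optional[tuple[float, float]] = None,
    near_radius_km: float = 10.0,
) -> FidelityResult:
    """Percent of daily locations inside the reserve and inside any PA.

    ``pa_polygons`` is the full protected-area layer; the reserve itself is
    always included in the union, so pct_all_pa >= pct_reserve.
    """
    days = track.day_index
    sel = days < window_days
    xy = track.xy[sel]
    n = int(len(xy))
    if n == 0:
        return FidelityResult(None, None, 0, 0, window_days, undefined=True)

    pct_reserve = _containment_pct(xy, [reserve_polygon])
    pct_all = _containment_pct(xy, [reserve_polygon, *pa_polygons])

    near = 0
    if release_site is not None:
        sub = Track(track.individual_id, track.fixes[sel].reset_index(drop=True),
                    track.release_time)
        near = days_near_release(sub, release_site, near_radius_km)
    return FidelityResult(pct_reserve, pct_all, near, n, window_days)


def days_near_release(
    track: Track, release_site: tuple[float, float], radius_km: float = 10.0
) -> int:
    """Number of daily locations within ``radius_km`` (inclusive) of the
    release site."""
    rx, ry = release_site
    xy = track.xy
    d = np.hypot(xy[:, 0] - rx, xy[:, 1] - ry)
    return int((d <= radius_km).sum())
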