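"""Homing classification and circular orientation statistics.

An individual homed if its last known location lies the full translocation
distance from the release site within +/-22.5 degrees of the bearing to the
capture site ("true home" = 0 degrees), or if it arrived at the capture
site or the captive facility (radius test, default 5 km).  Cohort
orientation is summarized by the circular mean and SD of the bearing
deviations and by chi-square tests of 90-degree sector counts against
uniformity and of in/out homing-sector counts against the expectation
under universal homing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

HOMING_SECTOR_DEG = 22.5


@dataclass
class HomingResult:
    """Per-individual homing assessment.

    ``bearing_deviation_deg`` is the signed angle in [-180, 180] between the
    release->last-location direction and the release->capture direction;
    ``normalized_distance`` is |release->last| / |release->capture|.
    """

    bearing_deviation_deg: Optional[float]
    normalized_distance: Optional[float]
    homed: Optional[bool]
    returned_to_facility: bool = False
    at_capture_site: bool = False
    unknown: bool = False


@dataclass
class OrientationSummary:
    mean_angle_deg: Optional[float]
    circular_sd_deg: Optional[float]
    sector_counts: list[int]
    chi2_uniform: float
    df_uniform: int
    p_uniform: float
    chi2_homing_sector: float
    p_homing_sector: float
    n: int
    zero_resultant: bool = False


def _signed_angle_deg(a_deg: float) -> float:
    return (a_deg + 180.0) % 360.0 - 180.0


def classify_homing(
    release: tuple[float, float],
    capture: tuple[float, float],
    last_location: Optional[tuple[float, float]],
    facility_location: Optional[tuple[float, float]] = None,
    site_radius_km: float = 5.0,
) -> HomingResult:
    """Classify one individual's homing status (planar km coordinates).

    The bearing-sector boundary is inclusive: |deviation| = 22.5 degrees
    still counts.  A missing last location yields an unknown result.
    """
    rx, ry = release
    cx, cy = capture
    if math.hypot(cx - rx, cy - ry) == 0:
        raise ValueError("release and capture sites coincide")
    if last_location is None:
        return HomingResult(None, None, None, unknown=True)
    lx, ly = last_location

    home_bearing = math.degrees(math.atan2(cy - ry, cx - rx))
    trans_dist = math.hypot(cx - rx, cy - ry)
    move_dist = math.hypot(lx - rx, ly - ry)
    nd = move_dist / trans_dist
    if move_dist == 0:
        deviation = 0.0
    else:
        bearing = math.degrees(math.atan2(ly - ry, lx - rx))
        deviation = _signed_angle_deg(bearing - home_bearing)

    at_capture = math.hypot(lx - cx, ly - cy) <= site_radius_km
    at_facility = (
        facility_location is not None
        and math.hypot(lx - facility_location[0], ly - facility_location[1]) <= site_radius_km
    )
    homed = (
        (abs(deviation) <= HOMING_SECTOR_DEG and nd >= 1.0)
        or at_capture
        or at_facility
    )
    return HomingResult(
        bearing_deviation_deg=deviation,
        normalized_distance=nd,
        homed=bool(homed),
        returned_to_facility=bool(at_facility),
        at_capture_site=bool(at_capture),
    )


def orientation_summary(
    results: Sequence[HomingResult] | Sequence[float],
    n_groups: int = 4,
) -> OrientationSummary:
    """Cohort circular summary of bearing deviations.

    Accepts HomingResult objects or raw deviations in degrees.  Sectors are
    ``n_groups`` equal arcs centred on the true-home direction (0 degrees);
    with the default four groups the sector edges fall at +/-45 and +/-135.
    The uniformity test is a Pearson chi-square of the sector counts; the
    homing-sector test compares in/out counts with the expectation were
    every individual homed (all mass inside the sector), so any out-of-
    sector observation is infinitely surprising under that hypothesis.
    """
    devs = []
    for r in results:
        d = r.bearing_deviation_deg if isinstance(r, HomingResult) else float(r)
        if d is not None:
            devs.append(float(d))
    n = len(devs)
    if n < 4:
        raise ValueError("need at least 4 known directions")
    rad = np.radians(devs)

    C, S = np.cos(rad).sum(), np.sin(rad).sum()
    R = math.hypot(C, S) / n
    if R < 1e-12:
        mean_deg = None
        sd_deg = None
        zero = True
    else:
        mean_deg = _signed_angle_deg(math.degrees(math.atan2(S, C)))
        sd_deg = math.degrees(math.sqrt(max(0.0, -2.0 * math.log(R))))
        zero = False

    # sector counts: n_groups arcs of width 360/n_groups centred on 0
    width = 360.0 / n_groups
    shifted = (np.asarray(devs) + width / 2.0) % 360.0
    sector = (shifted // width).astype(int)
    counts = np.bincount(sector, minlength=n_groups).tolist()

    expected = n / n_groups
    chi2_u = float(((np.array(counts) - expected) ** 2 / expected).sum())
    df_u = n_groups - 1
    p_u = float(stats.chi2.sf(chi2_u, df_u))

    in_sector = int(np.sum(np.abs(devs) <= HOMING_SECTOR_DEG))
    out_sector = n - in_sector
    if out_sector == 0:
        chi2_h, p_h = 0.0, 1.0
    else:
        # expected (n, 0) under all-homed: an occupied zero-expectation cell
        chi2_h, p_h = float("inf"), 0.0
    return OrientationSummary(
        mean_angle_deg=mean_deg,
        circular_sd_deg=sd_deg,
        sector_counts=counts,
        chi2_uniform=chi2_u,
        df_uniform=df_u,
        p_uniform=p_u,
        chi2_homing_sector=chi2_h,
        p_homing_sector=p_h,
        n=n,
        zero_resultant=zero,
    )
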