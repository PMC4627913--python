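"""Reading, validation and standardization of post-release telemetry.

Movement analyses downstream all operate on one location per day, the fix
closest to a configurable anchor time (default 12:00 UTC).  This module turns
raw multi-fix GPS schedules and sparse VHF relocations into that daily series,
removes speed-implausible and low-quality fixes, and quantifies the data gaps
that sparse VHF monitoring leaves behind.

Coordinates are planar kilometres throughout.  Readers optionally accept
longitude/latitude and convert to a local tangent-plane km system (spherical
equirectangular about a reference point) so that all area and distance
arithmetic stays planar.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

EARTH_RADIUS_KM = 6371.0088

FIX_COLUMNS = ["id", "timestamp", "x", "y", "source", "quality"]

SOURCES = {"GPS", "VHF", "observation"}
HABITUATION_CLASSES = ("wild", "semi", "habituated")


class SchemaError(ValueError):
    """A required column is missing from an input table."""


class RowError(ValueError):
    """A row could not be parsed (strict mode only)."""


@dataclass
class Track:
    """Ordered georeferenced fixes for one individual.

    ``fixes`` is a DataFrame with columns ``timestamp`` (tz-aware UTC),
    ``x``, ``y`` (planar km), ``source`` and ``quality``.  After
    :func:`standardize_daily` it additionally carries an integer
    ``day_index`` (days since release, day 0 = release day) with at most
    one fix per day.
    """

    individual_id: str
    fixes: pd.DataFrame
    release_time: Optional[pd.Timestamp] = None

    def __post_init__(self) -> None:
        if not isinstance(self.fixes, pd.DataFrame):
            raise TypeError("fixes must be a DataFrame")
        for col in ("timestamp", "x", "y"):
            if col not in self.fixes.columns:
                raise SchemaError(f"track missing required column {col!r}")
        xy = self.fixes[["x", "y"]].to_numpy(dtype=float)
        if xy.size and not np.all(np.isfinite(xy)):
            raise ValueError(f"{self.individual_id}: non-finite coordinates")

    def __len__(self) -> int:
        return len(self.fixes)

    @property
    def is_daily(self) -> bool:
        return "day_index" in self.fixes.columns

    @property
    def xy(self) -> np.ndarray:
        return self.fixes[["x", "y"]].to_numpy(dtype=float)

    @property
    def day_index(self) -> np.ndarray:
        if not self.is_daily:
            raise ValueError("track not standardized: no day_index")
        return self.fixes["day_index"].to_numpy(dtype=int)


@dataclass
class IndividualRecord:
    """Covariates of one translocated individual (subject table row)."""

    individual_id: str
    sex: str
    habituation: str
    captivity_days: int
    translocation_distance_km: float
    release_mode: str
    transmitter: str
    age_class: Optional[str] = None
    mass_kg: Optional[float] = None
    acclimation_weeks: Optional[float] = None
    social_unit: Optional[str] = None
    capture_site: Optional[tuple[float, float]] = None
    release_site: Optional[tuple[float, float]] = None
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.habituation not in HABITUATION_CLASSES:
            raise ValueError(
                f"{self.individual_id}: habituation {self.habituation!r} not in "
                f"{HABITUATION_CLASSES}"
            )
        if self.captivity_days < 0:
            raise ValueError(f"{self.individual_id}: captivity_days < 0")
        if self.translocation_distance_km <= 0:
            raise ValueError(f"{self.individual_id}: non-positive translocation distance")


@dataclass
class OutcomeRecord:
    """Fate of one translocated individual (outcome table row)."""

    individual_id: str
    known_survival_days: int
    event: str  # "death" | "censored"
    cause: Optional[str] = None
    homed: str = "no"  # "yes" | "no" | "unknown"
    livestock_killed_per_year: int = 0
    litters: list[int] = field(default_factory=list)
    comments: Optional[str] = None
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.known_survival_days <= 0:
            raise ValueError(f"{self.individual_id}: known_survival_days must be > 0")
        if self.event not in ("death", "censored"):
            raise ValueError(f"{self.individual_id}: event {self.event!r}")
        if self.event == "death" and not self.cause:
            raise ValueError(f"{self.individual_id}: death without cause")
        if self.event == "censored" and self.cause in (
            "shot", "hyaena", "accident", "trap",
        ):
            raise ValueError(
                f"{self.individual_id}: death cause {self.cause!r} with event=censored"
            )
        if self.homed not in ("yes", "no", "unknown"):
            raise ValueError(f"{self.individual_id}: homed {self.homed!r}")
        if self.livestock_killed_per_year < 0:
            raise ValueError(f"{self.individual_id}: negative livestock count")

    @property
    def removed_from_wild(self) -> bool:
        return self.cause == "recapture"


@dataclass
class GapReport:
    """Missing-day structure of a standardized daily track."""

    n_gaps: int
    gap_lengths: list[int]
    mean_gap: float

    def __post_init__(self) -> None:
        assert self.n_gaps == len(self.gap_lengths)


# ---------------------------------------------------------------------------
# coordinate handling


def lonlat_to_km(
    lon: np.ndarray, lat: np.ndarray, ref: tuple[float, float]
) -> tuple[np.ndarray, np.ndarray]:
    """Project lon/lat (degrees) onto a local tangent plane in km.

    Spherical equirectangular about ``ref=(lon0, lat0)``; adequate at the
    study scale (hundreds of km) where distortion is well below fix error.
    """
    lon0, lat0 = ref
    x = np.radians(np.asarray(lon) - lon0) * EARTH_RADIUS_KM * math.cos(math.radians(lat0))
    y = np.radians(np.asarray(lat) - lat0) * EARTH_RADIUS_KM
    return x, y


# ---------------------------------------------------------------------------
# readers


def read_fixes(
    path,
    strict: bool = True,
    lonlat: bool = False,
    projection_ref: Optional[tuple[float, float]] = None,
) -> list[Track]:
    """Read a delimited fix table (``id,timestamp,x,y,source,quality``).

    Returns one :class:`Track` per individual, time-sorted.  In lenient
    mode unparseable rows are dropped and counted; strict mode raises a
    :class:`RowError` naming the first offending line.
    """
    df = pd.read_csv(path)
    missing = [c for c in ("id", "timestamp", "x", "y") if c not in df.columns]
    if missing:
        raise SchemaError(f"fix table missing required column(s): {', '.join(missing)}")
    if "source" not in df.columns:
        df["source"] = "GPS"
    if "quality" not in df.columns:
        df["quality"] = np.nan

    ts = pd.to_datetime(df["timestamp"], utc=True, errors="coerce", format="ISO8601")
    bad = ts.isna()
    if bad.any():
        first = int(np.flatnonzero(bad.to_numpy())[0])
        if strict:
            raise RowError(
                f"unparseable timestamp at data row {first + 1}: "
                f"{df['timestamp'].iloc[first]!r}"
            )
        logger.warning("dropping %d unparseable row(s)", int(bad.sum()))
        df = df[~bad].copy()
        ts = ts[~bad]
    df["timestamp"] = ts

    if lonlat:
        if projection_ref is None:
            projection_ref = (float(df["x"].mean()), float(df["y"].mean()))
        df["x"], df["y"] = lonlat_to_km(
            df["x"].to_numpy(float), df["y"].to_numpy(float), projection_ref
        )

    tracks = []
    for ind, sub in df.groupby("id", sort=True):
        sub = sub.sort_values("timestamp").reset_index(drop=True)
        tracks.append(Track(str(ind), sub[["timestamp", "x", "y", "source", "quality"]]))
    if not tracks:
        logger.warning("fix table %s contained no rows", path)
    return tracks


def _opt_float(v):
    return None if pd.isna(v) else float(v)


def read_study_tables(
    path_individuals, path_outcomes
) -> tuple[list[IndividualRecord], list[OutcomeRecord]]:
    """Read the subject and outcome tables (column layouts of the packaged
    ``table1.csv`` / ``table3.csv`` fixtures)."""
    ind_df = pd.read_csv(path_individuals)
    out_df = pd.read_csv(path_outcomes)

    req_ind = [
        "id", "sex", "habituation", "captivity_days",
        "translocation_distance_km", "release_mode", "transmitter",
    ]
    missing = [c for c in req_ind if c not in ind_df.columns]
    if missing:
        raise SchemaError(f"individuals table missing column(s): {', '.join(missing)}")
    req_out = ["id", "known_survival_days", "event"]
    missing = [c for c in req_out if c not in out_df.columns]
    if missing:
        raise SchemaError(f"outcomes table missing column(s): {', '.join(missing)}")

    known = set(req_ind + ["age_class_years", "mass_kg", "acclimation_weeks", "social_unit"])
    individuals = []
    for _, r in ind_df.iterrows():
        individuals.append(
            IndividualRecord(
                individual_id=str(r["id"]),
                sex=str(r["sex"]),
                habituation=str(r["habituation"]),
                captivity_days=int(r["captivity_days"]),
                translocation_distance_km=float(r["translocation_distance_km"]),
                release_mode=str(r["release_mode"]),
                transmitter=str(r["transmitter"]),
                age_class=str(r["age_class_years"]) if "age_class_years" in r else None,
                mass_kg=_opt_float(r.get("mass_kg")),
                acclimation_weeks=_opt_float(r.get("acclimation_weeks")),
                social_unit=str(r["social_unit"]) if "social_unit" in r else None,
                extra={k: r[k] for k in ind_df.columns if k not in known},
            )
        )

    known_out = set(req_out + ["cause", "homed", "livestock_killed_per_year", "litters", "comments"])
    outcomes = []
    for _, r in out_df.iterrows():
        litters_raw = r.get("litters")
        if pd.isna(litters_raw) or str(litters_raw).strip() == "":
            litters: list[int] = []
        else:
            litters = [int(float(t)) for t in str(litters_raw).split(";")]
        cause = r.get("cause")
        outcomes.append(
            OutcomeRecord(
                individual_id=str(r["id"]),
                known_survival_days=int(r["known_survival_days"]),
                event=str(r["event"]),
                cause=None if pd.isna(cause) or str(cause) == "" else str(cause),
                homed=str(r.get("homed", "no")),
                livestock_killed_per_year=int(r.get("livestock_killed_per_year", 0) or 0),
                litters=litters,
                comments=None if pd.isna(r.get("comments")) else str(r.get("comments")),
                extra={k: r[k] for k in out_df.columns if k not in known_out},
            )
        )
    return individuals, outcomes


# ---------------------------------------------------------------------------
# filtering and standardization


def filter_fixes(
    track: Track,
    max_speed_kmh: float = 10.0,
    min_quality: Optional[float] = None,
) -> Track:
    """Remove speed-implausible and low-quality fixes.

    A fix is an outlier when the sustained speed from the previous retained
    fix exceeds ``max_speed_kmh``.  ``quality`` below ``min_quality`` is
    dropped (missing quality is kept).  Removal counts are logged.
    """
    df = track.fixes
    n0 = len(df)
    if min_quality is not None:
        keep_q = df["quality"].isna() | (df["quality"] >= min_quality)
        df = df[keep_q].reset_index(drop=True)
    n_quality = n0 - len(df)

    keep = np.ones(len(df), dtype=bool)
    ts = df["timestamp"].to_numpy()
    xy = df[["x", "y"]].to_numpy(dtype=float)
    last = 0 if len(df) else -1
    for i in range(1, len(df)):
        dt_h = (ts[i] - ts[last]) / np.timedelta64(1, "h")
        dist = float(np.hypot(*(xy[i] - xy[last])))
        if dt_h > 0 and dist / dt_h > max_speed_kmh:
            keep[i] = False
        else:
            last = i
    n_speed = int((~keep).sum())
    if n_quality or n_speed:
        logger.info(
            "%s: removed %d low-quality and %d speed-outlier fixes",
            track.individual_id, n_quality, n_speed,
        )
    return Track(track.individual_id, df[keep].reset_index(drop=True), track.release_time)


def standardize_daily(track: Track, anchor_time: str = "12:00") -> Track:
    """Reduce a track to one fix per calendar day, closest to the anchor.

    For every UTC calendar day with at least one fix, the fix minimizing
    ``|timestamp - anchor|`` is retained; ties go to the earlier fix.
    ``day_index`` counts days since release (the track's ``release_time``
    date if set, else the first fix's date).  Idempotent.
    """
    df = track.fixes
    if df.empty:
        out = df.copy()
        out["day_index"] = pd.Series(dtype=int)
        return Track(track.individual_id, out, track.release_time)

    ts = df["timestamp"]
    if ts.is_monotonic_increasing is False:
        df = df.sort_values("timestamp").reset_index(drop=True)
        ts = df["timestamp"]

    hh, mm = (int(p) for p in anchor_time.split(":"))
    anchor = ts.dt.normalize() + pd.Timedelta(hours=hh, minutes=mm)
    dist = (ts - anchor).abs()
    work = df.assign(_date=ts.dt.normalize(), _dist=dist)
    # stable sort: within a day the earlier of two equidistant fixes wins
    work = work.sort_values(["_date", "_dist", "timestamp"], kind="mergesort")
    picked = work.groupby("_date", sort=True).head(1).sort_values("timestamp")

    t0 = track.release_time
    day0 = (t0.normalize() if t0 is not None else picked["_date"].iloc[0])
    picked = picked.assign(
        day_index=((picked["_date"] - day0) / pd.Timedelta(days=1)).astype(int)
    )
    out = picked.drop(columns=["_date", "_dist"]).reset_index(drop=True)
    return Track(track.individual_id, out, track.release_time)


def gap_stats(track: Track, window_days: int = 365) -> GapReport:
    """Count data gaps in the first ``window_days`` of a daily track.

    A gap is any pair of consecutive daily locations whose day indices
    differ by >= 2; its length is the number of missing days between them.
    """
    days = np.asarray(
        sorted(d for d in track.day_index if d < window_days), dtype=int
    )
    if len(days) < 2:
        return GapReport(0, [], float("nan"))
    diffs = np.diff(days)
    lengths = [int(d - 1) for d in diffs if d >= 2]
    mean = float(np.mean(lengths)) if lengths else float("nan")
    return GapReport(len(lengths), lengths, mean)
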