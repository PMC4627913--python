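"""Synthetic telemetry cohorts, fates, and landscapes.

The generators emulate the statistical structure the downstream analyses
assume: a two-phase movement process (extensive exploration followed by
settlement around a range centre), GPS schedules of 1-6 fixes/day versus
sparse VHF relocations with multi-day gaps, habituation-stratified
mortality, and layered categorical landscapes for the recipient-area
suitability model.  Everything is a pure function of (parameters, seed);
coordinates are planar km.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from shapely.geometry import Polygon

from .telemetry import IndividualRecord, OutcomeRecord, Track
from .suitability import SuitabilityStack

_EPOCH = pd.Timestamp("2010-01-01 12:00", tz="UTC")


@dataclass(frozen=True)
class MovementScenario:
    """Two-phase post-release movement: correlated-random-walk exploration,
    then a discrete-time attraction step toward a range centre.

    ``homing_bias`` mixes the exploration heading with the bearing toward
    the capture site (0 = ignore home, 1 = head straight home).
    """

    phase1_duration_days: int = 90
    phase1_step_km: float = 12.0
    phase1_turn_concentration: float = 2.0
    phase2_center: tuple[float, float] = (30.0, 20.0)
    phase2_attraction: float = 0.3
    phase2_step_km: float = 3.0
    homing_bias: float = 0.0
    release_site: tuple[float, float] = (0.0, 0.0)
    capture_site: tuple[float, float] = (300.0, 0.0)
    seed: int = 0

    def __post_init__(self) -> None:
        vals = [
            self.phase1_duration_days, self.phase1_step_km,
            self.phase1_turn_concentration, *self.phase2_center,
            self.phase2_attraction, self.phase2_step_km, self.homing_bias,
            *self.release_site, *self.capture_site,
        ]
        if not all(math.isfinite(v) for v in vals):
            raise ValueError("non-finite scenario parameter")
        if self.phase1_duration_days < 0 or self.phase1_step_km < 0 or self.phase2_step_km < 0:
            raise ValueError("negative duration or step length")
        if not (0.0 <= self.homing_bias <= 1.0):
            raise ValueError("homing_bias outside [0, 1]")
        if not (0.0 < self.phase2_attraction <= 1.0):
            raise ValueError("phase2_attraction outside (0, 1]")


@dataclass(frozen=True)
class ObservationScheme:
    """GPS (1-6 fixes/day, near-certain daily detection) or VHF
    (single fixes, daily detection probability < 1)."""

    mode: str = "GPS"
    fixes_per_day: tuple[int, int] = (1, 6)
    detection_probability: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("GPS", "VHF"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if not (0.0 <= self.detection_probability <= 1.0):
            raise ValueError("detection_probability outside [0, 1]")
        lo, hi = self.fixes_per_day
        if lo < 1 or hi < lo:
            raise ValueError("invalid fixes_per_day range")


@dataclass(frozen=True)
class FateScenario:
    """Habituation-stratified constant per-day death hazard, collar-failure
    censoring, and a categorical cause-of-death mix."""

    hazard_by_class: Mapping[str, float] = field(
        default_factory=lambda: {"wild": 0.0008, "semi": 0.0015, "habituated": 0.008}
    )
    censor_day_mean: float = 600.0
    cause_mix: Mapping[str, float] = field(
        default_factory=lambda: {"human": 0.5, "hyaena": 0.29, "accident": 0.14, "other": 0.07}
    )

    def __post_init__(self) -> None:
        if not self.hazard_by_class:
            raise ValueError("empty hazard class map")
        if any(h < 0 for h in self.hazard_by_class.values()):
            raise ValueError("negative hazard")
        if abs(sum(self.cause_mix.values()) - 1.0) > 1e-9:
            raise ValueError("cause probabilities must sum to 1")


@dataclass(frozen=True)
class LandscapeSpec:
    """Extent, resolution and layer recipe for a synthetic landscape."""

    grid_extent_km: tuple[float, float] = (1000.0, 1000.0)
    cell_size_km: float = 2.0
    reserve_polygon: Optional[Polygon] = None
    pa_polygons: tuple[Polygon, ...] = ()
    species: tuple[str, ...] = ("cheetah", "lion", "hyaena")
    level_weights: Mapping[str, Sequence[float]] = field(
        default_factory=lambda: {
            "cheetah": (0.3, 0.4, 0.2, 0.1),
            "lion": (0.6, 0.25, 0.1, 0.05),
            "hyaena": (0.4, 0.3, 0.2, 0.1),
        }
    )
    smoothness_cells: float = 10.0
    n_urban_points: int = 8

    def __post_init__(self) -> None:
        if self.cell_size_km <= 0:
            raise ValueError("cell_size_km must be positive")
        w, h = self.grid_extent_km
        if w <= 0 or h <= 0:
            raise ValueError("grid extent must be positive")


def _wrap(a: np.ndarray | float) -> np.ndarray | float:
    return (a + np.pi) % (2 * np.pi) - np.pi


def simulate_track(scenario: MovementScenario, n_days: int) -> Track:
    """Simulate one true daily position per day, day 0 at the release site.

    Phase 1 (exploration) is a correlated random walk: heading evolves by
    wrapped-normal turns with SD pi/(1 + turn_concentration) and optionally
    bends toward the capture site (``homing_bias``); daily step lengths are
    exponential with the scenario mean.  Phase 2 (settlement) pulls the
    position toward ``phase2_center`` each day and adds isotropic Gaussian
    noise whose mean displacement equals ``phase2_step_km``.
    """
    if n_days < 1:
        raise ValueError("n_days must be >= 1")
    rng = np.random.default_rng(scenario.seed)
    pos = np.empty((n_days + 1, 2))
    pos[0] = scenario.release_site
    heading = rng.uniform(-np.pi, np.pi)
    turn_sd = np.pi / (1.0 + scenario.phase1_turn_concentration)
    # Rayleigh-with-mean-m noise: per-axis sigma = m / sqrt(pi/2)
    noise_sd = scenario.phase2_step_km / math.sqrt(math.pi / 2.0)
    cx, cy = scenario.phase2_center
    for t in range(1, n_days + 1):
        if t <= scenario.phase1_duration_days:
            heading = _wrap(heading + rng.normal(0.0, turn_sd))
            if scenario.homing_bias > 0:
                home = math.atan2(
                    scenario.capture_site[1] - pos[t - 1, 1],
                    scenario.capture_site[0] - pos[t - 1, 0],
                )
                heading = _wrap(heading + scenario.homing_bias * _wrap(home - heading))
            step = scenario.phase1_step_km * rng.exponential(1.0)
            pos[t] = pos[t - 1] + step * np.array([math.cos(heading), math.sin(heading)])
        else:
            a = scenario.phase2_attraction
            drift = pos[t - 1] + a * (np.array([cx, cy]) - pos[t - 1])
            pos[t] = drift + rng.normal(0.0, noise_sd, size=2)

    ts = _EPOCH + pd.to_timedelta(np.arange(n_days + 1), unit="D")
    df = pd.DataFrame(
        {
            "timestamp": ts,
            "x": pos[:, 0],
            "y": pos[:, 1],
            "source": "true",
            "quality": np.nan,
            "day_index": np.arange(n_days + 1),
        }
    )
    return Track("sim", df, release_time=_EPOCH)


def observe_track(track: Track, scheme: ObservationScheme) -> Track:
    """Subsample a true daily track according to an observation scheme.

    GPS mode emits 1-6 fixes on (almost) every day at random times; VHF
    mode retains each day with ``detection_probability`` and emits a single
    fix.  Fix coordinates are the day's true position.
    """
    if len(track) == 0:
        raise ValueError("empty track")
    rng = np.random.default_rng(scheme.seed)
    n = len(track)
    detected = rng.random(n) <= scheme.detection_probability
    if scheme.mode == "GPS":
        lo, hi = scheme.fixes_per_day
        counts = rng.integers(lo, hi + 1, size=n)
    else:
        counts = np.ones(n, dtype=int)
    counts = np.where(detected, counts, 0)

    day0 = (
        track.fixes["timestamp"].dt.tz_localize(None).dt.normalize().to_numpy()
    )
    xy = track.xy
    rep = np.repeat(np.arange(n), counts)
    hours = rng.uniform(0.0, 24.0, size=int(counts.sum()))
    # sort fix times within each day
    order = np.lexsort((hours, rep))
    ts = day0[rep] + (hours[order] * 3.6e12).astype("timedelta64[ns]")
    df = pd.DataFrame(
        {
            "timestamp": pd.DatetimeIndex(ts, tz="UTC"),
            "x": xy[rep, 0],
            "y": xy[rep, 1],
            "source": scheme.mode,
            "quality": np.nan,
        }
    )
    return Track(track.individual_id, df, track.release_time)


def simulate_cohort(
    n: int,
    scenarios: Sequence[MovementScenario] | MovementScenario,
    fates: FateScenario,
    seed: int = 0,
    horizon_days: int = 730,
    habituation_mix: Mapping[str, float] | None = None,
    with_tracks: bool = True,
) -> tuple[list[IndividualRecord], list[OutcomeRecord], list[Track]]:
    """Simulate a translocated cohort with fates drawn from class hazards.

    Death day is geometric with the class's per-day hazard; collar failure
    is exponential with ``censor_day_mean``; tracks are truncated at
    min(death, censoring, horizon) and outcome records agree with the
    truncation day.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    classes = list(fates.hazard_by_class)
    if habituation_mix is None:
        probs = np.full(len(classes), 1.0 / len(classes))
    else:
        probs = np.array([habituation_mix[c] for c in classes], dtype=float)
        probs = probs / probs.sum()

    individuals, outcomes, tracks = [], [], []
    for i in range(n):
        cls = classes[int(rng.choice(len(classes), p=probs))]
        h = fates.hazard_by_class[cls]
        if h > 0:
            death_day = int(rng.geometric(h))
        else:
            death_day = horizon_days + 1
        censor_day = max(1, int(math.ceil(rng.exponential(fates.censor_day_mean))))
        end = min(death_day, censor_day, horizon_days)
        died = death_day <= min(censor_day, horizon_days)

        scen = scenarios[i] if isinstance(scenarios, Sequence) else scenarios
        scen = replace(scen, seed=int(rng.integers(0, 2**31 - 1)))
        ind_id = f"sim{i:03d}"
        if with_tracks:
            track = simulate_track(scen, n_days=end)
            track.individual_id = ind_id
            tracks.append(track)

        causes = list(fates.cause_mix)
        cause = causes[int(rng.choice(len(causes), p=np.array(list(fates.cause_mix.values()))))]
        individuals.append(
            IndividualRecord(
                individual_id=ind_id,
                sex="F" if rng.random() < 0.5 else "M",
                habituation=cls,
                captivity_days=int(rng.integers(1, 1200)),
                translocation_distance_km=float(
                    math.hypot(
                        scen.capture_site[0] - scen.release_site[0],
                        scen.capture_site[1] - scen.release_site[1],
                    )
                    or 1.0
                ),
                release_mode="hard" if rng.random() < 0.5 else "soft",
                transmitter="GPS",
                capture_site=scen.capture_site,
                release_site=scen.release_site,
            )
        )
        outcomes.append(
            OutcomeRecord(
                individual_id=ind_id,
                known_survival_days=end,
                event="death" if died else "censored",
                cause=cause if died else ("collar_failure" if censor_day < horizon_days else None),
            )
        )
    return individuals, outcomes, tracks


# ---------------------------------------------------------------------------
# landscapes


def _smooth_categorical(
    rng: np.random.Generator,
    shape: tuple[int, int],
    weights: Sequence[float],
    smoothness_cells: float,
) -> np.ndarray:
    """Spatially autocorrelated ordinal field with target level proportions.

    Gaussian-smoothed white noise is quantile-binned so that level i covers
    (approximately) weights[i] of the grid.
    """
    field_ = ndimage.gaussian_filter(rng.standard_normal(shape), smoothness_cells)
    w = np.asarray(weights, dtype=float)
    w = w / w.sum()
    edges = np.quantile(field_, np.cumsum(w)[:-1])
    return np.digitize(field_, edges).astype(np.int8)


def generate_landscape(spec: LandscapeSpec, seed: int = 0) -> SuitabilityStack:
    """Generate co-registered categorical occurrence grids, a protected-area
    mask, and an urban-distance grid on one planar km lattice."""
    rng = np.random.default_rng(seed)
    nx = int(round(spec.grid_extent_km[0] / spec.cell_size_km))
    ny = int(round(spec.grid_extent_km[1] / spec.cell_size_km))
    shape = (ny, nx)

    # cell-centre coordinates
    xs = (np.arange(nx) + 0.5) * spec.cell_size_km
    ys = (np.arange(ny) + 0.5) * spec.cell_size_km
    xx, yy = np.meshgrid(xs, ys)

    pa_polygons = list(spec.pa_polygons)
    reserve = spec.reserve_polygon
    if reserve is None and not pa_polygons:
        # default: a handful of random rectangular reserves
        for _ in range(5):
            w = rng.uniform(0.05, 0.25) * spec.grid_extent_km[0]
            h = rng.uniform(0.05, 0.25) * spec.grid_extent_km[1]
            x0 = rng.uniform(0, spec.grid_extent_km[0] - w)
            y0 = rng.uniform(0, spec.grid_extent_km[1] - h)
            pa_polygons.append(Polygon([(x0, y0), (x0 + w, y0), (x0 + w, y0 + h), (x0, y0 + h)]))
        reserve = pa_polygons[0]
    elif reserve is not None and not pa_polygons:
        pa_polygons = [reserve]

    import shapely

    pa_mask = np.zeros(shape, dtype=bool)
    for poly in pa_polygons:
        pa_mask |= shapely.covers(poly, shapely.points(xx, yy))

    occurrence = {
        sp: _smooth_categorical(
            rng, shape, spec.level_weights[sp], spec.smoothness_cells
        )
        for sp in spec.species
    }

    if spec.n_urban_points > 0:
        ux = rng.uniform(0, spec.grid_extent_km[0], spec.n_urban_points)
        uy = rng.uniform(0, spec.grid_extent_km[1], spec.n_urban_points)
        d = np.full(shape, np.inf)
        for px, py in zip(ux, uy):
            d = np.minimum(d, np.hypot(xx - px, yy - py))
        urban_points = list(zip(ux.tolist(), uy.tolist()))
    else:
        d = np.full(shape, np.inf)
        urban_points = []

    return SuitabilityStack(
        pa_mask=pa_mask,
        occurrence=occurrence,
        urban_distance_km=d,
        cell_size_km=spec.cell_size_km,
        reserve_polygon=reserve,
        pa_polygons=tuple(pa_polygons),
        urban_points=urban_points,
    )
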