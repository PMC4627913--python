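"""Step-wise elimination model of recipient-area suitability.

A candidate cell is suitable only if it satisfies every criterion
(equal parameter weighting realized as strict conjunction): designated
protected status, low-to-medium cheetah occurrence (connectivity with
conspecifics but no saturated or empty range), at most low lion and
spotted-hyaena occurrence (intra-guild risk and kleptoparasitism), and
more than 50 km from urban areas.  An optional second stage removes
connected suitable patches smaller than the maximum observed exploratory
range, reflecting that smaller patches cannot contain post-release
movements.  Because the rules are intersections, their application order
cannot affect the result.

Grids are plain numpy arrays on a shared planar-km lattice; occurrence is
the 4-level ordinal scale none < low < medium < high coded 0..3.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Optional, Sequence

import numpy as np
from scipy import ndimage

LEVELS = ("none", "low", "medium", "high")
LEVEL_CODE = {name: i for i, name in enumerate(LEVELS)}

#: maximum observed exploratory 100% MCP (km^2); default patch-size threshold
DEFAULT_MIN_PATCH_KM2 = 19_743.0


class MissingLayerError(KeyError):
    """A rule references a layer the stack does not carry."""


@dataclass
class SuitabilityStack:
    """Co-registered categorical grids plus vector context."""

    pa_mask: np.ndarray  # bool, True inside protected areas
    occurrence: Mapping[str, np.ndarray]  # species -> int8 grid coded 0..3
    urban_distance_km: np.ndarray
    cell_size_km: float
    reserve_polygon: object | None = None
    pa_polygons: tuple = ()
    urban_points: list = field(default_factory=list)

    def __post_init__(self) -> None:
        shape = self.pa_mask.shape
        for name, grid in self.occurrence.items():
            if grid.shape != shape:
                raise ValueError(f"occurrence grid {name!r} extent mismatch")
            if grid.min() < 0 or grid.max() > 3:
                raise ValueError(f"occurrence grid {name!r} outside ordinal scale 0..3")
        if self.urban_distance_km.shape != shape:
            raise ValueError("urban_distance_km extent mismatch")
        if self.cell_size_km <= 0:
            raise ValueError("cell_size_km must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pa_mask.shape

    @property
    def cell_area_km2(self) -> float:
        return self.cell_size_km**2


@dataclass(frozen=True)
class ExclusionRule:
    """Named pure predicate returning the mask of cells it excludes."""

    name: str
    predicate: Callable[[SuitabilityStack], np.ndarray]
    order_index: int = 0

    def excluded(self, stack: SuitabilityStack) -> np.ndarray:
        return np.asarray(self.predicate(stack), dtype=bool)


def _occ(stack: SuitabilityStack, species: str) -> np.ndarray:
    try:
        return stack.occurrence[species]
    except KeyError:
        raise MissingLayerError(f"stack has no occurrence layer {species!r}") from None


def default_rules(urban_buffer_km: float = 50.0) -> list[ExclusionRule]:
    """The five exclusion criteria of the recipient-area model."""
    return [
        ExclusionRule("land_use", lambda s: ~s.pa_mask, 0),
        ExclusionRule(
            "lion_occurrence",
            lambda s: _occ(s, "lion") >= LEVEL_CODE["medium"], 1,
        ),
        ExclusionRule(
            "hyaena_occurrence",
            lambda s: _occ(s, "hyaena") >= LEVEL_CODE["medium"], 2,
        ),
        ExclusionRule(
            "cheetah_occurrence",
            lambda s: (_occ(s, "cheetah") == LEVEL_CODE["none"])
            | (_occ(s, "cheetah") == LEVEL_CODE["high"]), 3,
        ),
        ExclusionRule(
            "urban_buffer",
            lambda s: s.urban_distance_km <= urban_buffer_km, 4,
        ),
    ]


@dataclass
class Patch:
    id: int
    n_cells: int
    area_km2: float


@dataclass
class PatchReport:
    """Connected suitable patches and per-rule elimination impact."""

    patches: list[Patch]
    suitable_area_km2: float
    labels: np.ndarray
    rule_impact_pct: dict[str, float] = field(default_factory=dict)

    @property
    def n_patches(self) -> int:
        return len(self.patches)

    def areas(self) -> list[float]:
        return [p.area_km2 for p in self.patches]


def apply_exclusions(
    stack: SuitabilityStack, rules: Sequence[ExclusionRule]
) -> tuple[np.ndarray, dict[str, float]]:
    """Intersect all rules; report each rule's solo impact.

    Returns the boolean suitability mask and, per rule, the percentage of
    protected-area cells that the rule alone eliminates.
    """
    if not rules:
        raise ValueError("rules must be non-empty")
    suitable = np.ones(stack.shape, dtype=bool)
    impact: dict[str, float] = {}
    n_pa = int(stack.pa_mask.sum())
    for rule in rules:
        excl = rule.excluded(stack)
        suitable &= ~excl
        if n_pa:
            impact[rule.name] = 100.0 * float((excl & stack.pa_mask).sum()) / n_pa
        else:
            impact[rule.name] = float("nan")
    return suitable, impact


def label_patches(mask: np.ndarray, cell_size_km: float, connectivity: int = 8) -> PatchReport:
    """Label connected suitable patches (4- or 8-neighbour)."""
    if connectivity == 8:
        structure = np.ones((3, 3), dtype=int)
    elif connectivity == 4:
        structure = ndimage.generate_binary_structure(2, 1)
    else:
        raise ValueError("connectivity must be 4 or 8")
    labels, n = ndimage.label(mask, structure=structure)
    cell_area = cell_size_km**2
    counts = np.bincount(labels.ravel(), minlength=n + 1)[1:]
    patches = [
        Patch(id=i + 1, n_cells=int(c), area_km2=float(c) * cell_area)
        for i, c in enumerate(counts)
    ]
    total = float(mask.sum()) * cell_area
    return PatchReport(patches=patches, suitable_area_km2=total, labels=labels)


def filter_by_patch_size(report: PatchReport, min_area_km2: float) -> PatchReport:
    """Drop patches below the minimum area (site-fidelity criterion)."""
    if min_area_km2 < 0:
        raise ValueError("min_area_km2 must be >= 0")
    keep = [p for p in report.patches if p.area_km2 >= min_area_km2]
    keep_ids = {p.id for p in keep}
    labels = np.where(np.isin(report.labels, list(keep_ids)), report.labels, 0)
    return PatchReport(
        patches=keep,
        suitable_area_km2=sum(p.area_km2 for p in keep),
        labels=labels,
        rule_impact_pct=dict(report.rule_impact_pct),
    )


def run_model(
    stack: SuitabilityStack,
    mode: str = "full",
    min_patch_area_km2: float = DEFAULT_MIN_PATCH_KM2,
    connectivity: int = 8,
    rules: Optional[Sequence[ExclusionRule]] = None,
) -> PatchReport:
    """Run the elimination model in either iteration.

    ``full`` chains all five criteria and then removes patches smaller
    than ``min_patch_area_km2``; ``no_site_fidelity`` omits the patch-size
    filter.  Results are independent of rule order (intersection).
    """
    if mode not in ("full", "no_site_fidelity"):
        raise ValueError(f"unknown mode {mode!r}")
    if rules is None:
        rules = default_rules()
    mask, impact = apply_exclusions(stack, rules)
    report = label_patches(mask, stack.cell_size_km, connectivity=connectivity)
    report.rule_impact_pct = impact
    if mode == "full":
        report = filter_by_patch_size(report, min_patch_area_km2)
    return report


# ---------------------------------------------------------------------------
# text raster I/O (ESRI ASCII grid)


def write_ascii_grid(path, grid: np.ndarray, cell_size_km: float) -> None:
    g = np.asarray(grid, dtype=float)
    with open(path, "w") as fh:
        fh.write(f"ncols {g.shape[1]}\n")
        fh.write(f"nrows {g.shape[0]}\n")
        fh.write("xllcorner 0.0\nyllcorner 0.0\n")
        fh.write(f"cellsize {cell_size_km}\n")
        fh.write("NODATA_value -9999\n")
        np.savetxt(fh, g[::-1], fmt="%.6g")


def read_ascii_grid(path) -> tuple[np.ndarray, float]:
    header: dict[str, float] = {}
    with open(path) as fh:
        lines = fh.readlines()
    for line in lines[:6]:
        key, val = line.split()
        header[key.lower()] = float(val)
    data = np.loadtxt(lines[6:])
    return data[::-1], header["cellsize"]
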