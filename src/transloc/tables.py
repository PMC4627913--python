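"""Loaders for the packaged study tables.

The package ships the per-individual study tables (subject covariates,
outcomes, and movement summaries) as plain CSV fixtures so every cohort
statistic can be recomputed without external data.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

from .telemetry import IndividualRecord, OutcomeRecord, read_study_tables

_DATA = resources.files("transloc") / "data"


def _path(name: str):
    return _DATA / name


def load_study_records() -> tuple[list[IndividualRecord], list[OutcomeRecord]]:
    """The 23 translocated adults: covariates and outcomes."""
    with resources.as_file(_path("table1.csv")) as p1, resources.as_file(
        _path("table3.csv")
    ) as p3:
        return read_study_tables(p1, p3)


def load_individuals_df() -> pd.DataFrame:
    with resources.as_file(_path("table1.csv")) as p:
        return pd.read_csv(p)


def load_outcomes_df() -> pd.DataFrame:
    with resources.as_file(_path("table3.csv")) as p:
        return pd.read_csv(p)


def load_movement_df() -> pd.DataFrame:
    """Per-individual movement summaries (exploration durations, range
    areas, overlap percentages and release-site distances)."""
    with resources.as_file(_path("table4.csv")) as p:
        return pd.read_csv(p)


def settling_days(movement_df: pd.DataFrame | None = None) -> np.ndarray:
    """Settling day (days post-release) for the individuals that settled.

    The exploration-duration column carries ``>d`` (monitoring ended while
    still exploring) and ``unknown`` markers for unsettled or unconfirmed
    individuals; only plain integers denote a confirmed settling day.
    """
    df = load_movement_df() if movement_df is None else movement_df
    vals = []
    for v in df["exploration_days"]:
        s = str(v).strip()
        if s and s not in ("nan", "") and not s.startswith(">") and s != "unknown":
            vals.append(int(float(s)))
    return np.array(vals, dtype=int)
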