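"""Cohort report: the headline quantities of a translocation evaluation.

Everything here is recomputed from the per-individual records — nothing is
looked up.  The report gathers captivity and translocation-distance
summaries, first-year Kaplan-Meier survivorship, the composite success
rate, habituation association tests, survival-period and reproduction
summaries, settling-day and release-site distance statistics, and the
90-day conditional survival probabilities.
"""

from __future__ import annotations

from dataclasses import asdict
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import evaluation, survival, tables
from .telemetry import HABITUATION_CLASSES, IndividualRecord, OutcomeRecord


def habituation_survival_table(
    individuals: Sequence[IndividualRecord],
    outcomes: Sequence[OutcomeRecord],
    year_days: int = 365,
) -> np.ndarray:
    """3x2 table: habituation class x (survived year one, died in year one).

    Unknown-fate individuals (censored before the year with no recorded
    death) are excluded, matching the evaluable cohort.
    """
    by_id = {i.individual_id: i for i in individuals}
    rows = {c: [0, 0] for c in HABITUATION_CLASSES}
    for o in outcomes:
        if o.event == "censored" and o.known_survival_days < year_days:
            if not o.removed_from_wild:
                continue  # collar failure: fate unknown
        survived = o.known_survival_days >= year_days
        rows[by_id[o.individual_id].habituation][0 if survived else 1] += 1
    return np.array([rows[c] for c in HABITUATION_CLASSES], dtype=int)


def habituation_success_table(
    individuals: Sequence[IndividualRecord],
    outcomes: Sequence[OutcomeRecord],
) -> np.ndarray:
    """3x2 table: habituation class x (success, failure), evaluable only."""
    by_id = {i.individual_id: i for i in individuals}
    cohort = evaluation.evaluate_cohort(outcomes, individuals)
    rows = {c: [0, 0] for c in HABITUATION_CLASSES}
    for r in cohort.results:
        if r.success == "unknown":
            continue
        rows[by_id[r.individual_id].habituation][0 if r.success == "yes" else 1] += 1
    return np.array([rows[c] for c in HABITUATION_CLASSES], dtype=int)


def cohort_report(
    individuals: Optional[Sequence[IndividualRecord]] = None,
    outcomes: Optional[Sequence[OutcomeRecord]] = None,
    movement_df: Optional[pd.DataFrame] = None,
) -> dict:
    """Compute the cohort evaluation; defaults to the packaged study tables."""
    if individuals is None or outcomes is None:
        individuals, outcomes = tables.load_study_records()
    if movement_df is None:
        movement_df = tables.load_movement_df()

    capt = np.array([i.captivity_days for i in individuals], dtype=float)
    dist = np.array([i.translocation_distance_km for i in individuals], dtype=float)

    km = survival.km_estimate(survival.from_outcomes(outcomes))
    s365 = km.survival_at(365)

    cohort = evaluation.evaluate_cohort(outcomes, individuals)

    surv_tab = habituation_survival_table(individuals, outcomes)
    succ_tab = habituation_success_table(individuals, outcomes)
    g_surv = survival.lr_contingency(surv_tab)
    g_succ = survival.lr_contingency(succ_tab)

    periods = evaluation.survival_period_summary(outcomes, known_fates_only=True)
    by_id = {i.individual_id: i for i in individuals}
    habituated = [o for o in outcomes if by_id[o.individual_id].habituation == "habituated"]
    hab_periods = evaluation.survival_period_summary(habituated)

    repro = evaluation.reproduction_summary(outcomes)

    cond_365, n365_surv, n365_elig = survival.conditional_survival(outcomes, 90, 365)
    cond_730, n730_surv, n730_elig = survival.conditional_survival(outcomes, 90, 730)

    settle = tables.settling_days(movement_df)
    last_dist = movement_df["last_dist_km"].dropna().to_numpy(dtype=float)

    return {
        "n_adults": len(individuals),
        "captivity_mean_days": float(capt.mean()),
        "captivity_sd_days": float(capt.std(ddof=1)),
        "translocation_mean_km": float(dist.mean()),
        "translocation_sd_km": float(dist.std(ddof=1)),
        "km_s365": float(s365),
        "n_evaluable": cohort.n_evaluable,
        "n_success": cohort.n_success,
        "success_rate_pct": cohort.success_rate_pct,
        "g_survival_habituation": g_surv.G,
        "g_survival_habituation_df": g_surv.df,
        "x2_survival_habituation": g_surv.X2,
        "g_success_habituation": g_succ.G,
        "g_success_habituation_df": g_succ.df,
        "mean_known_survival_months": periods.mean_months,
        "sd_known_survival_months": periods.sd_months,
        "n_known_fates": periods.n,
        "habituated_median_survival_months": hab_periods.median_months,
        "n_habituated": hab_periods.n,
        "median_litter_size": repro.median_litter,
        "n_litters": len(repro.litter_sizes),
        "conditional_survival_90_365_pct": 100.0 * cond_365,
        "conditional_survival_90_365_n": n365_elig,
        "conditional_survival_90_730_pct": 100.0 * cond_730,
        "conditional_survival_90_730_n": n730_elig,
        "median_settling_day": float(np.median(settle)),
        "n_settled": int(len(settle)),
        "mean_last_to_release_km": float(last_dist.mean()),
        "sd_last_to_release_km": float(last_dist.std(ddof=1)),
        "n_last_distances": int(len(last_dist)),
    }
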