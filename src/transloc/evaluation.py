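"""Composite translocation success rule and cohort summaries.

A translocation is successful when the individual survived at least one
year in the wild, did not home to its capture area or the captive
facility, killed at most five livestock per year, and was not removed
from the wild (e.g., recaptured).  Individuals whose collars failed
before day 365 with no later known fate are unknowable and excluded from
the cohort rate.  Livestock killed by a social unit is attributed to each
member, so a coalition's shared kills can push every member over the
threshold.

Months are reported as days / 30 throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

from .telemetry import IndividualRecord, OutcomeRecord

DAYS_PER_MONTH = 30.0
SUCCESS_SURVIVAL_DAYS = 365
DEFAULT_CONFLICT_THRESHOLD = 5


@dataclass
class SuccessResult:
    individual_id: str
    success: str  # "yes" | "no" | "unknown"
    failure_reasons: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.success == "yes" and self.failure_reasons:
            raise ValueError("successful individual cannot carry failure reasons")


@dataclass
class CohortSuccess:
    results: list[SuccessResult]
    n_evaluable: int
    n_success: int

    @property
    def success_rate_pct(self) -> float:
        return 100.0 * self.n_success / self.n_evaluable


@dataclass
class PeriodSummary:
    n: int
    mean_months: float
    sd_months: Optional[float]
    median_months: float
    min_months: float
    max_months: float


@dataclass
class ReproductionSummary:
    litter_sizes: list[int]
    median_litter: Optional[float]
    females_reproducing: int


@dataclass
class CostSummary:
    median_cost: float
    total_cost: float
    n_successful: int
    individual_conservation_cost: Optional[float]


def classify_success(
    outcome: OutcomeRecord,
    individual: Optional[IndividualRecord] = None,
    conflict_threshold: int = DEFAULT_CONFLICT_THRESHOLD,
) -> SuccessResult:
    """Apply the composite rule to one individual.

    Deterministic and total over valid records.  ``individual`` is accepted
    for symmetry with cohort evaluation but the rule needs only the outcome
    fields.
    """
    reasons = []
    if outcome.homed == "yes":
        reasons.append("homed")
    if outcome.livestock_killed_per_year > conflict_threshold:
        reasons.append("conflict_exceeded")
    if outcome.removed_from_wild:
        reasons.append("removed_from_wild")
    survived_year = outcome.known_survival_days >= SUCCESS_SURVIVAL_DAYS
    if outcome.event == "death" and not survived_year:
        reasons.append("died_within_year")

    if reasons:
        return SuccessResult(outcome.individual_id, "no", reasons)
    if survived_year:
        return SuccessResult(outcome.individual_id, "yes")
    # censored before one year, nothing disqualifying known -> unknowable
    return SuccessResult(outcome.individual_id, "unknown")


def evaluate_cohort(
    outcomes: Sequence[OutcomeRecord],
    individuals: Optional[Sequence[IndividualRecord]] = None,
    conflict_threshold: int = DEFAULT_CONFLICT_THRESHOLD,
) -> CohortSuccess:
    by_id = {i.individual_id: i for i in individuals} if individuals else {}
    results = [
        classify_success(o, by_id.get(o.individual_id), conflict_threshold)
        for o in outcomes
    ]
    evaluable = [r for r in results if r.success != "unknown"]
    n_success = sum(1 for r in evaluable if r.success == "yes")
    return CohortSuccess(results, n_evaluable=len(evaluable), n_success=n_success)


def survival_period_summary(
    outcomes: Sequence[OutcomeRecord],
    known_fates_only: bool = False,
) -> PeriodSummary:
    """Mean/SD/median/range of known survival periods, in months (days/30).

    With ``known_fates_only`` the three unknown-outcome collar failures are
    excluded (the cohort the headline mean describes).
    """
    sel = list(outcomes)
    if known_fates_only:
        sel = [o for o in sel if o.cause != "collar_failure"]
    if not sel:
        raise ValueError("empty group")
    months = np.array([o.known_survival_days for o in sel], dtype=float) / DAYS_PER_MONTH
    sd = float(np.std(months, ddof=1)) if len(months) > 1 else None
    return PeriodSummary(
        n=len(months),
        mean_months=float(months.mean()),
        sd_months=sd,
        median_months=float(np.median(months)),
        min_months=float(months.min()),
        max_months=float(months.max()),
    )


def reproduction_summary(outcomes: Sequence[OutcomeRecord]) -> ReproductionSummary:
    """Litter sizes and count of reproducing females; median by midpoint."""
    sizes = [s for o in outcomes for s in o.litters]
    reproducing = sum(1 for o in outcomes if o.litters)
    median = float(np.median(sizes)) if sizes else None
    return ReproductionSummary(sizes, median, reproducing)


def cost_summary(
    costs: Mapping[str, float] | Sequence[float],
    successes: CohortSuccess | int,
) -> CostSummary:
    """Median per-individual cost and the Individual Conservation Cost
    (total cohort cost / number of successful adults)."""
    vals = np.array(
        list(costs.values()) if isinstance(costs, Mapping) else list(costs), dtype=float
    )
    if np.any(vals < 0):
        raise ValueError("costs must be non-negative")
    n_success = successes.n_success if isinstance(successes, CohortSuccess) else int(successes)
    total = float(vals.sum())
    icc = total / n_success if n_success > 0 else None
    return CostSummary(
        median_cost=float(np.median(vals)),
        total_cost=total,
        n_successful=n_success,
        individual_conservation_cost=icc,
    )
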