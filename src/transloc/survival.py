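"""Staggered-entry Kaplan-Meier survivorship and association tests.

The product-limit estimator S(t) = prod_{t_i <= t} (1 - d_i / n_i) is
computed on the time-since-release scale with optional left truncation
(staggered calendar entry): an individual is at risk at time t when
entry_day < t <= exit_day.  At tied days, deaths are processed before
censorings.  Variance is Greenwood's formula with linear 95% intervals
clipped to [0, 1].

Association between categorical covariates and binary outcomes is tested
with the likelihood-ratio chi-square G = 2 sum O ln(O/E) (headline, with
the 0 ln 0 = 0 convention) alongside the Pearson X^2; groups of survival
inputs are compared with a two-sample log-rank Z.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .telemetry import OutcomeRecord


@dataclass(frozen=True)
class SurvivalInput:
    """One at-risk interval: (entry_day, exit_day] with a terminal event."""

    exit_day: int
    event: str  # "death" | "censored"
    entry_day: int = 0
    individual_id: Optional[str] = None

    def __post_init__(self) -> None:
        if self.exit_day <= self.entry_day:
            raise ValueError("exit_day must exceed entry_day")
        if self.event not in ("death", "censored"):
            raise ValueError(f"event {self.event!r}")


@dataclass
class KMCurve:
    event_times: np.ndarray  # distinct days with deaths and/or censorings
    S: np.ndarray  # survival just after each time
    at_risk: np.ndarray
    deaths: np.ndarray
    censored: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray

    def survival_at(self, day: float) -> float:
        """Step-function evaluation of S at ``day`` (S(0) = 1)."""
        s = 1.0
        for t, v in zip(self.event_times, self.S):
            if t <= day:
                s = v
            else:
                break
        return float(s)


@dataclass
class ContingencyResult:
    observed: np.ndarray
    expected: np.ndarray
    G: float
    X2: float
    df: int
    p_G: float
    p_X2: float


def from_outcomes(outcomes: Sequence[OutcomeRecord]) -> list[SurvivalInput]:
    """Survival inputs on the time-since-release scale."""
    return [
        SurvivalInput(
            exit_day=o.known_survival_days,
            event=o.event,
            individual_id=o.individual_id,
        )
        for o in outcomes
    ]


def km_estimate(
    inputs: Sequence[SurvivalInput], horizon_days: Optional[int] = None
) -> KMCurve:
    """Product-limit estimate with staggered entry.

    Risk set at day t counts individuals with entry < t <= exit; deaths at
    t reduce S by (1 - d/n) with the full risk set n (ties: deaths before
    censorings).
    """
    if not inputs:
        raise ValueError("no survival inputs")
    entry = np.array([i.entry_day for i in inputs])
    exit_ = np.array([i.exit_day for i in inputs])
    death = np.array([i.event == "death" for i in inputs])
    times = np.unique(exit_)
    if horizon_days is not None:
        times = times[times <= horizon_days]

    S = 1.0
    var_sum = 0.0
    rows = []
    for t in times:
        n_at_risk = int(np.sum((entry < t) & (exit_ >= t)))
        d = int(np.sum((exit_ == t) & death))
        c = int(np.sum((exit_ == t) & ~death))
        if n_at_risk > 0 and d > 0:
            S *= 1.0 - d / n_at_risk
            if n_at_risk > d:
                var_sum += d / (n_at_risk * (n_at_risk - d))
        se = S * np.sqrt(var_sum)
        rows.append((t, S, n_at_risk, d, c, max(0.0, S - 1.96 * se), min(1.0, S + 1.96 * se)))

    arr = np.array(rows, dtype=float) if rows else np.empty((0, 7))
    return KMCurve(
        event_times=arr[:, 0].astype(int) if len(arr) else np.array([], int),
        S=arr[:, 1] if len(arr) else np.array([]),
        at_risk=arr[:, 2].astype(int) if len(arr) else np.array([], int),
        deaths=arr[:, 3].astype(int) if len(arr) else np.array([], int),
        censored=arr[:, 4].astype(int) if len(arr) else np.array([], int),
        ci_low=arr[:, 5] if len(arr) else np.array([]),
        ci_high=arr[:, 6] if len(arr) else np.array([]),
    )


def conditional_survival(
    outcomes: Sequence[OutcomeRecord],
    condition_day: int = 90,
    target_day: int = 365,
) -> tuple[float, int, int]:
    """Proportion of condition-day survivors known to reach the target day.

    The conditioning set holds individuals surviving past ``condition_day``
    whose status at ``target_day`` is known: individuals censored between
    the two days are excluded (their fate is unknowable), individuals with
    a recorded death or with monitoring beyond the target day are kept.
    Returns (proportion, survivors, eligible).
    """
    eligible = []
    for o in outcomes:
        if o.known_survival_days <= condition_day:
            continue
        known_at_target = o.event == "death" or o.known_survival_days >= target_day
        if known_at_target:
            eligible.append(o)
    if not eligible:
        raise ValueError("empty conditioning set")
    survivors = sum(1 for o in eligible if o.known_survival_days >= target_day)
    return survivors / len(eligible), survivors, len(eligible)


def lr_contingency(observed) -> ContingencyResult:
    """Likelihood-ratio (G) and Pearson chi-square for an r x c table."""
    obs = np.asarray(observed, dtype=float)
    if obs.ndim != 2 or np.any(obs < 0):
        raise ValueError("observed must be a non-negative 2-D table")
    row_sums = obs.sum(axis=1)
    col_sums = obs.sum(axis=0)
    if np.any(row_sums == 0):
        raise ValueError(f"degenerate row(s) with zero margin: {np.flatnonzero(row_sums == 0).tolist()}")
    if np.any(col_sums == 0):
        raise ValueError(f"degenerate column(s) with zero margin: {np.flatnonzero(col_sums == 0).tolist()}")

    G, p_G, df, expected = stats.chi2_contingency(
        obs, correction=False, lambda_="log-likelihood"
    )
    X2, p_X2, _, _ = stats.chi2_contingency(obs, correction=False)
    return ContingencyResult(
        observed=obs,
        expected=expected,
        G=float(G),
        X2=float(X2),
        df=int(df),
        p_G=float(p_G),
        p_X2=float(p_X2),
    )


def km_group_compare(
    inputs_a: Sequence[SurvivalInput], inputs_b: Sequence[SurvivalInput]
) -> tuple[float, float]:
    """Two-sample log-rank Z on the time-since-entry scale.

    Z = (O_a - E_a) / sqrt(V) summed over distinct death times; negative Z
    means group A experienced fewer deaths than expected.  Returns (Z, p)
    with a two-sided normal p-value; degenerate variance yields (nan, nan).
    """
    if not inputs_a or not inputs_b:
        raise ValueError("both groups must be non-empty")
    inputs = list(inputs_a) + list(inputs_b)
    group = np.array([0] * len(inputs_a) + [1] * len(inputs_b))
    entry = np.array([i.entry_day for i in inputs])
    exit_ = np.array([i.exit_day for i in inputs])
    death = np.array([i.event == "death" for i in inputs])

    death_times = np.unique(exit_[death])
    OmE = 0.0
    V = 0.0
    for t in death_times:
        at_risk = (entry < t) & (exit_ >= t)
        n = int(at_risk.sum())
        n_a = int((at_risk & (group == 0)).sum())
        d = int(((exit_ == t) & death).sum())
        d_a = int(((exit_ == t) & death & (group == 0)).sum())
        if n == 0:
            continue
        OmE += d_a - d * n_a / n
        if n > 1:
            V += d * (n_a / n) * (1 - n_a / n) * (n - d) / (n - 1)
    if V <= 0:
        return float("nan"), float("nan")
    Z = OmE / np.sqrt(V)
    p = 2.0 * float(stats.norm.sf(abs(Z)))
    return float(Z), p
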