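"""Kaplan-Meier estimation, conditional survival, G-tests, log-rank."""

import math

import numpy as np
import pytest

from transloc import survival
from transloc.survival import (
    SurvivalInput,
    conditional_survival,
    from_outcomes,
    km_estimate,
    km_group_compare,
    lr_contingency,
)


def km_oracle(inputs, day):
    """Independent product-limit computation (no left truncation):
    walk every distinct day, deaths before censorings at ties."""
    times = sorted({i.exit_day for i in inputs})
    n = len(inputs)
    s = 1.0
    for t in times:
        if t > day:
            break
        d = sum(1 for i in inputs if i.exit_day == t and i.event == "death")
        c = sum(1 for i in inputs if i.exit_day == t and i.event == "censored")
        if d:
            s *= 1 - d / n
        n -= d + c
    return s


class TestKMEstimate:
    def test_study_cohort_annual_survivorship(self, study_records):
        """S(365) = 0.57 from the 23 collared adults' fates."""
        _, outcomes = study_records
        inputs = from_outcomes(outcomes)
        # the year-one event structure the estimate rests on
        deaths = sorted(i.exit_day for i in inputs if i.event == "death" and i.exit_day <= 365)
        cens = sorted(i.exit_day for i in inputs if i.event == "censored" and i.exit_day <= 365)
        assert deaths == [13, 14, 19, 19, 71, 71, 71, 205, 322]
        assert cens == [11, 67, 112, 290]
        km = km_estimate(inputs)
        assert round(km.survival_at(365), 2) == 0.57

    def test_simple_quarter_drop(self):
        inputs = [SurvivalInput(10, "death")] + [SurvivalInput(20, "censored")] * 3
        km = km_estimate(inputs)
        assert km.survival_at(15) == pytest.approx(0.75)

    def test_matches_bruteforce_oracle_on_random_small_instances(self):
        rng = np.random.default_rng(21)
        for _ in range(50):
            n = int(rng.integers(1, 11))
            inputs = [
                SurvivalInput(
                    int(rng.integers(1, 15)),
                    "death" if rng.random() < 0.5 else "censored",
                )
                for _ in range(n)
            ]
            km = km_estimate(inputs)
            for day in (0, 3, 7, 14, 30):
                assert km.survival_at(day) == pytest.approx(km_oracle(inputs, day))

    def test_no_censoring_equals_empirical_survival(self):
        rng = np.random.default_rng(2)
        days = rng.integers(1, 100, 40)
        inputs = [SurvivalInput(int(d), "death") for d in days]
        km = km_estimate(inputs)
        for t in (10, 50, 99):
            assert km.survival_at(t) == pytest.approx(float(np.mean(days > t)))

    def test_all_censored_survival_stays_one(self):
        inputs = [SurvivalInput(int(d), "censored") for d in (5, 10, 20)]
        km = km_estimate(inputs)
        assert km.survival_at(100) == 1.0

    def test_deaths_processed_before_censorings_at_ties(self):
        # death and censoring on the same day: the censored animal is still
        # at risk for the death, so S drops by 1 - 1/4, not 1 - 1/3
        inputs = [
            SurvivalInput(10, "death"),
            SurvivalInput(10, "censored"),
            SurvivalInput(30, "censored"),
            SurvivalInput(30, "censored"),
        ]
        km = km_estimate(inputs)
        assert km.survival_at(10) == pytest.approx(0.75)

    def test_survival_curve_monotone_and_bounded(self):
        rng = np.random.default_rng(6)
        inputs = [
            SurvivalInput(int(rng.integers(1, 200)),
                          "death" if rng.random() < 0.6 else "censored")
            for _ in range(60)
        ]
        km = km_estimate(inputs)
        assert np.all(np.diff(km.S) <= 1e-12)
        assert np.all((km.S >= 0) & (km.S <= 1))
        assert np.all(km.ci_low <= km.S + 1e-12) and np.all(km.S <= km.ci_high + 1e-12)

    def test_staggered_entry_left_truncation(self):
        # late entrant is not at risk for the early death
        early = [SurvivalInput(10, "death"), SurvivalInput(50, "censored")]
        late = [SurvivalInput(40, "death", entry_day=20)]
        km = km_estimate(early + late)
        # day 10: risk set {A, B} -> S = 1/2; day 40: risk set {B, C} -> 1/4
        assert km.survival_at(10) == pytest.approx(0.5)
        assert km.survival_at(45) == pytest.approx(0.25)

    def test_agrees_with_lifelines(self, study_records):
        lifelines = pytest.importorskip("lifelines")
        _, outcomes = study_records
        kmf = lifelines.KaplanMeierFitter()
        kmf.fit(
            [o.known_survival_days for o in outcomes],
            [o.event == "death" for o in outcomes],
        )
        km = km_estimate(from_outcomes(outcomes))
        for t in (14, 71, 205, 322, 365, 600):
            assert km.survival_at(t) == pytest.approx(
                float(kmf.predict(t)), abs=1e-9
            )


class TestConditionalSurvival:
    def test_study_90_to_365(self, study_records):
        _, outcomes = study_records
        p, surv, n = conditional_survival(outcomes, 90, 365)
        assert (surv, n) == (10, 12)
        assert round(100 * p) == 83

    def test_study_90_to_730(self, study_records):
        _, outcomes = study_records
        p, surv, n = conditional_survival(outcomes, 90, 730)
        assert (surv, n) == (3, 8)
        assert round(100 * p) == 38

    def test_everyone_survives(self):
        from transloc.telemetry import OutcomeRecord

        outs = [OutcomeRecord(f"i{k}", 400, "censored") for k in range(5)]
        p, _, n = conditional_survival(outs, 90, 365)
        assert p == 1.0 and n == 5

    def test_empty_conditioning_set_rejected(self):
        from transloc.telemetry import OutcomeRecord

        outs = [OutcomeRecord("a", 10, "death", cause="shot")]
        with pytest.raises(ValueError, match="empty"):
            conditional_survival(outs, 90, 365)


class TestContingency:
    def test_habituation_survival_g_statistic(self):
        res = lr_contingency([[8, 4], [2, 1], [0, 5]])
        assert round(res.G, 2) == 8.63
        assert res.df == 2
        assert res.X2 == pytest.approx(6.67, abs=0.005)
        # independent arithmetic oracle: G = 2 sum O ln(O/E)
        obs = np.array([[8, 4], [2, 1], [0, 5]], float)
        exp = np.outer(obs.sum(1), obs.sum(0)) / obs.sum()
        with np.errstate(divide="ignore", invalid="ignore"):
            terms = np.where(obs > 0, obs * np.log(obs / exp), 0.0)
        assert res.G == pytest.approx(2 * terms.sum())

    def test_habituation_success_g_statistic(self):
        res = lr_contingency([[6, 6], [2, 1], [0, 5]])
        assert round(res.G, 2) == 6.47
        assert res.df == 2
        assert res.p_G == pytest.approx(0.0394, abs=0.0005)

    def test_zero_when_observed_equals_expected(self):
        res = lr_contingency([[5, 5], [5, 5]])
        assert res.G == 0.0 and res.X2 == 0.0

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError, match="column"):
            lr_contingency([[3, 0], [4, 0]])
        with pytest.raises(ValueError, match="row"):
            lr_contingency([[0, 0], [4, 2]])

    def test_g_and_pearson_agree_as_deviation_shrinks_relative_to_margins(self):
        # G ~ X2 when O is close to E; hold the absolute deviation from
        # independence fixed while the margins grow k-fold
        delta = np.array([[3.0, -3.0], [-3.0, 3.0]])
        gaps = []
        for k in (1, 10, 100):
            res = lr_contingency(np.full((2, 2), 10.0) * k + delta)
            gaps.append(abs(res.G - res.X2) / res.X2)
        assert gaps[0] > gaps[1] > gaps[2]


class TestGroupCompare:
    def test_identical_groups_give_zero(self):
        g = [SurvivalInput(d, "death") for d in (5, 10, 20, 40)]
        z, p = km_group_compare(g, list(g))
        assert z == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_sign_fixed_when_one_group_dies_later(self):
        a = [SurvivalInput(d, "death") for d in (5, 10, 20, 40)]
        b = [SurvivalInput(2 * d, "death") for d in (5, 10, 20, 40)]
        z, _ = km_group_compare(a, b)
        assert z > 0  # group A accumulated more deaths than expected

    def test_equal_hazard_type_i_error_near_alpha(self):
        rng = np.random.default_rng(44)
        reps, rejections = 1000, 0
        for _ in range(reps):
            a = [SurvivalInput(int(d) + 1, "death")
                 for d in rng.exponential(100, 20)]
            b = [SurvivalInput(int(d) + 1, "death")
                 for d in rng.exponential(100, 20)]
            z, _ = km_group_compare(a, b)
            rejections += abs(z) >= 1.96
        assert 0.03 < rejections / reps < 0.07

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            km_group_compare([], [SurvivalInput(5, "death")])
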