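# Methods

This note documents the statistical procedures the package implements, the
conventions adopted where the underlying field methods leave choices open,
and what the synthetic-data validation does and does not demonstrate.

## Telemetry standardization

All movement analyses operate on one location per day: for each UTC
calendar day with at least one fix, the fix minimizing |timestamp − anchor|
is kept, with the anchor at 12:00 UTC by default (configurable — the study
region sits 1–2 h off UTC, so the anchor choice must be explicit). Ties at
equal offset go to the earlier fix. Day index 0 is the release day.
Standardization is idempotent and never leaves two fixes with one day index.

Outlier filtering removes any fix whose sustained speed from the previous
retained fix exceeds 10 km/h (default; configurable), plus fixes whose
quality score falls below an optional threshold. The source data's outlier
criteria are not recoverable, so the rule is declared rather than inferred;
removal counts are logged so the effect is auditable.

A data gap is a pair of consecutive daily locations whose day indices
differ by ≥ 2; its length is the number of missing days. The accounting
identity (days spanned = fix days + missing days) is property-tested.

## Exploration, settling, and home ranges

Exploration is profiled with 100% MCP areas over 10-day windows shifted by
one day; windows with fewer than 5 daily fixes are skipped. A progressive
series gives the cumulative 100% MCP through each fix day and is monotone
non-decreasing by construction.

"Range asymptote" is operationalized as a deterministic relative-increase
rule rather than a significance test (the original procedure is not
reproducible): the settling day is the first day *d* with
A(d + L) − A(d) ≤ θ·A(d) on the progressive series, with lookahead
L = 30 days and θ = 0.05 by default. The rule is monotone in θ (a looser
threshold never settles later), returns "unknown" (distinct from
not-settled) when the track is shorter than the lookahead, and settles a
stationary track on its first evaluable day. On simulated tracks with a
phase switch at day 90, the recovered settling day falls within ±15 days in
≥ 80% of seeds; detection runs slightly early (median ≈ 86) because hull
growth decelerates before the switch.

Percent MCPs keep the stated fraction of points nearest the centroid of
all points before taking the hull; hull areas are validated against an
O(n³) gift-wrapping oracle. Kernel ranges approximate movement-based
estimation by linearly interpolating the daily path at a fixed spatial
step and fitting a single plug-in (Scott) Gaussian bandwidth per
individual; isopleth areas come from grid integration (smallest cell set
holding the stated mass), which guarantees 50% ⊆ 95% nesting. On large
bivariate-normal samples the 95% isopleth area matches the analytic
π σ² χ²₂(0.95) ellipse within 10% (the plug-in bandwidth inflates the
density's variance by ≈ n^(−1/3), which sets the scale of that error).
Tracks with fewer than 30 fixes raise an explicit insufficient-data error.
Printed per-individual range areas depend on unrecoverable smoothing
choices and are not reproduction targets; the movement summary table's
distance columns are.

## Homing and orientation

Bearing deviations are measured against the release→capture direction
(true home = 0°). Homing requires the full normalized distance (≥ 1) inside
the inclusive ±22.5° sector, or arrival within 5 km (configurable) of the
capture site or captive facility — the radius is a package convention; the
source defines no arrival radius. Classification is invariant under global
rotation and translation (property-tested).

The circular mean comes from the resultant vector; circular SD is
√(−2 ln R̄) (degrees). Sector counts over four 90° arcs centred on true
home are tested against uniformity with Pearson chi-square (a 6/6/6/5
split of 23 gives χ² = 0.13, df = 3). The in/out homing-sector counts are
compared with the expectation under universal homing; since that
hypothesis puts zero mass outside the sector, any out-of-sector
observation yields χ² = ∞ and p = 0 — the convention is documented rather
than smoothed away. Cohort mean homing angles require capture/release
coordinates that are not part of the packaged tables, so they are excluded
from validation.

## Site fidelity

Fidelity is the percentage of daily locations in the first 365 days inside
(a) the recipient reserve and (b) the union of the reserve and all other
protected areas; boundary points count as inside (deterministic and
monotone under layer union). Detection bias between near-daily GPS and
sparse VHF monitoring is reported through location counts and gap
statistics, not corrected — matching how the programme itself treated it.

## Survival

The product-limit estimator runs on the time-since-release scale with
optional left truncation for staggered calendar entry (at risk when
entry < t ≤ exit). Deaths are processed before censorings at tied days.
Variance is Greenwood's; 95% intervals are linear and clipped to [0, 1]
(the CI method in the source is unstated, so intervals are not
reproduction targets). With no censoring the estimator equals the
empirical survival function exactly; small instances are checked against
an independent hand product and against lifelines.

From the packaged fates (deaths on days 13, 14, 19, 19, 71, 71, 71, 205,
322; year-one censorings on days 11, 67, 112, 290 for the recapture and
the three collar failures), S(365) = 0.565 → 0.57. The recaptured female
is censored for wild survivorship but counted as a failure ("removed from
the wild") by the success rule — both are needed to reproduce the printed
survivorship and the 8/20 success split simultaneously. Second-year cohort
estimates are not targets: the censoring bookkeeping behind them is not
reproducible from the printed tables.

Interval-conditional survival restricts to individuals alive at the
condition day whose status at the target day is known (death recorded, or
monitoring past the target); individuals censored in between are excluded.
Months are days/30 throughout (991 days → 33.0 months, matching the
printed range).

Association tests report both the likelihood-ratio chi-square
G = 2ΣO ln(O/E) (headline — it reproduces the printed 8.63 and 6.47
exactly) and Pearson's X² (6.67 on the survival table). The two agree
asymptotically when the deviation from independence is small relative to
the margins; note they do *not* converge under plain table scaling, since
both statistics are degree-1 homogeneous. The log-rank Z uses the
hypergeometric variance; identical groups give Z = 0 and equal-hazard
simulations achieve ≈ 5% type-I error at α = 0.05.

## Success, reproduction, costs

Success = survival ≥ 365 days ∧ no homing ∧ ≤ 5 livestock/year ∧ remained
in the wild. Group-level livestock kills are attributed to every member of
the social unit (a coalition's 11 shared smallstock exceeds the threshold
for each member) — the per-row outcomes require this reading. The rule is
monotone in the conflict threshold. Applied to the packaged outcomes it
matches the recorded success column row for row: 8/20 evaluable = 40%.
Litter summaries use the midpoint median (litters {4, 2, 3, 5} → 3.5).
Costs are pass-through inputs; the Individual Conservation Cost is total
cohort cost divided by successful adults. Per-individual costs are not
packaged, so cost outputs are illustrative only.

## Recipient-area suitability

Suitability is a strict conjunction of five exclusion criteria on
co-registered grids: protected status; cheetah occurrence ∈ {low, medium}
(connectivity without saturation or vacancy); lion ≤ low; spotted hyaena
≤ low; Euclidean distance to urban points > 50 km (distance grid rather
than buffered polygons — equivalent on-grid and simpler). Because the
rules intersect, application order cannot affect the result
(property-tested over permutations). Patches are 8-connected components by
default (4-connectivity available; the original choice is unstated);
patch areas conserve total suitable area exactly. The full iteration
additionally removes patches smaller than the maximum observed exploratory
range (19,743 km² in 112 days); the second iteration omits that criterion.
Synthetic landscapes default to 2 × 2 km cells — patch areas at the
magnitudes of interest resolve comfortably at desk memory. Absolute
suitable-area figures for the real landscape require national occurrence
and protected-area layers and are out of scope; the model is validated
structurally on synthetic stacks. Natural prey availability is explicitly
not a model input.

## Synthetic data

The generators provide the statistical structure the analyses assume, not
a behavioural cheetah model. Exploration is a correlated random walk
(wrapped-normal turning, SD π/(1 + κ) with κ = 2 by default; exponential
daily step lengths, mean 12 km) for 90 days; settlement is
x_{t+1} = x_t + a(c − x_t) + ε with attraction a = 0.3, isotropic Gaussian
noise scaled so the mean settled displacement is 3 km/day. No quantitative
movement parameters exist in the source; these defaults were chosen once
to reproduce the qualitative pattern of multi-thousand-km² three-month
exploration MCPs (the defaults give ~2,000–12,000 km²) followed by
range residency, and are not tuned thereafter. Homing is a single mixture
weight bending the exploration heading toward the capture site.
Observation schemes emit 1–6 fixes/day (GPS, daily detection ≈ 1) or
single fixes with daily detection < 1 and multi-day gaps (VHF). Fates are
habituation-stratified geometric death days (constant per-day hazard) with
exponential collar-failure censoring and a categorical cause mix weighted
toward human persecution. Landscapes are Gaussian-smoothed noise fields
quantile-binned to the four-level occurrence scale, with rectangular
protected areas and random urban points.

Every generator is a pure function of (parameters, seed). What passing
validation shows: the estimators recover known inputs (hazards within
Monte-Carlo tolerance at n = 2000, settling change-points, range centres,
detection probabilities) under the assumed structure. What it does not
show: robustness to real-data features the generators omit — fix error and
habitat-driven detection bias, behavioural interaction, territoriality,
prey dynamics, non-stationary hazards.

## Problem sizes and numerics

Default test and demonstration sizes — 100-seed settling recovery, 1000-rep
type-I simulations, 2000-animal hazard recovery, 500 × 500-cell landscapes,
128–256-cell kernel grids — were chosen so the full validation cycle runs
in minutes on one CPU while keeping Monte-Carlo error well inside the
asserted tolerances. Areas and distances are planar km/km²; geographic
input can be projected with the built-in local equirectangular conversion,
adequate at study scale (hundreds of km). Degenerate inputs are explicit:
hulls of < 3 or collinear points have zero area; zero-resultant circular
means, empty conditioning sets, zero-margin tables, and
shorter-than-lookahead tracks are flagged or rejected rather than guessed.
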