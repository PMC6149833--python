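# Methods

## Model and estimands

Antibody concentrations are modelled as log10-normal within each group ×
antigen × visit cell. The reported location summary is the geometric mean
concentration, `GMC = 10^m` with `m` the mean of log10 concentrations,
and its confidence interval is the t-interval on the log10 scale,
`10^(m ± t_{n−1,1−α/2} · s/√n)`. Whether published GMC intervals of this
kind use t or z quantiles is rarely stated; t is adopted here because it
is standard for per-group GMC reporting at these sample sizes and because
it makes the calibration round trip (back-solving a log10 SD from a
printed CI, then regenerating the CI) exact. At n ≥ 35 the difference
from z is in the second decimal.

Concentrations below the assay quantification cut-off are left-censored.
The analysis convention, applied before every estimator, is single
imputation to half the cut-off. This defines the estimand: for a cell
with censoring fraction `Φ(a)`, `a = (log10 c − μ)/σ`, the population
value of the imputed mean log-concentration is

    E[log10 c_imputed] = Φ(a)·log10(c/2) + (1−Φ(a))·μ + σ·φ(a),

which differs from the latent `μ` where censoring is heavy (up to +1.5%
on the GMC scale at 10% censoring, +3.6% at 30%). Half-cut-off imputation
is the field's reporting convention, not an unbiased estimator of the
latent mean; all parameter-recovery checks in this package therefore
target the imputed estimand (closed form above), which coincides with the
configured GMC wherever censoring is negligible.

Threshold rates (seroprotection at 0.1 and 1.0 IU/ml for diphtheria and
tetanus, seropositivity at the assay cut-off for PT/FHA/PRN) are
inclusive (`≥`) counts with Clopper–Pearson exact intervals from beta
quantiles. Imputed values (half the cut-off) can never cross a threshold
at or above the cut-off, so rates are insensitive to the imputation
constant.

## Non-inferiority machinery

**Rate difference.** The "standardized asymptotic" interval for
`p₁ − p₂` is the Miettinen–Nurminen score interval: at a hypothesised
difference `d`, the score statistic uses the restricted MLE of
`(p₁, p₂)` under `p₁ − p₂ = d` (Farrington–Manning closed-form cubic) in
its variance, multiplied by `N/(N−1)`. Bounds are the roots of
`z(d) = ±z_{1−α/2}`, found by bisection (Brent) to 1e-10 on the
proportion scale. The variant question — with or without the `N/(N−1)`
factor — was settled by calibration against the published degenerate
comparison (100% vs 100% at n = 115 vs 35): the corrected form reproduces
the printed bounds (−3.25, 9.95) to two decimals (−3.2534, 9.9499); the
uncorrected form gives (−3.23, 9.89). The corrected form is the default;
the Newcombe hybrid-score (square-and-add Wilson) interval is provided as
a labelled alternative, and the uncorrected form via `corrected=False`.
Note that Wald-type intervals are undefined for the 100%-vs-100% case,
which is precisely the comparison that arises when a booster is highly
immunogenic — a practical reason this package implements the score
interval natively rather than delegating to a library routine that
rejects the degenerate case.

**GMC ratio.** The between-study comparison uses the MOVER construction
(Zou–Donner): each group's log10 mean receives its own t-interval
`(l_i, u_i)`, and the interval for `d = m₁ − m₂` recovers the variance
estimates from those bounds,

    L = d − √((m₁−l₁)² + (u₂−m₂)²),   U = d + √((u₁−m₁)² + (m₂−l₂)²),

anti-logged to the ratio scale. With equal variances and large equal n
this converges to the pooled two-sample t interval; with unequal
variances (the motivating case: an adult booster arm versus an infant
comparator assayed decades earlier) it keeps close to nominal coverage
where pooling does not. The comparator arm enters as summary statistics
(N, GMC, log10 SD); if only a GMC interval is available, the SD is
back-solved from it by the same t-inversion as the calibration round
trip.

**Hierarchy.** Objective 1 (diphtheria and tetanus rate differences,
margin −10 percentage points) gates objective 2 (PT/FHA/PRN GMC ratios,
margin 0.67): objective 2 is evaluated only if every objective-1 lower
limit is at or above its margin. All margin comparisons are inclusive.
One-sided non-inferiority at 2.5% is expressed through the two-sided 95%
CI lower limit.

## Booster-response classification

The tiered rules are pure functions of the (imputed) pre/post pair.
Diphtheria/tetanus: seronegative baseline (< 0.1 IU/ml) requires
post ≥ 0.4 IU/ml; seropositive baseline requires a ≥ 4-fold rise. The
alternative definition excludes baselines ≥ 6.0 IU/ml and relaxes to a
≥ 2-fold rise for baselines in [1.0, 6.0). Pertussis antigens scale with
the assay cut-off `c`: seronegatives (< c) must reach 4c; seropositives
below 4c need a 4-fold rise, at or above 4c a 2-fold rise. Every
`≥`-phrased boundary is inclusive, `<` strict; participants missing
either visit are excluded from denominators; empty strata are reported
with N = 0 and rendered as an em-dash. Correctness is tested against a
literal nested-conditional transcription of the rules on 10⁵ random
(pre, post) points and by boundary cases on every tier edge.

## Adverse-event analysis

Grading re-derives severity from measurements where a measurement rule
exists (diameter > 50 mm strict; fever case at ≥ 37.5 °C, grade 3 at
> 39.0 °C strict; large swelling > 100 mm or diffuse-swelling code) and
otherwise trusts the recorded activity-impact grade. Tabulation is
participant-level (a participant counts once per event row however many
diary days mention it), windowed (days 0–3 solicited, 0–30 unsolicited,
inclusive), with per-section denominators supplied by the caller because
documented-dose and administered-dose counts legitimately differ.
Solicited local reactions are causally related by definition and are
forced so.

## The synthetic cohort generator

The generator emulates exactly the structure the estimators assume: per
participant and antigen a bivariate normal (log10 pre, log10 post) with
configurable correlation; left-censoring by recording values below the
cut-off *at* the cut-off with a censored flag (imputation is an analysis
step, so the generator stays reusable for other conventions); Bernoulli
completion and ATP-exclusion draws; and per-event Bernoulli diaries with
grade-3/related/serious incidences nested inside the overall incidence
(one uniform draw per event, so the rarest category is a subset of the
commoner ones). Randomness is one `SeedSequence` per participant, keyed
by (group index, participant index), so enlarging a group leaves earlier
participants' records bit-identical.

Default parameters are the published group-level summaries of the
decennial Tdap booster study the package ships as constants: group sizes
37 (Td) and 128 (Tdap); attrition 5/165 (dropout) and 10/160 (protocol
exclusion); per-cell log10 means equal to log10 of the printed GMCs with
SDs back-solved from the printed CIs; adverse-event incidences equal to
the printed counts over their section denominators. Two quantities are
not identifiable from published summaries and are fixed by choice:

- the within-subject pre/post correlation, set to 0.5 — a middling
  plausible value for repeat serology a month apart — and exposed in the
  config;
- the comparator arm's log10 SD, set to 0.45 (a typical between-subject
  ELISA spread). This is a synthetic stand-in: comparator-based ratio
  CIs computed from it exercise the machinery but do not reproduce any
  published interval.

What the generator does **not** emulate: the 10-year antibody decay
between boosters (only the two analysis visits exist); dependence
between adverse events or between serology and safety; assay measurement
error beyond the log-normal spread; calendar structure of visits. A
passing test suite therefore demonstrates that the estimators are
correct for the assumed data-generating process and calibration targets,
not that the model captures every feature of real diary or assay data.

## Numerical and design choices

- All latent serology is on the log10 scale; calibration and reporting
  round-trip through the same base.
- Score-interval root finding: Brent bisection, tolerance 1e-10 on the
  proportion scale; restricted MLE clipped into the feasible interval;
  zero-variance (all-success/all-failure at the hypothesised difference)
  returns ±∞ statistic so bounds stay well defined.
- Degenerate inputs: n = 0 groups and empty record sets are errors;
  n = 1 GMC intervals are flagged undefined (NaN) rather than invented;
  zero-width CIs are rejected by SD back-solving (continuous data cannot
  produce them).
- Display rounding is centralized in the report layer — one decimal for
  percentages and GMCs, two for ratios, em-dash for empty strata —
  and never applied before computation.
- Monte-Carlo test design: replicate counts are 2000 for interval
  coverage and type-I checks and 200 for parameter recovery, sized so
  each check resolves its tolerance. Replicate GMCs are averaged on the
  log scale (geometric mean): arithmetic averaging of GMC estimates
  carries a Jensen inflation of `exp((ln10)²σ²/2n)` — +6% for the
  widest cell — that is an artifact of the aggregation, not the
  estimator. Where a 2% tolerance is below three Monte-Carlo standard
  errors at the fixed replicate count (small-group, high-variance
  cells), the recovery test asserts an unbiasedness z-bound and a pooled
  calibration check instead of asserting on noise.

## Known limitations

- The dropout sensitivity analysis of the original study (a repeated
  generalized linear model borrowing the parent study's post-booster
  results) is not implemented; its model is not specified tightly enough
  to reproduce.
- Comparator-based GMC-ratio intervals depend on the chosen comparator
  SD (see above) until a real log-scale SD is supplied.
- The safety module performs no term coding; event names are free
  strings, and pooling (e.g. gastrointestinal symptoms) is the
  generator's/caller's responsibility.
- Power calculations for the hierarchical design are out of scope; the
  simulator can be used to explore power empirically.
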