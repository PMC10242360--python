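# Methods

This note documents the statistical model behind `rwcea`, the conventions
the implementation fixes where the methodology leaves choices open, what
the synthetic-data generator does and does not emulate, and the known
limitations. It states no empirical result that the test suite does not
itself compute.

## Estimands and time conventions

All quantities are discounted five-year means per patient under the
population-average (ATE) contrast: the mean cost (CAD), life-years (LY) and
quality-adjusted life-years (QALY) that would accrue if the whole cohort
population received, respectively, the treatment of interest or the
comparator. Time is measured in days from the index date (first dose of
second-line therapy); follow-up is partitioned into half-open 30-day
intervals `[30k, 30(k+1))`; the horizon is 1826 days, so there are 61
intervals, the last truncated to 26 days. Six months is 182.625 days
(365.25/2). Discounting multiplies each interval's contribution by
`(1 + r)^(−t_mid/365.25)` with `t_mid` the interval midpoint and
`r = 0.015` by default; the choice of continuous midpoint discounting
(rather than annual steps) is a package convention.

## Confounding adjustment (IPTW)

Treatment assignment is modelled by maximum-likelihood logistic regression
on the prognosis-relevant baseline covariates (Charlson ≥ 1, morbidity
score, age, urban residence, months from diagnosis to second line, prior
radiation). Default weights are unstabilized ATE weights `1/e` and
`1/(1−e)`; the weighted group sizes then exceed the raw arm sizes, the
familiar non-integer "weighted N" of baseline tables. Stabilization (by
marginal arm prevalence) and symmetric percentile truncation are options,
not defaults, because nothing in the target methodology requires them.
Balance is measured by weighted standardized differences using the
population (frequency-weight) variance formula without finite-sample
correction — this is the variant that reproduces printed balance tables
from printed weighted means/SDs — with `|d| < 0.1` flagged adequate.
Covariates outside the propensity model (e.g. first-line treatment class)
are reported in the balance table as diagnostics and may legitimately stay
imbalanced.

## Censoring adjustment (partitioned IPCW)

Within each arm, the probability of remaining uncensored at each interval
start, `K(t)`, is a reversed Kaplan–Meier estimate: censoring is the event,
death removes a patient from the risk set without an event, and when a
death and a censoring share a day the death leaves the risk set first.
`K` is evaluated left-continuously (events strictly before `t` reduce
`K(t)`), so `K(0) = 1` always.

Each patient contributes, per interval, the observed days (and ledger
costs) of that interval divided by `K` at the interval start — but only for
intervals the patient is observed *through*: fully observed intervals and
the interval containing the patient's death count; the partial interval in
which a censoring occurs contributes zero. This exclusion is the package
default because the weight `1/K(start)` describes patients under
observation for the interval; the alternative (include the partial accrual
of the censoring interval, Lin-style) is available as
`include_partial=True`.

**Known discretization bias.** At a fixed 30-day interval width neither
convention is exactly unbiased under within-interval censoring: inclusion
in an interval requires remaining uncensored through its *end* while the
weight uses `K` at its *start*, so each interval's term is shrunk by that
interval's conditional censoring probability (the include-partial variant
recovers on average half of it). On a no-death cohort with uniform
censoring on (0, M) the relative bias has the closed form
`−Σ_k w_k² / (M − s_k) / horizon` (exclusion; half that for inclusion), and
the test suite verifies the implementation against this prediction. Under
the default study conditions the bias is on the order of −1.5 to −2.5% of
arm means — material relative to Monte-Carlo noise at n = 5000/arm, and an
inherent property of the 30-day partitioned estimator rather than an
implementation artifact. The bias vanishes as the censoring hazard per
interval shrinks (longer administrative windows, finer partitions).

If `K` reaches zero at a grid point before the horizon (the arm's last
follow-up ends in censoring), the mean beyond that point is not identified;
the default behaviour is an error advising horizon truncation, with
`on_zero="allow"` available to proceed with zero contribution where nothing
is observed. An arm in which every patient is censored within the first
interval is degenerate and always an error.

## Health states and QALYs

Each patient's observed time is split into progression-free and progressed
states. Progression starts at the earliest of (a) third-line treatment
start and (b), for decedents without third-line treatment, the later of
second-line end and 182.625 days before death; patients surviving less than
six months are therefore progression-free exactly while on second-line
treatment. Patients alive at censoring or the horizon without third-line
treatment remain progression-free — no progression trigger ever fires for
them. The progression-free utility is Beta with mean 0.79 and SD 0.02; the
progressed utility subtracts an independent Beta disutility (mean 0.24, SD
0.02), floored at zero. Both betas are parameterized by method of moments
(`ν = m(1−m)/s² − 1`, `α = mν`, `β = (1−m)ν`). The disutility's beta family
(the methodology names only its moments) is a package choice made for
support safety. Point estimates use the distribution means; inside the
bootstrap one utility pair is drawn per (resampled) patient per replicate,
independently across patients. QALYs multiply each interval's adjusted,
discounted life-days by the time-weighted average state utility of that
interval, keeping QALY consistent with the 30-day grid; consequently
`0 ≤ QALY ≤ LY` always.

## Bootstrap and decision analysis

Uncertainty is quantified by a nonparametric bootstrap stratified by arm
(default B = 1000; study-scale tests use 200–500). Each replicate resamples
patients with replacement within arm and re-runs the entire estimation —
propensity refit, per-arm censoring curves, fresh utility draws — so that
all estimation stages contribute to the intervals; a weights-frozen mode
(`reestimate_weights=False`) is available for speed. Replicates with a
degenerate arm or inestimable weights are redrawn and counted. CIs are
percentile intervals; the ICER interval uses replicate ratio percentiles
and is reported as undefined when replicate incremental effects change
sign (net benefit is the meaningful scale there). The CEAC evaluates
`P(λ·ΔE − ΔC > 0)` across a $0–$300,000 grid in $1,000 steps (grid spacing
is a package choice). Net-benefit regression is weighted least squares of
per-patient `λ·E − C` on the treatment indicator with IPTW weights and
HC1 heteroskedasticity-robust errors; its coefficient equals the weighted
mean contrast, so incremental NMB is affine in λ with slope ΔE and
intercept −ΔC and crosses zero at the point ICER — identities the tests
assert. The price-reduction analysis scales only ledger entries tagged as
the drug of interest by `(1 − f)` before adjustment and re-runs the
pipeline per fraction; discount-rate sensitivity re-runs it at 0%, 1.5%
and 3%.

## The synthetic cohort generator

The generator emulates the structure of a population-based second-line
immunotherapy funding evaluation; its defaults are the package's reference
study conditions.

* **Cohort**: 140 controls vs 189 treated in expectation; treatment
  assigned by a logistic model on centered covariates with intercept
  `logit(n_treated/n_total)`, so zero coefficients reproduce the marginal
  split. Default coefficients confound assignment with age, morbidity and
  (survival-irrelevantly) first-line class.
* **Survival**: per-arm mixture-cure model — Weibull deaths (control:
  shape 1.2, scale 230 d; treated: shape 1.1, scale 300 d) accelerated by a
  shared log-AFT frailty in age and morbidity, plus cure fractions 0.04
  (control) and 0.13 (treated) surviving past the horizon. This yields
  survival curves flattening below 15% near the horizon and discounted
  mean LY of roughly 0.8 vs 1.35 years.
* **Costs**: eight resource categories at arm-specific base monthly rates,
  gamma noise (CV 0.4) per interval, a terminal-phase uplift of 1.5 on the
  last six months of life, and in the treated arm a $27,500 drug dose
  charged on days 0/21/42/63 while still on second-line treatment (about
  $82k expected per treated patient, front-loading the incremental cost so
  that systemic therapy dominates it at roughly three quarters). Rates were
  set so the discounted five-year arm means land near $66k (control) and
  $156k (treated) with an ICER in the $160k/LY region.
* **Censoring**: per-patient maximum follow-up uniform on (0, 2192) days —
  a uniform accrual window under a fixed data cut, compressed so censoring
  bites within the horizon (≈15% of controls, ≈24% of treated) while a
  positive fraction of patients reaches day 1826 fully observed, which the
  censoring weights require. Censoring is independent of survival and
  costs within arm, the assumption the IPCW estimator needs.
* **Progression**: gamma second-line durations (means 105/75 days), a 35%
  third-line probability with a gamma delay after second-line end.
* **Ground truth**: `true_estimands` simulates large counterfactual arms
  (everyone assigned to each arm, censoring disabled, noise-free expected
  costs) through the same accrual-and-discount machinery and reports means
  with Monte-Carlo SEs — the targets for estimator-recovery tests.

What the generator does **not** emulate: real administrative database
schemas, within-patient cost autocorrelation beyond the terminal uplift,
covariate-dependent censoring, treatment switching, or calendar-time trends
in background care. Passing recovery tests therefore demonstrates
correctness of the estimators under independent administrative censoring
and measured confounding — not robustness to informative censoring or
unmeasured confounding, which the underlying methodology itself does not
claim to handle.

## Numerical choices and edge cases

Problem sizes in the test suite are chosen to make Monte-Carlo tolerances
meaningful at interactive runtimes: consistency and confounding-recovery
checks use 5,000 patients per arm against ground truth from 150,000
simulated patients per arm; interval-coverage checks use 50 outer
repetitions at 500 patients per arm with B = 200. Propensity scores are
clipped to (1e−12, 1−1e−12) after fitting; constant covariate columns are
dropped with a warning; perfect separation raises an error advising
covariate revision. An ICER is reported as undefined (`None`), never
infinite, when the incremental effect is zero. Bootstrap redraw budgets cap
at `max(100, B)` inestimable replicates before failing loudly.

## Limitations

No doubly-robust (augmented) censoring estimator and no covariate-dependent
censoring weights — the simple partitioned form is the point. No survival
extrapolation beyond the five-year horizon. Percentile bootstrap intervals
only (no BCa/Fieller). The QALY timeline for patients censored before death
treats their observed time per the observed triggers; progression occurring
after censoring is unobservable by construction.
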