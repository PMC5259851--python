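# Methods

## The estimand

For event time `T` and binary exposure `Z`, the attributable risk at time `t`
contrasts the factual cumulative incidence with the counterfactual incidence
under exposure removal:

    A(t) = [P(T ≤ t) − P(T ≤ t | Z = 0)] / P(T ≤ t)
         = 1 − (1 − S0(t)) / (1 − S(t)).

`A(t)` is undefined at `t = 0` (0/0) and wherever no events have occurred;
every estimator in this package reports such times as missing (NaN) rather
than zero. Estimates may be negative early in follow-up when, by chance, the
baseline group has accumulated more events than the population average; they
are returned as-is.

## Estimators

**Nonparametric (KM, WKM).** `S0` is the Kaplan-Meier curve of the stratum
coded 0 (by default the unexposed). For KM, `S` is the pooled Kaplan-Meier
curve; for WKM it is `(1/n) Σ_k n_k Ŝ_k(t)`, the stratum-size-weighted
average of per-stratum KM curves, which stays consistent when censoring
depends on the (categorical) covariate. Ties between events and censorings
at the same time follow the standard convention that events come first.
Evaluation at an arbitrary `t` takes the value at the closest preceding
observed event time (right-continuous step semantics). The nonparametric path
is restricted to categorical covariates by construction.

**Semiparametric (COX).** A Cox model `λ(t|Z) = λ0(t) e^{βZ}` is fitted by
Newton-Raphson on the scalar partial likelihood with Breslow tie handling —
chosen to match the Breslow baseline estimator, so the fitted pair (β̂, Λ̂0)
is internally consistent and run-to-run stable. Convergence requires a Newton
step or score below 1e-9; monotone likelihoods are detected a priori from the
score limits at β → ±∞ and reported as divergence errors. Then
`Ŝ0(t) = exp{−Λ̂0(t)}` and `Ŝ(t) = (1/n) Σ_i exp{−e^{β̂ z_i} Λ̂0(t)}`. For
the fixed covariates supported here the general time-dependent-covariate
integral reduces to `e^{β̂ z_i} Λ̂0(t)`; covariate paths are deliberately out
of scope. An optional administrative-censoring argument truncates follow-up
before fitting, supporting shorter-follow-up comparisons.

**Parametric (PCH).** Follow-up is partitioned at cutpoints
`0 = a_0 < a_1 < … < a_J` (default four 5-year intervals over [0, 20]); the
baseline hazard is `exp(α_j)` on interval `j` and exposure acts through
`e^β`. The log-likelihood is the piecewise exponential one, equivalent to a
Poisson log-linear model on the subject×interval expansion with log
person-time offsets; we maximize it by Newton-Raphson on the sufficient
statistics (events and person-time per interval × exposure group), starting
from `α_j = log(pooled events_j / person-time_j)` and `β = 0`. The observed
information at the optimum gives the parameter covariance. An interval with
zero pooled events makes the likelihood unbounded below in `α_j`; fitting
raises an explicit empty-interval error, and the simulation harness — not the
fitter — discards and regenerates such datasets. Model survivals
`Ŝ_PCH(t|Z) = exp{−Σ_j e^{α̂_j + β̂Z} δ_j(t)}` use the interval exposure
times `δ_j(t)` (0 before the interval, `t − a_{j−1}` inside it, the full
width after). No extrapolation beyond `a_J` is allowed.

**Global (Simpler / Spiegelman).** `AR = q(RR − 1)/{1 + q(RR − 1)}` with
`RR = e^{β̂}` from the Cox fit and `q` either the baseline exposure
proportion or the exposed share of person-years. Because exposed subjects
fail earlier, the person-years prevalence is smaller, and under proportional
hazards the global value exceeds `A(t)` at every interior time. The
denominator `(1 − q) + q·RR` is strictly positive for valid inputs; the
guard against a nonpositive denominator is defensive only.

## Variance estimation

The closed-form counting-process variances for the KM/WKM/COX attributable
risks exist in the literature but are not reproduced here; instead those
methods use a subject-level nonparametric bootstrap (resample `n` subjects
with replacement, recompute Â(t); default 200 replicates, seedable). This is
a deliberate design choice: it is testable against the coverage behaviour it
must produce, and an influence-function variance can later be added behind
the same `variance_method` interface. Bootstrap resamples that lose the
baseline stratum or separate the exposure groups are skipped; a time point
needs at least 10 finite bootstrap values to report a standard error.

The PCH variance uses the delta method: the gradient of Â(t) with respect to
(α, β) is computed by central finite differences with step
`1e-6 · max(1, |parameter|)` and propagated through the inverse observed
information. The differences route was chosen over hand-derived analytic
gradients because the bootstrap provides an independent arbiter: tests
require delta and 500-replicate bootstrap standard errors to agree within
15% relative. The global estimator's delta method treats `q̂` and `β̂` as
asymptotically independent (binomial term plus inverse partial-likelihood
information); with person-years prevalence the same binomial-style `q`
variance is used as an approximation, and the bootstrap remains available as
a cross-check.

Confidence intervals are Wald, by default on the identity scale; a
complementary-log option builds the interval on `ln{1 − A(t)}` and
back-transforms, keeping the upper limit below 1.

## The simulator

The generator emulates a prospective cohort with a fixed binary exposure
drawn as Bernoulli(q), q ∈ {0.25, 0.5, 0.75} in the study scenarios:

- **PH**: Weibull baseline hazard `γ θ^{−γ} t^{γ−1}` with γ ∈ {3/4, 1, 4/3}
  and `θ = 15/(ln 2)^{1/γ}` years, so the unexposed median survival is 15
  years in every scenario; log hazard ratio β ∈ {0, ln 2}. Event times are
  drawn by inverse CDF, `t = θ[−ln U / e^{βZ}]^{1/γ}`, which is the inversion
  consistent with `S(t|Z) = exp{−(t/θ)^γ e^{βZ}}`; a Kolmogorov-Smirnov test
  against the closed-form CDF at n = 100,000 guards this property.
- **NPH**: `Λ(t|Z) = ln(1 + 2 λ0 t e^{βZ})/2` with λ0 = 0.1/year (again a
  15-year unexposed median); `t = (U^{−2} − 1)/(2 λ0 e^{βZ})`. The hazard
  ratio decays from `e^β` at t = 0 toward 1, violating proportionality.

Censoring is Uniform[0, τ] with τ = 20 years, independent of exposure and
event time, giving roughly 45-70% censoring across scenarios. Per subject the
draws occur in the fixed order exposure → event uniform → censoring, so a
seed pins a dataset byte-for-byte. Replicate `r` (and regeneration attempt
`a` after a discard) uses the independent stream
`SeedSequence(seed, spawn_key=(r, a))`, making any replicate reproducible in
isolation and the aggregate independent of execution order.

What the generator does *not* emulate: covariate-dependent censoring,
left truncation/delayed entry, competing risks, time-varying exposure, and
continuous covariates. Passing tests therefore demonstrate correctness of
the estimators under independent censoring and a point exposure; they say
nothing about those harder real-data features, which the estimators (WKM
aside, for censoring) do not claim to handle.

## Evaluation harness

For each scenario the harness evaluates every method at τ/4, τ/2, 3τ/4, τ
and aggregates: signed mean bias against the closed-form A(t) (the sign is
kept, since late-follow-up biases are systematically positive), mean
estimated standard error (SEE), empirical standard deviation (SSD), and the
coverage of nominal 95% Wald intervals. Replicates with an undefined Â(t)
(no events by `t`) are excluded from all four aggregates at that time, with
exclusion counts reported — imputation would mix estimand and availability.
Coverage additionally requires a finite standard error; such exclusions are
counted separately. Replicates any method fails on (empty PCH interval,
monotone Cox likelihood) are discarded, counted, and regenerated from the
next substream.

Typical problem sizes: the unit and property tests run at n ≤ 40,000 with a
handful of Monte-Carlo replicates; the end-to-end checks use one n = 100,000
cohort for consistency, 250 replicates at n = 1,000 (with 200 bootstrap
resamples per replicate for the semiparametric standard errors) for the
proportional-hazards metrics, and 1,000 point-estimate replicates at
n = 1,000 for the nonproportional-hazards biases. These sizes keep
Monte-Carlo standard errors small enough that all published-table
comparisons are made at 3 Monte-Carlo standard errors of the difference
between two finite simulations.

## Numerical and degenerate-input choices

- Survival-curve evaluation before the first jump returns 1; A(t) there is
  missing, never 0.
- KM risk sets count same-time censored subjects as still at risk (events
  precede censorings).
- Cox: β bounded at |β| ≤ 30 as a divergence tripwire behind the a-priori
  monotone-likelihood check; variance from the inverse information at β̂.
- PCH: cutpoints must cover the largest follow-up time; event-at-cutpoint
  times belong to the left-closed interval `(a_{j−1}, a_j]`.
- Wald intervals with se = 0 are degenerate [est, est]; missing se gives a
  missing interval.
- All CSV I/O is comma-separated, period-decimal, UTF-8, header mandatory;
  times are in years throughout, with no unit inference.

## Known limitations

- Single binary exposure (plus optional categorical strata for WKM); no
  multivariable adjustment, continuous covariates, left truncation or
  competing risks.
- Bootstrap rather than closed-form variances for KM/WKM/COX: roughly 200×
  the point-estimation cost when standard errors are requested, and slightly
  conservative in very small samples.
- The global delta method ignores the (small, positive) dependence between
  prevalence and hazard-ratio estimates.
- Under nonproportional hazards the COX and PCH estimators are inconsistent
  for A(t) by design — that failure mode is a study outcome, not a bug; the
  harness quantifies it (late-time bias ≈ +0.03 at the study's NPH settings,
  with coverage collapsing as n grows).
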