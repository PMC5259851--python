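"""Semiparametric attributable risk via a Cox model with Breslow baseline.

The hazard of subject i is λ(t|Z_i) = λ0(t) exp(β Z_i) with a single binary
exposure Z.  β is estimated by maximum partial likelihood (Breslow tie
handling, matching the Breslow baseline), the baseline cumulative hazard by
the Breslow estimator

    Λ0(t) = Σ_{event times s ≤ t} d(s) / Σ_{j at risk at s} exp(β Z_j),

and the survival functions entering A(t) = 1 - (1 - S0(t)) / (1 - S(t)) are

    S0(t) = exp[-Λ0(t)],
    S(t)  = (1/n) Σ_i exp[-exp(β Z_i) Λ0(t)],

i.e. the average of the model-implied per-subject survivals with covariates
fixed at their observed values (for fixed covariates the general
time-dependent integral collapses to exp(β z_i)·Λ0(t)).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._stats import bootstrap_sd, wald_ci
from .cohort import ARCurve, CohortSample, ConvergenceError, SurvivalCurve

__all__ = ["CoxFit", "fit_cox", "ar_cox"]

_MAX_ITER = 60
_TOL = 1e-9  # convergence: |Newton step| or |score| below this
_BETA_BOUND = 30.0  # |beta| beyond this signals monotone likelihood


@dataclass(frozen=True)
class CoxFit:
    """Result of a binary-exposure Cox partial-likelihood fit."""

    beta: float
    var_beta: float
    event_times: np.ndarray  # distinct event times (ascending)
    cumhaz: np.ndarray  # Breslow baseline cumulative hazard at event_times
    loglik: float
    converged: bool
    n_events: int

    def baseline_cumhaz(self, t):
        """Λ̂0 evaluated as a right-continuous step function (0 before the
        first event)."""
        t = np.asarray(t, dtype=float)
        idx = np.searchsorted(self.event_times, t, side="right") - 1
        out = np.where(idx >= 0, self.cumhaz[np.clip(idx, 0, None)], 0.0)
        return out if out.ndim else float(out)

    def baseline_survival(self) -> SurvivalCurve:
        return SurvivalCurve(self.event_times, np.exp(-self.cumhaz))


def _risk_set_counts(sample: CohortSample):
    """Distinct event times with event counts (total/exposed) and at-risk
    counts (unexposed/exposed).  Subjects censored exactly at an event time
    are still at risk there (events precede censorings)."""
    time, event, z = sample.time, sample.event, sample.exposure
    ev = event == 1
    if not ev.any():
        raise ConvergenceError("no events in the sample; Cox fit impossible")
    te, inverse = np.unique(time[ev], return_inverse=True)
    d = np.bincount(inverse, minlength=te.size).astype(float)
    d1 = np.bincount(inverse, weights=z[ev].astype(float), minlength=te.size)
    t1_sorted = np.sort(time[z == 1])
    t0_sorted = np.sort(time[z == 0])
    r1 = t1_sorted.size - np.searchsorted(t1_sorted, te, side="left")
    r0 = t0_sorted.size - np.searchsorted(t0_sorted, te, side="left")
    return te, d, d1, r0.astype(float), r1.astype(float)


def fit_cox(sample: CohortSample, admin_censor_time: float | None = None) -> CoxFit:
    """Maximum partial likelihood fit of the binary-exposure Cox model.

    Newton-Raphson on the scalar log partial likelihood (Breslow ties);
    the information at the optimum gives ``var_beta``.  Raises
    :class:`ConvergenceError` on monotone likelihood (all events effectively
    in one exposure group) or absence of events.
    """
    if admin_censor_time is not None:
        sample = sample.truncate_follow_up(admin_censor_time)
    te, d, d1, r0, r1 = _risk_set_counts(sample)
    total_d1 = d1.sum()
    # The score is decreasing in beta; a finite root exists iff its limits
    # bracket zero.  As beta -> +inf, p_e -> 1 wherever an exposed subject is
    # at risk; as beta -> -inf, p_e -> 0 wherever an unexposed one is.
    score_at_plus_inf = total_d1 - d[r1 > 0].sum()
    score_at_minus_inf = total_d1 - d[r0 == 0].sum()
    if score_at_plus_inf >= 0 or score_at_minus_inf <= 0:
        raise ConvergenceError(
            "monotone partial likelihood: the score has no finite root "
            "(events are separated by exposure)"
        )
    beta = 0.0
    converged = False
    for _ in range(_MAX_ITER):
        w1 = r1 * np.exp(beta)
        p = w1 / (w1 + r0)
        score = total_d1 - np.sum(d * p)
        info = np.sum(d * p * (1.0 - p))
        if info <= 0:
            raise ConvergenceError("zero partial-likelihood information")
        step = score / info
        beta += step
        if abs(beta) > _BETA_BOUND:
            raise ConvergenceError("partial likelihood diverged (|beta| too large)")
        if abs(step) < _TOL or abs(score) < _TOL:
            converged = True
            break
    w1 = r1 * np.exp(beta)
    denom = w1 + r0
    loglik = float(beta * total_d1 - np.sum(d * np.log(denom)))
    cumhaz = np.cumsum(d / denom)
    info = float(np.sum(d * (w1 / denom) * (1.0 - w1 / denom)))
    return CoxFit(
        beta=float(beta),
        var_beta=1.0 / info,
        event_times=te,
        cumhaz=cumhaz,
        loglik=loglik,
        converged=converged,
        n_events=int(d.sum()),
    )


def _ar_point_from_fit(fit: CoxFit, n0: int, n1: int, times: np.ndarray) -> np.ndarray:
    lam = np.atleast_1d(fit.baseline_cumhaz(times))
    s0 = np.exp(-lam)
    s = (n0 * s0 + n1 * np.exp(-np.exp(fit.beta) * lam)) / (n0 + n1)
    denom = 1.0 - s
    with np.errstate(divide="ignore", invalid="ignore"):
        ar = 1.0 - (1.0 - s0) / denom
    return np.where(denom > 0, ar, np.nan)


def ar_cox(
    sample: CohortSample,
    times,
    variance_method: str = "bootstrap",
    boot_reps: int = 200,
    seed: int | None = None,
    admin_censor_time: float | None = None,
    ci_transform: str = "identity",
    level: float = 0.95,
) -> ARCurve:
    """Semiparametric attributable-risk curve from a Cox/Breslow fit.

    Before the first event the pooled survival is 1 and A(t) is undefined
    (NaN).  Bootstrap standard errors refit the Cox model on each resample;
    resamples with monotone likelihood are skipped.
    """
    if variance_method not in ("bootstrap", "none"):
        raise ValueError("variance_method must be 'bootstrap' or 'none'")
    if admin_censor_time is not None:
        sample = sample.truncate_follow_up(admin_censor_time)
    times = np.atleast_1d(np.asarray(times, dtype=float))
    n1 = int(sample.exposure.sum())
    n0 = sample.n - n1
    fit = fit_cox(sample)
    est = _ar_point_from_fit(fit, n0, n1, times)
    if variance_method == "bootstrap":
        rng = np.random.default_rng(seed)
        draws = np.full((boot_reps, times.size), np.nan)
        for b in range(boot_reps):
            boot = sample.resample(rng)
            try:
                bfit = fit_cox(boot)
            except ConvergenceError:
                continue
            bn1 = int(boot.exposure.sum())
            draws[b] = _ar_point_from_fit(bfit, boot.n - bn1, bn1, times)
        se = bootstrap_sd(draws)
    else:
        se = np.full(times.size, np.nan)
    lo, hi = wald_ci(est, se, level=level, transform=ci_transform)
    return ARCurve("COX", times, est, se, lo, hi, transform=ci_transform)
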