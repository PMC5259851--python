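"""Parametric attributable risk under piecewise constant hazards (PCH).

Follow-up is partitioned into J prespecified intervals (a_0=0, a_1], ...,
(a_{J-1}, a_J].  The baseline hazard is constant at exp(α_j) inside interval
j and the exposure acts proportionally through exp(β), so

    S_PCH(t | Z) = exp{ - Σ_j exp(α_j + β Z) δ_j(t) },

with δ_j(t) the time at risk accrued in interval j by time t.  The model is a
piecewise exponential likelihood — equivalent to a Poisson log-linear model on
interval-expanded data with log person-time offsets — maximized here by
Newton-Raphson on the sufficient statistics (events and person-time per
interval × exposure group).  A(t) plugs the averaged parametric survivals into
A(t) = 1 - (1 - S0(t)) / (1 - S(t)); its standard error comes from the delta
method through the inverse observed information.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._stats import bootstrap_sd, wald_ci
from .cohort import ARCurve, CohortSample, ConvergenceError, EmptyIntervalError

__all__ = ["PCHFit", "exposure_time", "fit_pch", "ar_pch", "DEFAULT_CUTPOINTS"]

DEFAULT_CUTPOINTS = (5.0, 10.0, 15.0, 20.0)  # four 5-year intervals

_MAX_ITER = 100
_TOL = 1e-10


def _check_cutpoints(cutpoints) -> np.ndarray:
    a = np.asarray(cutpoints, dtype=float)
    if a.ndim != 1 or a.size == 0:
        raise ValueError("cutpoints must be a nonempty 1-d sequence")
    if a[0] <= 0 or np.any(np.diff(a) <= 0):
        raise ValueError("cutpoints must be strictly increasing and positive")
    return a


def exposure_time(t, cutpoints) -> np.ndarray:
    """Time at risk δ_j(t) accrued in each interval j by time t.

    δ_j(t) = 0 for t ≤ a_{j-1}, t - a_{j-1} on (a_{j-1}, a_j], and the full
    width a_j - a_{j-1} beyond a_j; components sum to min(t, a_J).  Accepts a
    scalar or an array of times (last axis indexes intervals).
    """
    a = _check_cutpoints(cutpoints)
    lower = np.concatenate(([0.0], a[:-1]))
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("time must be nonnegative")
    delta = np.clip(t_arr[..., None] - lower, 0.0, a - lower)
    return delta


@dataclass(frozen=True)
class PCHFit:
    """Fitted piecewise-constant-hazards model.

    ``alpha`` holds the J log baseline hazards, ``beta`` the log hazard
    ratio, ``cov`` the (J+1)×(J+1) inverse observed information for
    (α_1..α_J, β).
    """

    cutpoints: np.ndarray
    alpha: np.ndarray
    beta: float
    cov: np.ndarray
    loglik: float
    converged: bool
    events: np.ndarray  # events per interval × exposure group, shape (J, 2)
    person_time: np.ndarray  # person-time per interval × exposure group

    @property
    def n_intervals(self) -> int:
        return self.alpha.size

    def survival(self, t, z: int) -> np.ndarray:
        """Model survival S_PCH(t | Z=z); t must not exceed the last cutpoint."""
        a = self.cutpoints
        t_arr = np.asarray(t, dtype=float)
        if np.any(t_arr > a[-1] + 1e-12):
            raise ValueError(
                f"time beyond the last cutpoint a_J={a[-1]}; no extrapolation"
            )
        delta = exposure_time(t_arr, a)
        rates = np.exp(self.alpha + self.beta * z)
        return np.exp(-delta @ rates)


def _sufficient_stats(sample: CohortSample, cutpoints: np.ndarray):
    a = cutpoints
    if np.any(sample.time > a[-1] + 1e-12):
        raise ValueError(
            "follow-up times extend beyond the last cutpoint; extend the grid"
        )
    delta = exposure_time(sample.time, a)  # (n, J)
    z = sample.exposure.astype(float)
    person_time = np.stack(
        [delta[z == 0].sum(axis=0), delta[z == 1].sum(axis=0)], axis=1
    )
    # interval containing each event time: (a_{j-1}, a_j]
    interval = np.searchsorted(a, sample.time, side="left")
    interval = np.clip(interval, 0, a.size - 1)
    ev = sample.event == 1
    events = np.zeros((a.size, 2))
    np.add.at(events, (interval[ev], sample.exposure[ev].astype(int)), 1.0)
    return events, person_time


def fit_pch(
    sample: CohortSample, cutpoints=DEFAULT_CUTPOINTS, fit_exposure: bool = True
) -> PCHFit:
    """Maximum likelihood fit of the piecewise exponential model.

    With ``fit_exposure=False`` the log hazard ratio is fixed at 0 and only
    the interval rates are estimated (their MLE is the classical
    events/person-time ratio).  Raises :class:`EmptyIntervalError` when any
    interval has zero events pooled over exposure groups (the corresponding
    α_j would diverge to -∞).
    """
    a = _check_cutpoints(cutpoints)
    events, person_time = _sufficient_stats(sample, a)
    d_pooled = events.sum(axis=1)
    if np.any(d_pooled == 0):
        empty = np.nonzero(d_pooled == 0)[0]
        lower = np.concatenate(([0.0], a[:-1]))
        spans = ", ".join(f"({lower[j]:g}, {a[j]:g}]" for j in empty)
        raise EmptyIntervalError(f"no events in interval(s) {spans}")
    J = a.size
    if not fit_exposure:
        rates = d_pooled / person_time.sum(axis=1)
        alpha = np.log(rates)
        cov = np.zeros((J + 1, J + 1))
        cov[np.arange(J), np.arange(J)] = 1.0 / d_pooled  # Poisson rate variance
        mu = d_pooled
        loglik = float(np.sum(d_pooled * alpha - mu))
        return PCHFit(
            cutpoints=a,
            alpha=alpha,
            beta=0.0,
            cov=cov,
            loglik=loglik,
            converged=True,
            events=events,
            person_time=person_time,
        )
    if np.all(person_time[:, 1] == 0) or np.all(person_time[:, 0] == 0):
        raise ConvergenceError("one exposure group contributes no person-time")
    alpha = np.log(d_pooled / person_time.sum(axis=1))
    beta = 0.0
    converged = False
    d1 = events[:, 1]
    for _ in range(_MAX_ITER):
        mu0 = np.exp(alpha) * person_time[:, 0]
        mu1 = np.exp(alpha + beta) * person_time[:, 1]
        score = np.concatenate([d_pooled - (mu0 + mu1), [d1.sum() - mu1.sum()]])
        info = np.zeros((J + 1, J + 1))
        info[np.arange(J), np.arange(J)] = mu0 + mu1
        info[:J, J] = mu1
        info[J, :J] = mu1
        info[J, J] = mu1.sum()
        try:
            step = np.linalg.solve(info, score)
        except np.linalg.LinAlgError as exc:
            raise ConvergenceError("singular information matrix") from exc
        alpha += step[:J]
        beta += step[J]
        if abs(beta) > 30:
            raise ConvergenceError("hazard-ratio estimate diverged")
        if np.max(np.abs(step)) < _TOL:
            converged = True
            break
    mu0 = np.exp(alpha) * person_time[:, 0]
    mu1 = np.exp(alpha + beta) * person_time[:, 1]
    info = np.zeros((J + 1, J + 1))
    info[np.arange(J), np.arange(J)] = mu0 + mu1
    info[:J, J] = mu1
    info[J, :J] = mu1
    info[J, J] = mu1.sum()
    cov = np.linalg.inv(info)
    with np.errstate(divide="ignore"):
        loglik = float(
            np.sum(events[:, 0] * alpha - mu0)
            + np.sum(events[:, 1] * (alpha + beta) - mu1)
        )
    return PCHFit(
        cutpoints=a,
        alpha=alpha,
        beta=float(beta),
        cov=cov,
        loglik=loglik,
        converged=converged,
        events=events,
        person_time=person_time,
    )


def _ar_from_params(
    alpha: np.ndarray, beta: float, delta: np.ndarray, n0: int, n1: int
) -> np.ndarray:
    """A(t) from PCH parameters; delta has shape (T, J)."""
    h0 = delta @ np.exp(alpha)
    s0 = np.exp(-h0)
    s1 = np.exp(-np.exp(beta) * h0)
    s = (n0 * s0 + n1 * s1) / (n0 + n1)
    denom = 1.0 - s
    with np.errstate(divide="ignore", invalid="ignore"):
        ar = 1.0 - (1.0 - s0) / denom
    return np.where(denom > 0, ar, np.nan)


def ar_pch(
    sample: CohortSample,
    times,
    cutpoints=DEFAULT_CUTPOINTS,
    variance_method: str = "delta",
    boot_reps: int = 200,
    seed: int | None = None,
    ci_transform: str = "identity",
    level: float = 0.95,
) -> ARCurve:
    """Parametric attributable-risk curve with delta-method standard errors.

    The delta method propagates the (α, β) covariance through the gradient of
    A(t), computed by central finite differences with step
    1e-6·max(1, |parameter|).  ``variance_method="bootstrap"`` refits the
    model on subject-level resamples instead (used as a cross-check).
    Times beyond the last cutpoint are rejected (no extrapolation).
    """
    if variance_method not in ("delta", "bootstrap", "none"):
        raise ValueError("variance_method must be 'delta', 'bootstrap' or 'none'")
    a = _check_cutpoints(cutpoints)
    times = np.atleast_1d(np.asarray(times, dtype=float))
    if np.any(times > a[-1] + 1e-12):
        raise ValueError(f"requested time beyond the last cutpoint a_J={a[-1]}")
    fit = fit_pch(sample, a)
    n1 = int(sample.exposure.sum())
    n0 = sample.n - n1
    delta = exposure_time(times, a)
    est = _ar_from_params(fit.alpha, fit.beta, delta, n0, n1)
    if variance_method == "delta":
        params = np.concatenate([fit.alpha, [fit.beta]])
        grad = np.zeros((times.size, params.size))
        for p in range(params.size):
            h = 1e-6 * max(1.0, abs(params[p]))
            up, dn = params.copy(), params.copy()
            up[p] += h
            dn[p] -= h
            ar_up = _ar_from_params(up[:-1], up[-1], delta, n0, n1)
            ar_dn = _ar_from_params(dn[:-1], dn[-1], delta, n0, n1)
            grad[:, p] = (ar_up - ar_dn) / (2.0 * h)
        var = np.einsum("tp,pq,tq->t", grad, fit.cov, grad)
        se = np.sqrt(np.maximum(var, 0.0))
        se = np.where(np.isfinite(est), se, np.nan)
    elif variance_method == "bootstrap":
        rng = np.random.default_rng(seed)
        draws = np.full((boot_reps, times.size), np.nan)
        for b in range(boot_reps):
            boot = sample.resample(rng)
            try:
                bfit = fit_pch(boot, a)
            except (EmptyIntervalError, ConvergenceError):
                continue
            bn1 = int(boot.exposure.sum())
            draws[b] = _ar_from_params(
                bfit.alpha, bfit.beta, delta, boot.n - bn1, bn1
            )
        se = bootstrap_sd(draws)
    else:
        se = np.full(times.size, np.nan)
    lo, hi = wald_ci(est, se, level=level, transform=ci_transform)
    return ARCurve("PCH", times, est, se, lo, hi, transform=ci_transform)
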