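"""Nonparametric attributable-risk estimation (KM and weighted-KM methods).

Both methods plug Kaplan-Meier-type survival estimates into

    A(t) = 1 - (1 - S0(t)) / (1 - S(t)).

``S0`` is always the product-limit (Kaplan-Meier) curve of the baseline
stratum (exposure/stratum code 0).  The pooled survival ``S`` is either the
Kaplan-Meier curve of the whole sample (method "KM") or the weighted
Kaplan-Meier estimator (method "WKM"),

    S_WKM(t) = (1/n) * sum_k n_k * S_k(t),

the stratum-size-weighted average of per-stratum KM curves, which remains
consistent when censoring depends on the stratum.  Standard errors come from a
subject-level nonparametric bootstrap.
"""

from __future__ import annotations

import numpy as np

from ._stats import bootstrap_sd, wald_ci
from .cohort import ARCurve, CohortSample, EmptyStratumError, SurvivalCurve

__all__ = ["km_survival", "wkm_survival", "ar_nonparametric"]


def _km_arrays(time: np.ndarray, event: np.ndarray):
    """Product-limit estimate as (event_times, survival_values) arrays.

    Ties between events and censorings at the same time follow the standard
    convention: events happen first, so same-time censored subjects remain in
    the risk set for that event time.
    """
    order = np.argsort(time, kind="stable")
    t_sorted = time[order]
    d_sorted = event[order]
    event_mask = d_sorted == 1
    if not event_mask.any():
        return np.empty(0), np.empty(0)
    te, inverse = np.unique(t_sorted[event_mask], return_inverse=True)
    d = np.bincount(inverse, minlength=te.size).astype(float)
    n_at_risk = time.size - np.searchsorted(t_sorted, te, side="left")
    surv = np.cumprod(1.0 - d / n_at_risk)
    return te, surv


def km_survival(sample: CohortSample, restrict_stratum: int | None = None) -> SurvivalCurve:
    """Kaplan-Meier survival curve of the sample or of one stratum."""
    if restrict_stratum is not None:
        mask = sample.stratum == restrict_stratum
        if not mask.any():
            raise EmptyStratumError(
                f"stratum {restrict_stratum} contains no subjects"
            )
        sample = sample.subset(mask)
    times, values = _km_arrays(sample.time, sample.event)
    return SurvivalCurve(times, values)


def wkm_survival(sample: CohortSample) -> SurvivalCurve:
    """Weighted Kaplan-Meier curve: n_k-weighted mean of per-stratum KM curves.

    The jump set is the union of the stratum jump sets.  Every stratum must be
    nonempty (its weight n_k/n would otherwise be undefined); this holds by
    construction because stratum labels are contiguous.
    """
    n = sample.n
    grids = []
    per_stratum = []
    for k in range(sample.n_strata):
        mask = sample.stratum == k
        if not mask.any():  # defensive; contiguity normally guarantees this
            raise EmptyStratumError(f"stratum {k} contains no subjects")
        tk, sk = _km_arrays(sample.time[mask], sample.event[mask])
        grids.append(tk)
        per_stratum.append((int(mask.sum()), tk, sk))
    union = np.unique(np.concatenate(grids)) if grids else np.empty(0)
    values = np.zeros_like(union)
    for n_k, tk, sk in per_stratum:
        idx = np.searchsorted(tk, union, side="right") - 1
        s_on_union = np.where(idx >= 0, sk[np.clip(idx, 0, None)], 1.0)
        values += n_k * s_on_union
    values /= n
    return SurvivalCurve(union, values)


def _ar_point(sample: CohortSample, times: np.ndarray, weighting: str) -> np.ndarray:
    s0_curve = km_survival(sample, restrict_stratum=0)
    pooled = km_survival(sample) if weighting == "KM" else wkm_survival(sample)
    s0 = np.atleast_1d(s0_curve(times))
    s = np.atleast_1d(pooled(times))
    denom = 1.0 - s
    with np.errstate(divide="ignore", invalid="ignore"):
        ar = 1.0 - (1.0 - s0) / denom
    return np.where(denom > 0, ar, np.nan)


def ar_nonparametric(
    sample: CohortSample,
    times,
    weighting: str = "KM",
    variance_method: str = "bootstrap",
    boot_reps: int = 200,
    seed: int | None = None,
    ci_transform: str = "identity",
    level: float = 0.95,
) -> ARCurve:
    """Nonparametric attributable-risk curve at the requested times.

    Parameters
    ----------
    weighting
        "KM" pools the whole sample with one Kaplan-Meier curve; "WKM" uses
        the weighted Kaplan-Meier estimator for the pooled survival.
    variance_method
        "bootstrap" resamples subjects with replacement ``boot_reps`` times;
        "none" returns NaN standard errors.

    Times with no pooled event yet (1 - S(t) = 0) are undefined and returned
    as NaN; other times are still reported.  Negative estimates early in
    follow-up are returned as-is.
    """
    if weighting not in ("KM", "WKM"):
        raise ValueError("weighting must be 'KM' or 'WKM'")
    if variance_method not in ("bootstrap", "none"):
        raise ValueError("variance_method must be 'bootstrap' or 'none'")
    if not (sample.stratum == 0).any():
        raise EmptyStratumError("no subjects in the baseline (stratum 0) group")
    times = np.atleast_1d(np.asarray(times, dtype=float))
    est = _ar_point(sample, times, weighting)
    if variance_method == "bootstrap":
        rng = np.random.default_rng(seed)
        draws = np.full((boot_reps, times.size), np.nan)
        for b in range(boot_reps):
            boot = sample.resample(rng)
            if not (boot.stratum == 0).any():
                continue  # baseline stratum lost in the resample; skip draw
            try:
                draws[b] = _ar_point(boot, times, weighting)
            except EmptyStratumError:
                continue
        se = bootstrap_sd(draws)
    else:
        se = np.full(times.size, np.nan)
    lo, hi = wald_ci(est, se, level=level, transform=ci_transform)
    return ARCurve(weighting, times, est, se, lo, hi, transform=ci_transform)
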