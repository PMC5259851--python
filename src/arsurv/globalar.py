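"""Single-number (global) attributable-risk estimators.

For an unadjusted binary exposure the Spiegelman person-time formula reduces
to the familiar epidemiological expression

    AR = q (RR - 1) / {1 + q (RR - 1)},

with q the exposure prevalence and RR the relative risk (here the hazard
ratio exp(β) from a Cox fit).  The prevalence can be taken at baseline (the
proportion exposed at entry) or as exposed person-years over total
person-years.  The multi-category form AR = Σ_k q_k(RR_k - 1) / {1 + Σ_k
q_k(RR_k - 1)} is exposed as a pure function of (q_k, RR_k) vectors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._stats import wald_ci
from .cohort import CohortSample
from .cox import fit_cox

__all__ = [
    "GlobalAREstimate",
    "simpler_ar",
    "spiegelman_ar",
    "global_ar_from_cohort",
]

_PREVALENCE_SOURCES = ("baseline_proportion", "person_years")


@dataclass(frozen=True)
class GlobalAREstimate:
    """A single overall attributable-risk value with its uncertainty."""

    estimate: float
    se: float
    ci_low: float
    ci_high: float
    prevalence_source: str
    q: float
    rr: float


def simpler_ar(q: float, rr: float) -> float:
    """AR = q(RR-1)/{1 + q(RR-1)} for a binary exposure (point value).

    Raises ``ValueError`` when the denominator is not positive (possible for
    protective exposures, RR < 1, with large q).
    """
    if not 0.0 <= q <= 1.0:
        raise ValueError("exposure prevalence q must lie in [0, 1]")
    if rr <= 0:
        raise ValueError("relative risk must be positive")
    denom = 1.0 + q * (rr - 1.0)
    if denom <= 0:
        raise ValueError(
            f"attributable risk undefined: 1 + q(RR-1) = {denom:.4g} <= 0"
        )
    return q * (rr - 1.0) / denom


def spiegelman_ar(q, rr) -> float:
    """Multi-category global AR: Σ q_k(RR_k-1) / {1 + Σ q_k(RR_k-1)}.

    ``q`` and ``rr`` are aligned vectors over exposure categories (a baseline
    category with RR=1 contributes nothing and may be included or omitted).
    """
    q = np.asarray(q, dtype=float)
    rr = np.asarray(rr, dtype=float)
    if q.shape != rr.shape:
        raise ValueError("q and rr must have the same shape")
    if np.any(q < 0) or q.sum() > 1 + 1e-9:
        raise ValueError("prevalences must be nonnegative and sum to at most 1")
    if np.any(rr <= 0):
        raise ValueError("relative risks must be positive")
    excess = float(np.sum(q * (rr - 1.0)))
    denom = 1.0 + excess
    if denom <= 0:
        raise ValueError("attributable risk undefined: denominator <= 0")
    return excess / denom


def global_ar_from_cohort(
    sample: CohortSample,
    prevalence_source: str = "baseline_proportion",
    variance_method: str = "delta",
    boot_reps: int = 200,
    seed: int | None = None,
    level: float = 0.95,
) -> GlobalAREstimate:
    """Overall AR from a cohort: Cox hazard ratio × estimated prevalence.

    The delta-method variance treats q̂ and β̂ as asymptotically independent,
    combining a binomial prevalence term q(1-q)/n with the inverse
    partial-likelihood information for β; ``variance_method="bootstrap"``
    resamples subjects instead.  A cohort with no exposed subjects has AR 0
    by definition (no Cox fit is attempted).
    """
    if prevalence_source not in _PREVALENCE_SOURCES:
        raise ValueError(f"prevalence_source must be one of {_PREVALENCE_SOURCES}")
    if variance_method not in ("delta", "bootstrap", "none"):
        raise ValueError("variance_method must be 'delta', 'bootstrap' or 'none'")
    if not (sample.exposure == 1).any():
        return GlobalAREstimate(0.0, 0.0, 0.0, 0.0, prevalence_source, 0.0, np.nan)

    def point(s: CohortSample):
        fit = fit_cox(s)
        if prevalence_source == "baseline_proportion":
            q = float(np.mean(s.exposure))
        else:
            q = float(s.time[s.exposure == 1].sum() / s.time.sum())
        return q, fit
    q, fit = point(sample)
    rr = float(np.exp(fit.beta))
    est = simpler_ar(q, rr)
    if variance_method == "delta":
        denom = 1.0 + q * (rr - 1.0)
        dAdq = (rr - 1.0) / denom**2
        dAdb = q * rr / denom**2
        var_q = q * (1.0 - q) / sample.n
        var = dAdq**2 * var_q + dAdb**2 * fit.var_beta
        se = float(np.sqrt(var))
    elif variance_method == "bootstrap":
        rng = np.random.default_rng(seed)
        draws = []
        for _ in range(boot_reps):
            boot = sample.resample(rng)
            try:
                bq, bfit = point(boot)
                draws.append(simpler_ar(bq, float(np.exp(bfit.beta))))
            except (ValueError, RuntimeError):
                continue
        se = float(np.std(draws, ddof=1)) if len(draws) >= 10 else float("nan")
    else:
        se = float("nan")
    lo, hi = wald_ci(est, se, level=level)
    return GlobalAREstimate(est, se, float(lo), float(hi), prevalence_source, q, rr)
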