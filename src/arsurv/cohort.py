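"""Subject-level cohort data and survival-curve containers.

The attributable risk (AR) of an exposure at time ``t`` is defined from
cumulative distribution functions of the event time,

    A(t) = 1 - (1 - S0(t)) / (1 - S(t)),

where ``S`` is the marginal survival of the population as observed and ``S0``
the counterfactual survival with exposure removed.  Every estimator in this
package consumes a :class:`CohortSample` (one row per subject: follow-up time,
event indicator, binary exposure, optional categorical stratum) and produces an
:class:`ARCurve` (estimates, standard errors and Wald confidence limits at
requested times).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "CohortSample",
    "SurvivalCurve",
    "ARCurve",
    "ValidationError",
    "EmptyStratumError",
    "ConvergenceError",
    "EmptyIntervalError",
]


class ValidationError(ValueError):
    """Input data violates a structural requirement."""


class EmptyStratumError(ValidationError):
    """A stratum required by an estimator contains no subjects."""


class ConvergenceError(RuntimeError):
    """A likelihood maximization diverged or failed to converge."""


class EmptyIntervalError(RuntimeError):
    """A piecewise-constant-hazard interval contains no events.

    The piecewise exponential likelihood has no finite maximizer for the
    log-hazard of an eventless interval; the simulation harness discards and
    regenerates such datasets rather than fitting them.
    """


@dataclass(frozen=True)
class CohortSample:
    """Right-censored cohort data with a binary exposure.

    Parameters
    ----------
    time
        Nonnegative follow-up times in years.
    event
        1 if the event was observed at ``time``, 0 if censored.
    exposure
        Binary exposure code Z, 0 = unexposed (baseline), 1 = exposed.
    stratum
        Integer covariate-profile labels forming a contiguous ``0..K`` set;
        defaults to ``exposure``.
    """

    time: np.ndarray
    event: np.ndarray
    exposure: np.ndarray
    stratum: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        time = np.asarray(self.time, dtype=float)
        event = np.asarray(self.event)
        exposure = np.asarray(self.exposure)
        if time.ndim != 1 or time.size == 0:
            raise ValidationError("sample must contain at least one subject")
        if event.shape != time.shape or exposure.shape != time.shape:
            raise ValidationError("time, event and exposure must have equal length")
        if not np.all(np.isfinite(time)) or np.any(time < 0):
            raise ValidationError("follow-up times must be finite and nonnegative")
        if not np.isin(event, (0, 1)).all():
            raise ValidationError("event indicator must be coded 0/1")
        if not np.isin(exposure, (0, 1)).all():
            raise ValidationError("exposure must be coded 0/1")
        stratum = self.stratum
        if stratum is None:
            stratum = exposure.astype(np.int64)
        else:
            stratum = np.asarray(stratum)
            if stratum.shape != time.shape:
                raise ValidationError("stratum must have the same length as time")
            stratum = stratum.astype(np.int64)
            labels = np.unique(stratum)
            if labels[0] != 0 or not np.array_equal(labels, np.arange(labels.size)):
                raise ValidationError(
                    "stratum labels must form a contiguous 0..K set; got "
                    f"{labels.tolist()}"
                )
        object.__setattr__(self, "time", time)
        object.__setattr__(self, "event", event.astype(np.int8))
        object.__setattr__(self, "exposure", exposure.astype(np.int8))
        object.__setattr__(self, "stratum", stratum)

    @property
    def n(self) -> int:
        return self.time.size

    @property
    def n_strata(self) -> int:
        """Number of strata K+1."""
        return int(self.stratum.max()) + 1

    def stratum_sizes(self) -> np.ndarray:
        return np.bincount(self.stratum, minlength=self.n_strata)

    def subset(self, mask: np.ndarray) -> "CohortSample":
        if not mask.any():
            raise EmptyStratumError("subset selects no subjects")
        return CohortSample(
            self.time[mask], self.event[mask], self.exposure[mask], self.stratum[mask]
        )

    def resample(self, rng: np.random.Generator) -> "CohortSample":
        """Nonparametric bootstrap draw: n subjects with replacement."""
        idx = rng.integers(0, self.n, size=self.n)
        return CohortSample(
            self.time[idx], self.event[idx], self.exposure[idx], self.stratum[idx]
        )

    def truncate_follow_up(self, admin_time: float) -> "CohortSample":
        """Administratively censor all follow-up at ``admin_time``.

        Events after ``admin_time`` become censored observations at
        ``admin_time``; earlier records are unchanged.
        """
        if admin_time <= 0:
            raise ValidationError("administrative censoring time must be positive")
        time = np.minimum(self.time, admin_time)
        event = np.where(self.time <= admin_time, self.event, 0)
        return CohortSample(time, event, self.exposure, self.stratum)


@dataclass(frozen=True)
class SurvivalCurve:
    """Right-continuous step estimate of a survival function.

    ``times`` are the sorted jump (event) times and ``values`` the survival
    probabilities just after each jump; the curve equals 1 before the first
    jump.  Evaluation at an arbitrary ``t`` returns the value at the closest
    preceding jump.
    """

    times: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        values = np.asarray(self.values, dtype=float)
        if times.shape != values.shape or times.ndim != 1:
            raise ValidationError("times and values must be 1-d and equally long")
        if times.size and np.any(np.diff(times) <= 0):
            raise ValidationError("jump times must be strictly increasing")
        if np.any(values < -1e-12) or np.any(values > 1 + 1e-12):
            raise ValidationError("survival probabilities must lie in [0, 1]")
        if times.size and np.any(np.diff(values) > 1e-12):
            raise ValidationError("survival values must be nonincreasing")
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "values", np.clip(values, 0.0, 1.0))

    def __call__(self, t):
        t = np.asarray(t, dtype=float)
        idx = np.searchsorted(self.times, t, side="right") - 1
        out = np.where(idx >= 0, self.values[np.clip(idx, 0, None)], 1.0)
        return out if out.ndim else float(out)


@dataclass(frozen=True)
class ARCurve:
    """Attributable-risk estimates over time for one estimation method.

    Undefined values (no events observed by ``t``, so 1 - S(t) = 0) are stored
    as NaN; estimates may legitimately be negative early in follow-up.
    """

    method: str
    times: np.ndarray
    estimate: np.ndarray
    se: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    transform: str = "identity"

    def __post_init__(self) -> None:
        arrays = {}
        for name in ("times", "estimate", "se", "ci_low", "ci_high"):
            arr = np.atleast_1d(np.asarray(getattr(self, name), dtype=float))
            arrays[name] = arr
        length = arrays["times"].size
        if any(a.size != length for a in arrays.values()):
            raise ValidationError("all ARCurve vectors must have equal length")
        est, lo, hi = arrays["estimate"], arrays["ci_low"], arrays["ci_high"]
        ok = np.isfinite(est) & np.isfinite(lo) & np.isfinite(hi)
        if np.any(est[ok] > 1 + 1e-9):
            raise ValidationError("attributable risk cannot exceed 1")
        if np.any(lo[ok] > est[ok] + 1e-9) or np.any(est[ok] > hi[ok] + 1e-9):
            raise ValidationError("confidence limits must bracket the estimate")
        for name, arr in arrays.items():
            object.__setattr__(self, name, arr)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "method": self.method,
                "time": self.times,
                "estimate": self.estimate,
                "se": self.se,
                "ci_low": self.ci_low,
                "ci_high": self.ci_high,
            }
        )
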