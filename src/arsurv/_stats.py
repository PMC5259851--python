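"""Shared small-statistics helpers (Wald intervals, bootstrap SD)."""

from __future__ import annotations

import numpy as np
from scipy import stats

_VALID_TRANSFORMS = ("identity", "cloglog")


def wald_ci(estimate, se, level: float = 0.95, transform: str = "identity"):
    """Wald confidence interval for an attributable risk A(t).

    ``identity`` builds ``estimate ± z·se`` directly.  ``cloglog`` builds the
    interval on the complementary-log scale ln{1 - A(t)} and back-transforms,
    which keeps the upper limit below 1 and can improve small-sample coverage.
    A missing (NaN) standard error yields a missing interval.
    """
    if transform not in _VALID_TRANSFORMS:
        raise ValueError(f"transform must be one of {_VALID_TRANSFORMS}")
    if not 0 < level < 1:
        raise ValueError("confidence level must be in (0, 1)")
    estimate = np.asarray(estimate, dtype=float)
    se = np.asarray(se, dtype=float)
    if np.any(se[np.isfinite(se)] < 0):
        raise ValueError("standard errors must be nonnegative")
    z = stats.norm.ppf(0.5 + level / 2.0)
    if transform == "identity":
        lo = estimate - z * se
        hi = estimate + z * se
    else:
        # g = ln(1 - A) is decreasing in A, so the limits swap on back-transform.
        with np.errstate(divide="ignore", invalid="ignore"):
            g = np.log1p(-estimate)
            se_g = se / (1.0 - estimate)
            lo = -np.expm1(g + z * se_g)
            hi = -np.expm1(g - z * se_g)
    if lo.ndim == 0:
        return float(lo), float(hi)
    return lo, hi


def bootstrap_sd(values: np.ndarray, min_reps: int = 10) -> np.ndarray:
    """Column-wise SD over bootstrap replicates, NaN-aware.

    ``values`` has shape (reps, times).  Columns with fewer than ``min_reps``
    finite replicates (e.g. no events by an early time in most resamples)
    return NaN rather than an unstable estimate.
    """
    values = np.asarray(values, dtype=float)
    n_ok = np.sum(np.isfinite(values), axis=0)
    with np.errstate(invalid="ignore"):
        sd = np.nanstd(values, axis=0, ddof=1)
    return np.where(n_ok >= min_reps, sd, np.nan)
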