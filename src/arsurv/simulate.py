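"""Cohort data generation and closed-form truth for the simulation study.

Two data-generating mechanisms for a single binary exposure Z ~ Bernoulli(q):

* **PH** — proportional hazards with Weibull baseline hazard
  λ0(t) = γ θ^{-γ} t^{γ-1}, so S(t|Z) = exp{-(t/θ)^γ e^{βZ}}.  Event times
  come from the inverse CDF t = θ[-ln U / e^{βZ}]^{1/γ}.  The scale θ is
  calibrated so the unexposed median survival equals 15 years:
  θ = 15 / (ln 2)^{1/γ}.
* **NPH** — a transformation model with cumulative hazard
  Λ(t|Z) = G(λ0 t e^{βZ}), G(t) = ln(1 + 2t)/2, whose hazard ratio between
  exposed and unexposed decreases from e^β toward 1 over time.  Event times
  come from t = G^{-1}(-ln U) / (λ0 e^{βZ}) with G^{-1}(y) = (e^{2y} - 1)/2.
  λ0 = 0.1/year again gives a 15-year unexposed median.

Censoring times are Uniform[0, τ] independent of Z and of the event time,
with τ = 20 years maximal follow-up by default.  Closed-form survival
functions give the true attributable risk A(t) against which estimators are
judged.

Reproducibility: per-subject draws always occur in the fixed order exposure →
event-time uniform → censoring, so a seed pins the dataset byte-for-byte.
Replicate r of a scenario uses an independent ``SeedSequence(seed,
spawn_key=(r, attempt))`` stream, so any replicate (and any regeneration
attempt after a discard) is reproducible in isolation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .cohort import CohortSample

__all__ = [
    "ScenarioConfig",
    "calibrate_theta",
    "generate_ph",
    "generate_nph",
    "generate",
    "replicate_rng",
    "theoretical_survival",
    "theoretical_ar",
    "theoretical_global_ar",
    "event_time_cdf",
]

LN2 = math.log(2.0)


def calibrate_theta(gamma: float, median: float = 15.0) -> float:
    """Weibull scale θ giving S0(median) = 0.5: θ = median/(ln 2)^{1/γ}."""
    if gamma <= 0:
        raise ValueError("Weibull shape gamma must be positive")
    if median <= 0:
        raise ValueError("target median must be positive")
    return median / LN2 ** (1.0 / gamma)


@dataclass(frozen=True)
class ScenarioConfig:
    """All parameters of one simulation scenario.

    ``theta`` defaults to the median-calibrated value 15/(ln 2)^{1/γ}; pass
    it explicitly to decouple the scale from the 15-year median.
    """

    model: str = "PH"  # "PH" or "NPH"
    gamma: float = 1.0  # Weibull shape (PH only)
    beta: float = LN2  # log hazard ratio
    q: float = 0.5  # exposure probability
    lambda0: float = 0.1  # NPH rate per year
    tau: float = 20.0  # maximal follow-up (years)
    n: int = 1000
    reps: int = 1000
    seed: int = 0
    admin_censor_time: float | None = None
    theta: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.model not in ("PH", "NPH"):
            raise ValueError("model must be 'PH' or 'NPH'")
        if not 0.0 < self.q < 1.0:
            raise ValueError("exposure probability q must lie in (0, 1)")
        if self.tau <= 0 or self.n < 1 or self.reps < 1:
            raise ValueError("tau must be positive and n, reps at least 1")
        if self.gamma <= 0 or self.lambda0 <= 0:
            raise ValueError("gamma and lambda0 must be positive")
        if self.admin_censor_time is not None and not (
            0 < self.admin_censor_time <= self.tau
        ):
            raise ValueError("admin_censor_time must lie in (0, tau]")
        if self.theta is None:
            object.__setattr__(self, "theta", calibrate_theta(self.gamma))
        elif self.theta <= 0:
            raise ValueError("theta must be positive")

    def with_(self, **kwargs) -> "ScenarioConfig":
        return replace(self, **kwargs)


def replicate_rng(seed: int, rep: int = 0, attempt: int = 0) -> np.random.Generator:
    """Independent RNG stream for replicate ``rep`` (regeneration ``attempt``)."""
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(rep, attempt)))


def _latent_event_times_ph(config: ScenarioConfig, z: np.ndarray, u: np.ndarray):
    return config.theta * (-np.log(u) / np.exp(config.beta * z)) ** (1.0 / config.gamma)


def _latent_event_times_nph(config: ScenarioConfig, z: np.ndarray, u: np.ndarray):
    ginv = 0.5 * np.expm1(-2.0 * np.log(u))  # G^{-1}(-ln U) = (e^{-2 ln U} - 1)/2
    return ginv / (config.lambda0 * np.exp(config.beta * z))


def _assemble(config: ScenarioConfig, z, t_event, c) -> CohortSample:
    time = np.minimum(t_event, c)
    event = (t_event <= c).astype(np.int8)
    sample = CohortSample(time, event, z.astype(np.int8))
    if config.admin_censor_time is not None:
        sample = sample.truncate_follow_up(config.admin_censor_time)
    return sample


def generate_ph(config: ScenarioConfig, rng: np.random.Generator) -> CohortSample:
    """One cohort under the Weibull proportional-hazards mechanism."""
    if config.model != "PH":
        raise ValueError("config.model must be 'PH'")
    z = (rng.random(config.n) < config.q).astype(np.int8)
    u = rng.random(config.n)
    t_event = _latent_event_times_ph(config, z, u)
    c = rng.random(config.n) * config.tau
    return _assemble(config, z, t_event, c)


def generate_nph(config: ScenarioConfig, rng: np.random.Generator) -> CohortSample:
    """One cohort under the nonproportional-hazards transformation model."""
    if config.model != "NPH":
        raise ValueError("config.model must be 'NPH'")
    z = (rng.random(config.n) < config.q).astype(np.int8)
    u = rng.random(config.n)
    t_event = _latent_event_times_nph(config, z, u)
    c = rng.random(config.n) * config.tau
    return _assemble(config, z, t_event, c)


def generate(config: ScenarioConfig, rng: np.random.Generator) -> CohortSample:
    return generate_ph(config, rng) if config.model == "PH" else generate_nph(config, rng)


def theoretical_survival(config: ScenarioConfig, t):
    """Closed-form (S0(t), S(t)) under the scenario's mechanism.

    S0 is the unexposed survival; S the q-mixture of unexposed and exposed
    survivals (the marginal survival of the generated population).
    """
    t = np.asarray(t, dtype=float)
    if config.model == "PH":
        x = (t / config.theta) ** config.gamma
        s0 = np.exp(-x)
        s1 = np.exp(-x * np.exp(config.beta))
    else:
        s0 = np.exp(-0.5 * np.log1p(2.0 * config.lambda0 * t))
        s1 = np.exp(-0.5 * np.log1p(2.0 * config.lambda0 * t * np.exp(config.beta)))
    s = (1.0 - config.q) * s0 + config.q * s1
    return s0, s


def theoretical_ar(config: ScenarioConfig, t):
    """True attributable risk A(t) = 1 - (1-S0(t))/(1-S(t)); undefined at t=0."""
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr <= 0):
        raise ValueError("A(t) is undefined at t <= 0 (0/0 limit)")
    s0, s = theoretical_survival(config, t_arr)
    out = 1.0 - (1.0 - s0) / (1.0 - s)
    return out if out.ndim else float(out)


def theoretical_global_ar(config: ScenarioConfig) -> float:
    """True overall AR of the simpler formula: q(e^β - 1)/{1 + q(e^β - 1)}."""
    excess = config.q * math.expm1(config.beta)
    return excess / (1.0 + excess)


def event_time_cdf(config: ScenarioConfig, t):
    """Marginal CDF of the latent (uncensored) event time; for KS checks."""
    _, s = theoretical_survival(config, t)
    return 1.0 - s
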