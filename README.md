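# arsurv

Attributable risk as a function of time from censored cohort data.

## The problem

Epidemiologists quantify the public-health impact of an exposure with the
attributable risk (AR, also called the population attributable fraction): the
proportion of disease cases in a population that can be ascribed to the
exposure. In cohort studies with censored time-to-event outcomes the AR is
naturally a function of follow-up time. Interpreting disease incidence as a
cumulative distribution function gives

    A(t) = 1 − (1 − S0(t)) / (1 − S(t)),

where `S(t) = P(T > t)` is the survival of the population as observed and
`S0(t)` the counterfactual survival of the same population with the exposure
removed. `arsurv` implements, for a binary exposure, the main estimators of
A(t) proposed in the biostatistical literature and the simulation machinery
needed to study their behaviour:

- **KM** — nonparametric: `S0` and `S` both by Kaplan-Meier;
- **WKM** — nonparametric: `S` by the weighted Kaplan-Meier estimator
  `Ŝ(t) = (1/n) Σ_k n_k Ŝ_k(t)` (stratum-size-weighted KM average);
- **COX** — semiparametric: Cox partial likelihood with Breslow baseline,
  `Ŝ0 = exp(−Λ̂0)`, `Ŝ = (1/n) Σ_i exp{−e^{β̂ z_i} Λ̂0(t)}`;
- **PCH** — parametric: piecewise constant baseline hazards over prespecified
  intervals, maximum likelihood, delta-method standard errors;
- **Simpler / Spiegelman** — a single overall value
  `AR = q(RR − 1)/{1 + q(RR − 1)}` from the Cox hazard ratio and the exposure
  prevalence (at baseline, or from person-years).

A simulator generates cohorts from a Weibull proportional-hazards model
(shape γ, scale calibrated so the unexposed median survival is 15 years) or
from a nonproportional-hazards transformation model with cumulative hazard
`Λ(t|Z) = ln(1 + 2 λ0 t e^{βZ})/2`, both with Uniform[0, τ] censoring, and an
evaluation harness aggregates bias, mean estimated standard error (SEE),
empirical standard deviation (SSD) and 95% Wald CI coverage over replicates
against the closed-form A(t).

## Worked example

```python
import numpy as np
import arsurv as av

# a proportional-hazards cohort: hazard ratio 2, half the subjects exposed
config = av.ScenarioConfig(model="PH", gamma=1.0, beta=np.log(2), q=0.5,
                           n=2000, seed=42)
sample = av.generate_ph(config, av.replicate_rng(42, 0))

curve = av.ar_cox(sample, times=[5, 10, 15, 20], boot_reps=200, seed=1)
for t, a, se in zip(curve.times, curve.estimate, curve.se):
    print(f"t={t:4.0f}  AR={a:.3f}  se={se:.3f}   truth={av.theoretical_ar(config, t):.3f}")
```

prints

```
t=   5  AR=0.325  se=0.026   truth=0.284
t=  10  AR=0.272  se=0.023   truth=0.240
t=  15  AR=0.226  se=0.021   truth=0.200
t=  20  AR=0.187  se=0.019   truth=0.166
```

i.e. at 5 years an estimated 32.5% (±2.6%) of events are attributable to the
exposure in this cohort, against a true 28.4%; the AR declines with follow-up
because the exposed fail earlier and the surviving population becomes
progressively less exposed. The same interface serves `ar_nonparametric`
(KM/WKM), `ar_pch` and `global_ar_from_cohort`.

There is also a small CLI:

```sh
arsurv estimate --input cohort.csv --method pch --cutpoints 5,10,15,20 \
       --times 5,10,15,20 --out ar.csv
arsurv evaluate --scenario scenario.yaml --methods km,cox,pch --out table.csv
```

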