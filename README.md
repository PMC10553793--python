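# msitr — individualized treatment rules for multistate trial outcomes

`msitr` estimates **optimal individualized treatment rules (ITRs)** from
randomized clinical trials in which each patient's outcome is a
**right-censored multistate process** — e.g. an oncology trial whose states
are *initial disease* (1), *tumor response* (2) and *progression or death*
(3).  It is aimed at biostatisticians analyzing trials where the clinically
relevant outcome is the time spent in desirable health states (duration of
response, progression-free time, quality-adjusted lifetime) rather than a
single survival time, and where patient preferences over those states
matter.

## The method

For a preference weight `w ∈ [0,1]^S` the utility of a patient is the
weighted restricted state-occupation time
`∫₀^τ w'X̃(t) dt`, where `X̃(t)` indicates the occupied state.  The value of
a rule `d : Z → {−1,+1}` is `V_w(d)`, the expected utility were everyone
treated according to `d`.  Under randomization and independent censoring the
value is identified by inverse-probability-of-censoring weighting (IPCW):

    V̂_w(d) = (1/n) Σᵢ Uᵢ · I(Aᵢ = d(Zᵢ)) / (Aᵢ π̂ + (1−Aᵢ)/2),
    Uᵢ     = ∫₀^τ Y_{i,w}(t) · 1{t contributes} · exp{Λ̂((T̃ᵢ∧t)−)} dt,

with `Λ̂` the Nelson–Aalen estimator of the censoring cumulative hazard and
`π̂` the empirical randomization fraction.  The optimal rule is estimated by
outcome-weighted learning: minimize the convex hinge-loss surrogate risk

    R̂_φ(f) = (1/n) Σᵢ Uᵢ · max(0, 1 − Aᵢ f(Zᵢ)) / (Aᵢ π̂ + (1−Aᵢ)/2) + λ‖f‖²

over linear decision functions or a Gaussian-kernel RKHS — a weighted
support-vector problem — and set `d̂(z) = sgn(f̂(z))`.  The package provides
the plug-in and leave-one-out (jackknife) value estimators,
influence-function standard errors, and simultaneous confidence intervals
over several preference weights and contrasts against the one-size-fits-all
rules `d ≡ +1` and `d ≡ −1`, via Gaussian multiplier simulation.  A
progressive illness–death simulator with closed-form true values supports
validation end to end.  See `docs/methods.md` for the full model, numerical
choices and limitations.

## Worked example

```python
import numpy as np
from msitr import (SimScenario, simulate_trial, PreferenceWeight,
                   estimate_propensity, nelson_aalen_censoring, fit_linear,
                   estimate_value, jackknife_value, influence_functions,
                   value_report)

# a 300-subject trial with ~45% censoring; true optimal boundary z1+z2 = 0
data = simulate_trial(SimScenario(scenario_id=1, theta=-1.0, n=300, seed=7))
w = PreferenceWeight((0, 1, 0))            # value time in tumor response
pi_hat = estimate_propensity(data)
hazard = nelson_aalen_censoring(data)
fit = fit_linear(data, w, lam=300**-0.5, h=hazard, pi_hat=pi_hat)
print(f"f(z) = {fit.f.intercept:+.3f} {fit.f.slope[0]:+.3f} z1 "
      f"{fit.f.slope[1]:+.3f} z2")

v = estimate_value(data, fit.f, w, hazard, pi_hat)
se = influence_functions(data, fit.f, w, hazard, pi_hat).se
print(f"plug-in value {v:.3f} (SE {se:.3f}); "
      f"jackknife {jackknife_value(data, w, 300**-0.5):.3f}")

report = value_report(data, {w: fit.f}, B=1000, seed=1)
print(report.to_string(index=False, float_format=lambda x: f"{x:.3f}"))
```

Output:

```
f(z) = +0.222 +0.768 z1 +1.099 z2
plug-in value 1.359 (SE 0.143); jackknife 1.281
        w        parameter  estimate    se  ci_low  ci_high  sim_ci_low  sim_ci_high
(0, 1, 0)         V(d_hat)     1.359 0.143   1.079    1.640       1.034        1.685
(0, 1, 0) V(d_hat) - V(+1)     0.287 0.120   0.052    0.522       0.014        0.559
(0, 1, 0) V(d_hat) - V(-1)     0.446 0.135   0.181    0.711       0.138        0.753
```

The fitted linear rule points along the true boundary direction (slopes on
`z1` and `z2` both positive).  The plug-in value 1.359 is the estimated mean
months in response if everyone were treated by the fitted rule; the
jackknife value 1.281 removes the in-sample optimism.  The contrast rows
show the rule beats both fixed rules: e.g. +0.287 months of response versus
treating everyone with `+1`, with 95% pointwise CI (0.052, 0.522) and a
wider simultaneous CI (0.014, 0.559) that adjusts for reporting all three
parameters jointly.

A command-line interface mirrors the library:

```sh
msitr simulate --scenario 1 --theta -1.0 --n 300 --seed 7 --out trial.csv
msitr fit trial.csv --w 0,1,0 --lam 0.0577 --out rule.json
msitr value trial.csv --rule rule.json --seed 1
msitr study config.yaml --seed 1 --out metrics.csv
```

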