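# idprog

**Illness-death modelling of interval-censored chronic kidney disease
progression**, with the standard survival analyses it is meant to replace.

## The problem

Studies of progression to an advanced CKD stage (e.g. stage 5, measured
GFR < 15 mL/min/1.73 m²) observe renal function only at intermittent
visits: the onset time is *interval censored* between the last healthy
measure and the first evidence of the stage (a sub-threshold measure,
dialysis, or preemptive transplantation). Death competes with observation
— a patient who dies after a long visit gap may have progressed unobserved.
Common practice fits single-event Weibull/Cox models that censor the
progression clock at death (assuming no unobserved passage) or censor at
the last visit (conditioning on the future). This package implements the
alternative: a three-state **Weibull illness-death model for
interval-censored data** (healthy → stage → death, plus direct death)
whose likelihood integrates over the unknown onset time,

    pattern "died undiagnosed":
      S₀(T)h₀₂(T) + ∫_L^T S₀(u) h₀₁(u) exp(−(Λ₁₂(T)−Λ₁₂(u))) h₁₂(T) du,

with Weibull proportional-hazards intensities
`h(t|z) = (a/b)(t/b)^(a−1) exp(β·z)` on each transition — together with
the standard comparators:

* **M1** time to stage diagnosis, censored at death / latest news;
* **M2** death before diagnosis, censored at diagnosis;
* **M3** death after diagnosis, censored at transplantation;
* **M4** the illness-death model (transitions 01, 02, 12 in one fit).

It also computes model-based probabilities of progression within a horizon
for covariate profiles — the death-aware cumulative incidence
`F₀₁(t|z) = ∫₀ᵗ S₀(u|z)h₀₁(u|z)du` from M4 versus the naive
`1 − exp(−Λ(t|z))` from M1 — and ships a synthetic-cohort generator that
emulates the observation process of a nephrology referral cohort
(~1500 subjects, roughly annual visits with dropout, dialysis/transplant
diagnosis routes, registry-ascertained death, staggered administrative
censoring), since the motivating hospital cohort is not public.

Audience: biostatisticians and epidemiologists analyzing panel-observed
disease progression with competing mortality, and methodologists studying
the biases of naive censoring schemes.

## Worked example

```python
import numpy as np
from idprog import (default_config, simulate_cohort, derive_id_observation,
                    run_comparison, COVARIATES)

records, truth = simulate_cohort(default_config(seed=1))
obs = [derive_id_observation(r) for r in records]
report = run_comparison(
    obs, covariate_names=list(COVARIATES),
    profiles={"man50_mgfr30_pcr90": [0.0, 50.0, np.log(90.0), 30.0]})

print(report.event_counts)
print(report.aligned_hr_frame()[
    ["transition", "covariate", "hr_standard", "hr_imid"]].round(2))
print(report.curves["man50_mgfr30_pcr90"].iloc[-1][["imid", "naive"]])
```

Output (seed 1):

```
{'n': 1519, 'diagnosed': 288, 'death_without_diagnosis': 107,
 'death_after_diagnosis': 65, 'deaths_total': 172, 'alive_never_diagnosed': 1124}
   transition covariate  hr_standard  hr_imid
0          01       sex         0.75     0.79
1          01      age0         1.02     1.01
2          01  log_pcr0         1.80     1.86
3          01     mgfr0         0.39     0.36
4          02       sex         0.74     0.82
5          02      age0         2.02     2.18
6          02  log_pcr0         1.14     0.99
7          02     mgfr0         0.72     0.88
8          12       sex         0.96     0.92
9          12      age0         1.82     1.80
10         12  log_pcr0         1.03     1.05
11         12     mgfr0         0.92     0.91
imid     0.943419
naive    0.659968
```

Reading it: hazard ratios are per 10-year age increase, per
10 mL/min/1.73 m² of baseline mGFR, per unit log protein/creatinine ratio,
female vs male. On the progression transition (01) the naive M1 and the
illness-death M4 agree closely (log-PCR HR 1.80 vs 1.86). On death before
diagnosis (02) they separate: M2 attributes to baseline mGFR and
proteinuria part of the effect that actually operates through undetected
progression, so its HRs sit further from 1 than M4-02's. The five-year
progression probability for a 50-year-old man with mGFR 30 and PCR
90 mg/mmol is 0.94 under the illness-death model but only 0.66 under the
naive model — censoring at death plus interval censoring systematically
under-estimates progression.

A command-line interface mirrors the library
(`idprog simulate|derive|fit-standard|fit-imid|predict|compare`); YAML
scenario files configure the generator.

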