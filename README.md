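# hale — healthy and unhealthy life expectancy from panel surveys

`hale` estimates how many of the years remaining at older ages are lived
in good functional health, from longitudinal surveys that observe each
person only at widely spaced waves.  It is built for data shaped like the
EPS (Chile), CRELES (Costa Rica) and SHARE (Spain) ageing panels: adults
60+, two waves 2–3 years apart, self-reported limitations in four basic
activities of daily living defining the unhealthy state, exactly dated
deaths between waves, and time-fixed covariates such as sex, education
and social participation.

It is intended for demographers and epidemiologists who want
incidence-based health expectancies (a multistate model fitted to
transitions) rather than prevalence-based Sullivan-method estimates.

## The model

A continuous-time illness-death process with recovery: healthy (1) ⇄
unhealthy (2), both feeding the absorbing dead state (3).  Transition
intensities are Gompertz with proportional covariate effects,

    q_rs(x, z) = exp( β0_rs + ξ_rs (x − 60) + γ_rs·z ),   (r,s) ∈ {12, 13, 21, 23},

fitted by maximum likelihood on the interval-censored panel: living
states contribute interval transition probabilities P_rs(t1, t2)
(piecewise-constant generator, matrix exponentials), deaths contribute
the exact-death density Σ_u P_ru(t1, t2) q_u3(t2).  Life expectancies are
occupancy-time integrals e_rs(x) = ∫ₓ^ω P_rs(x, u) du, weighted by a
baseline-state logistic model π(x, z) into marginal quantities

    HLE = π₁e₁₁ + π₂e₂₁,  ULE = π₁e₁₂ + π₂e₂₂,  TLE = HLE + ULE,

with percentile confidence intervals from repeated draws of the
parameter vector at the MLE.  A synthetic-cohort generator with the same
structure (plus a Monte-Carlo occupancy oracle) supports validation
end-to-end.  See `docs/methods.md` for assumptions, defaults and
limitations.

## Worked example

`examples/03_life_expectancy.py` simulates a Costa-Rica-like two-wave
cohort (n = 2000, 58 % social participation, oversampled 80+), fits the
model and prints:

```
marginal life expectancy at 60 (years, 95% percentile CI from 500 parameter draws):

  with participation
    TLE:  17.49  (15.95-18.72)
    HLE:  12.32  (11.16-13.44)
    ULE:   5.16  (4.37-5.86)
    healthy share: 70.5%

  without participation
    TLE:  15.48  (13.81-17.01)
    HLE:   9.47  (8.25-10.65)
    ULE:   6.01  (4.80-6.98)
    healthy share: 61.2%
```

Read: a 60-year-old participant in this synthetic population can expect
17.5 more years, 12.3 of them free of ADL limitation (70.5 %); the
participation advantage (+2.0 years of TLE here) is concentrated in
healthy years, the qualitative pattern such surveys report.  The other
examples cover panel simulation (`01`), hazard ratios per transition
(`02`) and the reporting arithmetic on published estimates (`04`) — e.g.
men's healthy shares of 88.7 % (Chile), 80.0 % (Costa Rica) and 90.0 %
(Spain), and the 4.9-year Spanish gender gap in TLE, all reproduced from
the published TLE/HLE points bundled in `hale.reference`.

A thin CLI mirrors the pipeline:
`hale simulate cfg.yaml -o panel.csv`, `hale fit panel.csv -o fit.json`,
`hale le fit.json --panel panel.csv -o est.csv`, `hale report est.csv -o
table.txt` (exit codes: 2 validation error, 3 non-convergence).

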