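# Methods

## The model

`hale` estimates how much of remaining life at older ages is spent in good
functional health, from panel surveys that observe people only at widely
spaced waves.  The underlying process is a continuous-time illness-death
model with recovery: two recurrent living states — *healthy* (1, no
limitation in the four basic ADLs: bathing, walking across a room, bed
transfer, eating) and *unhealthy* (2, at least one limitation) — and an
absorbing *dead* state (3).  Allowed instantaneous transitions are
1→2, 2→1, 1→3 and 2→3.

Each transition intensity follows a Gompertz (log-linear in age) law with
proportional covariate effects,

    q_rs(x, z) = exp( β0_rs + ξ_rs (x − a0) + γ_rs·z ),

with age centred at the reference a0 = 60 y so that intercepts and slopes
are nearly uncorrelated in the fit.  Age slopes ξ are unconstrained in
sign (recovery typically declines with age while onset and mortality
rise).  By default every covariate enters every transition; per-transition
masks are available.

Interval transition probabilities are computed by the usual
piecewise-constant approximation: the interval [x, y] is cut into
subintervals of length ≤ h (default h = 1 y), the generator is frozen at
the start of each subinterval, and the subinterval matrix exponentials are
multiplied in age order.  Because the living-state 2×2 block of an
illness-death generator always has real, non-positive eigenvalues
(discriminant (a−d)² + 4bc ≥ 0 with b, c ≥ 0), its exponential has a
closed spectral form; `hale` evaluates it vectorised over thousands of
blocks at once, which is what makes the replicated simulation experiments
affordable.  The implementation is verified in the tests against
`scipy.linalg.expm` and a truncated-series oracle.

## Likelihood

Living states are interval-censored (the state is known only at wave
ages); death ages are exact, as the surveys obtained death dates from
registries or household report.  Consecutive observation pairs
(t1, r) → (t2, s) contribute

* `log P_rs(t1, t2)` when s is a living state;
* `log Σ_u P_ru(t1, t2) q_u3(t2)`, u over living states, when s is death
  at exact age t2 (the standard exact-death density contribution).

Subjects observed once contribute nothing.  Attrition between waves is
treated as ignorable right-censoring: subjects simply contribute the
pairs they were observed for.  The likelihood is maximised by BFGS from
crude occupancy-rate starting values (events / person-years, unobserved
transitions floored at 0.5 events); the covariance of the estimates is
the inverse of a central-difference numerical Hessian (step 1e-4 on the
log-scale parameters, which are of comparable magnitude).  Convergence is
declared on the optimiser's gradient tolerance (default 1e-6); a
singular or indefinite Hessian yields a fit without covariance and a
warning rather than a failure.  A seed-controlled multi-start option
exists for flat likelihoods but is off by default.

Parameters at a data-driven boundary (e.g. a covariate stratum with no
observed deaths drives that γ → −∞) are the main practical failure mode;
they show up as huge negative coefficients and a singular Hessian, and
the tooling then degrades to point estimates.

## Life expectancies

State-specific expectancies are occupancy-time integrals
e_rs(x) = ∫ₓ^ω P_rs(x, u) du, evaluated by the composite trapezoid rule
with step 0.25 y up to ω = 115 y (survival beyond 115 is numerically
negligible for realistic fits; truncation error ≪ 0.01 y).  Inside this
integral the generator is frozen at subinterval *midpoints*: the
left-endpoint rule used for the likelihood grid is only first-order, and
midpoint freezing is what keeps the step-halving error below the 0.01 y
reporting precision.  In the time-homogeneous limit the integrals equal
the fundamental matrix −(Q_LL)⁻¹, which the tests verify to 0.01 y.

Marginal expectancies weight the two starting states by the baseline
state distribution π(x, z), a logistic regression of baseline state on
centred age and covariates (fitted as a multinomial logit, which with two
living categories is the same thing).  π is evaluated at the age x of the
life-expectancy calculation, so the weights age along with the cohort.
Then

    HLE(x) = π₁ e₁₁ + π₂ e₂₁,  ULE(x) = π₁ e₁₂ + π₂ e₂₂,
    TLE = HLE + ULE  (an identity, asserted to 1e-8).

Confidence intervals: parameter vectors are drawn from the multivariate
normal at the MLE — the intensity block and the baseline-state block
independently, since they come from separate fits — the marginal LEs are
recomputed per draw, and the 2.5th/97.5th percentiles reported
(percentile intervals, not normal-theory; 500 draws by default).  The
point estimate is always the MLE's own value.  Draws are capped at
log-rate 30/y to keep absurd tail draws from overflowing; such draws
correspond to immediate death and contribute ~0 years.

## Synthetic cohorts

The generator emulates the structure of the EPS/CRELES/SHARE two-wave
panels: baseline ages 60+ drawn from survey-like 5-year band weights
(presets `eps`, `creles` — with its oversampling of 80+ — and `share`),
independent Bernoulli covariates at survey-like prevalences (social
participation 32/58/23 %, secondary+ education 32/16/20 %, women
50/54/56 %), a baseline state from the logistic truth, two waves 2.5 y
apart, 6 % attrition per follow-up wave (completely at random by default,
optionally health-dependent via a free log-odds knob), and exact death
ages between waves.

The default Gompertz truth uses per-year rates at 60 of 0.08 (onset),
0.008 (mortality from health), 0.25 (recovery) and 0.045 (mortality from
ill health) with slopes 0.07, 0.09, −0.03 and 0.08; participation carries
log-hazard-ratios (−0.3, −0.4, +0.2, −0.3).  These give a total life
expectancy at 60 in the high teens and a healthy share around 70 % —
plausible magnitudes for 60+ functional-limitation panels.  The baseline
logit is −1.9 + 0.045·(age−60) − 0.4·participation (~13 % unhealthy at
60).

Trajectories are simulated exactly for the piecewise-constant hazard
approximation on a fine grid (h_sim = 0.1 y, rates frozen at cell
midpoints): an Exp(1) clock is inverted against the cumulative total
hazard and the destination drawn proportional to the intensities at the
event's cell.  The Monte-Carlo life-expectancy oracle averages occupancy
times over such paths; because the numeric integration can be run on the
same 0.1 y grid, the two routes approximate the same process and their
agreement (within 3 Monte-Carlo standard errors at 10⁵ paths) is a
genuine cross-check of the integration and of the exponential machinery.

What the generator does *not* emulate: survey weights, proxy
respondents, misclassified health states, informative attrition (beyond
the optional knob), cohort effects, or time-varying covariates.  Passing
recovery tests therefore show that the estimator is correct for the
model's own data-generating process — not that the model is correct for
any particular survey.

## Experimental design and sizes

The validation experiments use cohorts of n = 2000 subjects (the order of
the real survey samples), two waves 2.5 y apart, one covariate
(participation), and fit with h = 0.5 y: the left-endpoint likelihood
grid biases log-rates by roughly ξh/2, so half-year steps keep that below
the experiments' Monte-Carlo resolution.  Parameter recovery runs 100
replicates; 95 % Wald intervals for every baseline log-rate and
log-hazard-ratio cover the truth at close-to-nominal rates, and the mean
absolute bias of the baseline log-rates is below 0.05.  A small negative
finite-sample bias concentrated in the unhealthy-state mortality baseline
(≈ −0.08 at n = 2000) halves by n = 8000, consistent with the usual
O(1/n) skew of panel MLEs rather than an estimator defect.

Interval-coverage runs use 40 replicate fits with 100 parameter draws
each; the percentile intervals for TLE cover the generating truth at
close to the nominal 95 %.

## Numerical choices and edge cases

* Probabilities are clipped at [0, 1] after the block product and the
  dead-state column defined as one minus the row sum; rows are stochastic
  to 1e-10.
* Zero-probability observation pairs (possible only under absurd
  parameters, by underflow) raise an error naming the pair; inside the
  optimiser the probability is floored at 1e-300 instead so the search
  can retreat.
* Nearly equal eigenvalues in the 2×2 exponential switch to a series form
  of the divided difference at |λ₁ − λ₂| < 1e-8.
* Subjects with missing covariates are dropped, never imputed; deaths
  without an exact age are right-censored at the last living observation.
* Reported years are rounded to 2 decimals, shares and differences to 1
  decimal, always computed from unrounded values first.

## Known limitations

* No hidden-Markov misclassification layer, frailty, or survey-weighted
  likelihood; three states only; no time-varying covariates.
* The exact-death contribution assumes death ages are known exactly for
  everyone who dies under observation; partially known death dates are
  not modelled.
* Finite-sample bias of weakly identified baselines (rare transitions) is
  visible at n ≈ 2000, as quantified above.
* The baseline-state regression conditions on survival to baseline; in
  short panels this is innocuous but it is not a joint model.
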