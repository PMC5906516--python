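# Methods

## The problem

Randomised trials of basal-insulin regimens report severe hypoglycaemia in
two aggregate forms: the *risk* `r/n` of at least one event over follow-up
`T`, and the *rate* `y/E` of events per person-year.  Any evidence synthesis
over such a mixed evidence base must choose a likelihood/link, and that
choice fixes (a) the scale of the relative effects and (b) the meaning of
the absolute baseline used downstream in economic models.  The package
implements four standard contrast-based Bayesian NMA models and carries
their outputs through to absolute 1-year probabilities, costs and
disutilities, so that the sensitivity of the economic quantities to the
modelling choice can be measured directly.

## Model structure

For arm `k` of study `i` with baseline arm `b` (lowest treatment code in the
study's records):

* logit:    `r_ik ~ Binomial(n_ik, p_ik)`, `logit(p_ik) = mu_i + delta_ik`
* cloglog:  `r_ik ~ Binomial(n_ik, p_ik)`,
  `cloglog(p_ik) = log(T_i) + mu_i + delta_ik`
* Poisson:  `y_ik ~ Poisson(E_ik exp(mu_i + delta_ik))`
* shared:   cloglog for studies that only report risks, Poisson for studies
  with rate records (a study reporting both contributes only its rates),
  with common `d` and common `sigma`.

`delta_ib = 0`.  Fixed effects: `delta_ik = d_k - d_b`.  Random effects:
`delta_ik ~ Normal(d_k - d_b, sigma^2)`, with compound-symmetry correlation
1/2 between the effects of a multi-arm study — algebraically identical to
the sequential conditional construction, and implemented as the joint
multivariate normal.  Consistency expresses all contrasts through
`d_2..d_K` versus the reference (treatment code 1, the once-daily glargine
slot); the inconsistency variant replaces this with one unrelated mean per
observed comparison, and is flagged when it materially (by ≥3) improves the
residual deviance or DIC.

The cloglog follow-up offset uses the natural log of follow-up in years, so
cloglog and Poisson effects are both hazards per year and directly
comparable.  The logit model deliberately ignores follow-up: its baseline is
a probability over the contributing trials' own horizons, which is exactly
why its absolute numbers sit below the 1-year scales when trials are short.

Priors are vague and configurable: `d, mu ~ Normal(0, 100^2)` on the linear
predictor scale, `sigma ~ Uniform(0, 2)`.  The baseline meta-analysis uses
the same machinery on single reference arms (`theta_i ~ Normal(m, sd_m^2)`),
and reports the posterior of the summary mean `m`, not the wider predictive
distribution for a new study (available as an option) — the summary-mean
choice matches how baseline probabilities of this kind are normally quoted.

## Absolute outcomes and economics

Scale-matched combination, draw-wise: `logit(p_k) = logit(p_1) + d_k`;
`cloglog(p_k) = cloglog(p_1) + d_k` (equivalently `p_k = 1-(1-p_1)^HR`);
`r_k = r_1 e^{d_k}` followed by `p = 1 - exp(-r t)` with `t = 1` year.
Baseline and relative-effect draws come from separate models, so they are
paired independently after seeded resampling to a common length.  Ranks are
computed per draw (rank 1 = fewest events; ties broken by treatment code)
and summarised by median and 95% CrI.  Expected cost and disutility are the
draw-wise products of the probability with a per-event cost (default £333)
and a per-event-experiencer utility decrement (default −0.012).  Charging
the cost against the probability of ≥1 event understates repeat-event costs
by construction; an events-based alternative (`cost × rate × t`) is provided
but off by default, mirroring how such analyses are usually done.

## Sampling

Posteriors are drawn by blocked Metropolis-within-Gibbs over independent
chains, vectorised across chains:

1. Two per-study Metropolis moves aligned with the posterior geometry:
   (A) shift `mu_i` while moving `delta_i.` oppositely, which keeps all
   non-baseline linear predictors fixed; (B) shift `delta_i.` alone.  Both
   use per-study Robbins-Monro scale adaptation (burn-in only, target
   acceptance 0.44).
2. Under random effects `d | delta, sigma` is exactly Gaussian and is drawn
   exactly (the likelihood touches `d` only through `delta`).  Under fixed
   effects each `d_k` gets an adaptive 1-D Metropolis update.
3. `sigma | delta, d` is exact: the precision is
   Gamma((A−1)/2, rate Q/2) truncated below at `upper^-2`, drawn by
   inverse CDF (grid fallback for a single effect).

This is the Gibbs structure BUGS-family software applies to these models.
An ensemble sampler was evaluated first and rejected: on hierarchical
posteriors its interacting walkers produced collectively biased
heterogeneity estimates that per-walker R-hat does not detect.  The present
sampler is validated in the test suite against `rjags` with identical
priors, both on a fixed-effect Poisson model and on the full shared-
parameter random-effects model (agreement on `sigma` to 0.03 and on every
`d_k` to 0.05 at test budgets).

Defaults: 4 chains × 3000 kept draws after 1000 burn-in iterations
(~2 s for a 20-study network), which holds split-R̂ ≤ 1.05 and bulk
ESS ≥ 400 for all reported parameters; fits that miss the contract carry a
warning rather than failing.  Identical seeds reproduce identical draws.
Numerical guards: linear predictors are clipped at ±60 before
exponentiation; binomial and Poisson deviances use the `0·log 0 = 0`
saturated-deviance convention; `p_D` is the plug-in `D̄ − D(mean fitted)`.

## Synthetic data

The generator draws, per study, a baseline log rate
`mu_i ~ Normal(log 0.38, 0.8^2)` and effects around fixed true log hazard
ratios (defaults span ±0.3 with `sigma = 0.3`), then simulates **one latent
Poisson count per patient**; the risk summary binarises those counts and the
rate summary sums them, so both formats describe the same events — the
coherence the shared-parameter model assumes.  Networks are
reference-centred two-arm studies by default (three-arm optional), 20
studies with a 12/4/4 both/risk-only/rate-only mix.  Defaults worth noting:

* **Follow-up** is log-uniform on [4 weeks, 2 years] (mean ≈ 7 months):
  real severe-hypoglycaemia evidence bases are dominated by short trials,
  and the published average in this literature is around five months.  A
  uniform draw over the same range would average >1 year and erase the
  logit-vs-1-year baseline contrast.
* **Baseline spread 0.8** on the log-rate scale reflects the very wide
  credible intervals reported for baseline severe-hypoglycaemia rates
  (roughly 0.07–1.2 events/person-year around a 0.38 centre).
* **Per-arm sizes** uniform on 50–500, a typical phase-3 range.
* **Patient frailty** (`patient_frailty_shape`, default off): with shape
  `k`, each patient's personal rate is the arm rate times a mean-one
  Gamma(k) frailty.  The arm's event *rate* is unchanged, but the
  first-event hazard drops to `k·log(1 + λT/k)/T` — events cluster in an
  event-prone subgroup, as observed clinically.  Shape 0.15 reproduces the
  published contrast between a 1-year first-event probability of ~0.17 and
  an event rate of 0.38/person-year (`k·log(1+0.38/k) = −log(1−0.17)`).
  With frailty off, cloglog-on-risk and Poisson-on-rate estimate the same
  hazard, which is what the process-equivalence test asserts; with frailty
  on, the risk-based baselines fall below the rate-based one, which is what
  the baseline-ordering test asserts.  No within-patient rate change after
  the first event is ever simulated, matching the models' assumption.

What passing tests show — and what they do not: the generator produces
constant hazards, exact exposure `E = n·T`, no dropout, no time-varying
rates, and no reporting selection.  Recovery and calibration results
therefore validate the estimation machinery under the models' own
assumptions; they do not certify the models against real-world violations
(non-constant hazards, informative censoring, outcome-definition
heterogeneity).

## Test and acceptance problem sizes

Interval-coverage and heterogeneity-recovery checks use 50 replicate
networks (8 regimens, 20 studies, `sigma = 0.3`) with 2000 kept draws per
chain per fit; the process-equivalence check uses one 20-study both-format
network with 50 000 patients per arm so that the information lost by
binarising counts is negligible against Monte-Carlo error; deviance
calibration averages `D̄/n` over three replicate networks.  These sizes give
each check comfortable statistical resolution at interactive runtimes.

## Known limitations

* Two-arm and three-arm trials are generated; the engine's multi-arm
  machinery is exercised by tests but the default evidence base is pairwise.
* No meta-regression, covariate adjustment, arm-based models, or
  negative-binomial likelihood (the natural next model when rate data are
  overdispersed).
* No node-splitting: inconsistency assessment is global (unrelated-effects
  model comparison) only.
* The logit baseline conflates trials with different horizons by design;
  it is reported because it is widely used, not because it is recommended.
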