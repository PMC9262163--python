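# Methods

This note documents the models, the synthetic-data generator, the numerical
machinery and the open design choices behind `capsoc`. Everything stated here
is either a modeling assumption or a property the test suite and
`scripts/acceptance.py` verify by computation; no empirical claim beyond
those is made.

## 1. From event streams to dyadic count/opportunity tables

The observational unit throughout is the **dyad-year**. Each behavior has an
explicit opportunity denominator so that uneven observation effort enters
the model as binomial exposure rather than as bias:

**Grooming** (directed). Scored per 10-min focal follow. For the ordered
dyad (i, j) in a year, opportunities = number of follows of *i* plus follows
of *j* at times when the two were co-resident; the count is the number of
those follows in which *i* groomed *j* at least once (repeats within one
follow collapse to one). Grooming events that reference no known follow, or
that the referenced follow could not have observed (neither participant is
the focal, or the pair was not co-resident), are skipped with a warning.

**Coalitionary support** (directed). The time-sorted aggression stream of
each group is segmented into 5-min conflict intervals *anchored at the first
event of each burst*: a new interval starts at the first event at least
5 min after the current anchor. Burst anchoring (rather than clock-aligned
bins) makes the segmentation invariant to clock offset. Within an interval,
*i* joins *j* when *i* aggresses a third party that *j* aggressed (j's
opponent or victim) or that aggressed *j*; at most one instance per directed
pair per interval, with no temporal-order requirement inside the interval.
Opportunities: every individual resident in the conflict's group at the
interval start had the opportunity to join each conflict participant. The
joinee must be a participant — one cannot join an individual who is not in
the conflict.

**Foraging proximity** (undirected). Only scans in a foraging context
qualify. Per unordered dyad, the qualifying scans (subject is one of the
pair, the other co-resident) are thinned greedily from the earliest so that
retained scans are at least 10 min apart; opportunities = retained scans,
and a retained scan's 10-min window scores 1 if any qualifying scan inside
it records the pair within 5 body lengths (~1 m). A neighbor with a missing
distance is treated as beyond threshold. Thinning restarts at calendar-year
boundaries, consistent with annual aggregation.

**Partner datasets.** Subjects are always adult females (age >= 5 years at
the event date); the partner side is restricted to all group members, adult
females, or adult males. The restriction is applied at the event/opportunity
level — tables are rebuilt from the filtered event base, never by subsetting
aggregated rows — so denominators always match the dataset definition.

Conventions: co-residence is evaluated at the follow/interval/scan start
time; a dyad-year row exists only if opportunities > 0; timestamps are
timezone-naive local time; all builders are deterministic.

Every builder has a brute-force twin in `capsoc.validation` that restates
the rule literally (per-query membership scans, full pair enumeration); the
test suite and the acceptance script require exact agreement on randomized
toy streams, including streams with group transfers, orphaned events and
missing distances.

## 2. The Social Relations Model stage

For one behavior x partner dataset,

    count_ijt ~ Binomial(opportunities_ijt, p_ijt)
    logit p_ijt = alpha + y_t + g_it + r_jt      (directed)
    logit p_ijt = alpha + y_t + s_it + s_jt      (undirected)

with year offsets y_t (omitted for single-year tables) and individual-year
offsets g, r, s. Each offset family enters the likelihood centered on its
own mean, which (a) matches the offsets' definition as zero-centered
deviations from the population average, and (b) removes the soft
non-identifiability between the intercept and the family means. Priors:
Normal(0, 2.5) on alpha; half-Normal(1) on every random-effect scale; both
weakly informative on the logit scale and overridable via `SRMSpec`.

Outputs are the posterior mean and SD of each offset per individual-year —
the quantity carried to the survival stage. Individual-years present in the
table with zero counts are retained (they inform shrinkage); individual-years
absent from the table get no estimate and propagate as missing.

Design choices where the random-effect structure was open: offsets are
independent across families (no giving-receiving correlation parameter) and
there is no dyad-level effect; year enters as a zero-centered random offset
family rather than fixed effects. These are the minimal structures that
support the pipeline's outputs (individual-year offsets with uncertainty);
correlated or dyadic extensions would refine, not change, the interface.

Convergence is flagged (not fatal) when split-R-hat exceeds 1.05 on any
reported offset. On large tables (thousands of offsets) the max over
offsets is a noisy statistic at modest ESS, so flags on full-scale runs at
reduced MCMC settings are expected and recorded in the run manifest.

## 3. The survival stage

Female-year rows carry age (years at July 1), dominance rank in [0, 1]
(1 = highest), mean group size, group id, and the integration estimate
joined at year t - lag (lag 0 by default; lag 1 drops each female's first
observed year). Status is `died` if the death date falls in the year,
`censored` in the final observed year otherwise, `survived` in between.
Rows lacking an estimate are dropped complete-case with a logged count.

All covariates are standardized over the analysis rows; the integration SD
is divided by the same scale as the integration mean, keeping the
measurement model consistent. The model is a piecewise-exponential AFT on a
log-days timescale:

    eta_it = mu + beta_social * s*_it + beta_age * age + beta_rank * rank
           + beta_gs * gs + u_female(i) + v_group(g)
    s*_it ~ Normal(integration_mean_it, integration_sd_it)
    P(death in year) = 1 - exp(-Delta * exp(-eta_it)),  Delta = 365.25 days

Death rows contribute log p, survived/censored rows log(1 - p); deaths are
assigned the full year's exposure (a partial-exposure refinement would
change Delta per row, not the structure). The hazard is exp(-eta), so
positive coefficients lengthen expected lifetime, and mu is interpretable
as log expected lifespan in days (~9.5 for a ~36-year expectancy). The AFT
family had to be chosen; the piecewise-exponential form is the simplest one
compatible with annual time-varying covariates, and its two limits are
testable: with no effects the intercept collapses to the exponential-rate
MLE log(person-days/deaths), and eta = 9.46 gives an annual death
probability of 1 - exp(-365.25 e^-9.46) = 0.028.

Priors: Normal(9.5, 2) on mu (days scale), Normal(0, 1) on slopes,
half-Normal(1) on both random-intercept scales. Intervals are central 89%
quantile intervals (5.5%/94.5%). The battery fits the 5 x 3 grid of
measures and partner datasets with an identical configuration per lag;
foraging is undirected, hence 15 models.

The measurement-error treatment assumes the stage-one (mean, sd) pair is a
calibrated posterior for the true score — exactly what the SRM emits, and
what the generator's emulated estimates reproduce by construction. Under
that assumption the latent-variable formulation corrects the attenuation a
plug-in covariate would suffer, and inflating the input SDs widens the
sociality coefficient's posterior (a tested contract). One subtlety: in the
rare-event limit the annual model is log-linear in eta, and with a roughly
homogeneous measurement SD the inflation term beta^2 s^2 / 2 is absorbed by
the intercept, so the widening is second-order and can vanish into Monte
Carlo noise. The contract is therefore checked on a synthetic dataset with
elevated mortality (~10% annual) and a strong true effect, where the hazard
nonlinearity makes measurement error first-order informative and the
widening is systematic (observed width ratios ~1.6-2.2 across seeds).

## 4. The synthetic-data generator

The generator emulates the study design, not any particular dataset:
10 groups, 8 adult females per group (plus 4 males and 6 immatures) over 15
years by default. Females are philopatric and adult from age 5; males
migrate with exponential tenures (mean 4 years) and are replaced on
departure; natal males emigrate at 5; each group produces ~1.2 births per
year. Dominance rank is a persistent per-female uniform quantile with small
annual noise (no rank-dynamics model). Group size is recomputed from
realized membership (quarterly counts averaged), so deaths and migration
feed back into the covariate.

Every individual-year has a latent sociality core c_it on the logit scale
(unit marginal variance; persistent per individual with small annual jitter
so lag-0 and lag-1 analyses differ). The five channel propensities load on
the core with channel-specific scales and loadings; grooming giving tracks
the core exactly (loading 1), making it the clean two-stage recovery
channel, while receiving, support and foraging channels carry channel noise.
Interactions are then drawn per opportunity with logit p = base + g_i + r_j
(+ s_i + s_j for foraging), so the grooming builder's table is exactly
binomial under the SRM — the generative round trip the recovery tests
close. Support adds one aggressor-target seed pair per burst with
co-residents joining either side; proximity is drawn per scan and neighbor.

Survival is drawn year by year from the AFT likelihood using the TRUE
latent core (never an estimate), with covariates standardized by fixed
nominal reference moments (age 12 +- 6, rank 0.5 +- 0.289, group size
20 +- 4) so the generator needs no second pass; deaths truncate membership
and the behavioral record. Defaults: mu = 9.46 log-days, beta_social = 0.5,
beta_age = -0.08, beta_rank = -0.10, beta_gs = 0.10, female/group intercept
SDs 0.3/0.2 — effect sizes of the order field studies report, with ~2.8-4%
annual adult-female mortality.

Observation densities default to roughly one fifth of a full long-term
study's (7 focal follows per individual-year, 64 aggressive intervals and
420 scans per group-year, vs. ~35/322/2086 in the `paper_scale` preset);
the reduced density keeps full-pipeline runs at desk timescales and is the
problem size at which the packaged recovery results are computed. A
`test_scale` preset (2 groups, 5 years) backs the fast tests.

`simulate_integration_estimates` additionally emulates stage-one output
directly from the truth: with measurement y = c + N(0, tau) and prior
c ~ N(0, 1), it emits the exact posterior (mean y/(1+tau^2), variance
tau^2/(1+tau^2)), so conditioning on the emitted pair the truth is
Normal(mean, sd) — the calibration the AFT's measurement model assumes.
This is the fast path for survival-stage recovery tests; the slow path runs
the real SRM.

What the generator does *not* emulate: fission-fusion or rank dynamics,
kinship, observer misidentification, seasonality, or correlated residuals
within dyads. Passing recovery tests therefore demonstrates correctness of
the inference machinery under the stated model, not robustness to every
field complication.

## 5. Posterior computation

Both stages expose an unconstrained log-posterior with analytic gradients
(scales on the log scale with half-normal priors plus Jacobian), sampled by
the package's Hamiltonian Monte Carlo engine:

* **Warm start.** L-BFGS locates the posterior mode (log-scale coordinates
  box-bounded in [-4, 3] to stay off the degenerate sigma -> 0 ridge of
  centered hierarchies); the diagonal curvature there — exact coordinate
  differences up to dimension 400, a Hutchinson diagonal estimate above —
  seeds the mass matrix, floored at curvature 0.1 since every coordinate is
  a z-score, log-scale or standardized coefficient.
* **Adaptation.** Dual-averaging step size toward 0.85 (0.8 for the large
  SRM fits) and windowed variance re-estimation of the diagonal mass at 50%
  and 85% of warmup.
* **Trajectories.** Leapfrog counts jittered uniformly in [1, max_leapfrog].
  High-dimensional fits (thousands of offsets) need long trajectories:
  max_leapfrog 48-64 for full-scale SRM tables, 24-32 elsewhere.
* **Funnel moves.** After each HMC iteration, a 1-D slice sampler updates
  each random-effect family along its joint rescaling direction
  (sigma -> sigma e^t with members scaled by e^t for centered families, by
  e^-t for non-centered ones, with the scaling Jacobian included). This
  direction is prior-free for a centered family and is exactly the slow
  "funnel" axis that diagonal-mass leapfrog cannot traverse; the sampler
  test suite checks it on a Neal-style funnel.
* **Parameterization by information.** The SRM uses centered offsets (its
  dyadic data inform each offset strongly — the regime where centering
  mixes well); the AFT uses non-centered female/group intercepts (death
  events are rare, so each intercept is weakly informed) and per-row
  non-centered measurement latents.
* **Diagnostics.** Split-R-hat and bulk ESS via `arviz`; fits are flagged
  above R-hat 1.05 on reported parameters, divergences are counted, and
  chains are deterministic given the seed (independent generators spawned
  from one `SeedSequence`; per-stage seeds in the pipeline derive from a
  master seed via a fixed splitting rule, giving byte-identical reruns).

Numerical guards: binomial terms via `logaddexp`; the death likelihood uses
`log(-expm1(-h))` with the hazard capped (log h <= 30) against overflow at
absurd linear predictors; non-finite proposals are rejected as divergences.

## 6. Problem sizes and tolerances in the packaged checks

The validation battery (tests and `scripts/acceptance.py`) runs at sizes
chosen to exercise each property at desk scale: 100 random toy streams for
builder/oracle agreement (exact equality); SRM recovery at 40 individuals x
50 opportunities (rank correlation >= 0.8; offset family centered within
0.1); AFT recovery at the default study scale with beta_social = 0.5
(posterior mean in [0.3, 0.7]); 89%-interval coverage under a null effect
over 50 scaled-down replicates (binomial tolerance +-10 points); the
closed-form intercept limit within one posterior SD; strict widening of the
beta interval under 10x input SDs (on the elevated-mortality dataset
described above); strict monotonicity of the prediction
curve when all draws are positive; and byte-identical summary tables across
two seeded pipeline reruns. The two-stage path (events -> SRM -> AFT, on
the adult-female grooming dataset) reports its recovery correlation and the
recovered beta rather than asserting a band, since the reduced observation
density widens its interval.

## 7. Known limitations

* The SRM omits dyad-level effects and giving-receiving correlation; with
  strongly reciprocal behaviors the offsets absorb dyadic structure.
* The exact random-effect and prior structure of a field analysis may
  differ (e.g. hierarchical year effects or group intercepts in the SRM
  stage); the interface would not change.
* Max-R-hat over thousands of offsets is conservative at modest ESS;
  full-scale SRM fits may be flagged although point estimates are stable.
* Deaths carry a full year of exposure; sub-annual exposure would need the
  per-row Delta refinement.
* The battery fits 15 models independently, as designed — no multiplicity
  adjustment or model comparison is attempted.
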