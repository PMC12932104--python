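# Methods

## The model

`dietabm` simulates how an immature Sumatran orangutan (*Pongo abelii*)
accumulates its diet repertoire — the set of food items it knows how to
process and eat — from birth to the end of immaturity at 15 years, and
asks whether adult-like diets can emerge without social learning.

The simulation is spatially implicit and runs in daily time steps of a
365-day year. Each day the immature visits a Poisson-distributed number
of feeding patches (mean 27/day, the observed daily patch count of Suaq
Balimbing mothers, whose dependent offspring are led to the same
patches). Each patch contains exactly one food item, drawn i.i.d. from a
fixed 262-item encounter distribution. At every patch the immature is
assigned one of four social states by a hierarchy of Bernoulli
decisions, each with an age-dependent probability:

1. **associated** with a conspecific? — if not, *alone*;
2. if associated, **close** (≤10 m)? — if not, *distant association*;
3. if close, **peering** (close-range observation of a conspecific)? —
   if not, *close association*.

If the patch's item is already in the repertoire the immature simply
feeds. Otherwise it explores the item with a probability set by its age
and social state; each food item must be explored a number of times
scaled to its processing complexity (ranks 0–5 mapping to 1, 2, 2, 3, 3,
4 required explorations) before it enters the repertoire, permanently.

Social-learning treatments remove branches of the state hierarchy
without touching any other curve: the *no-peering* treatment forces
decision 3 to fail (removing observational learning), the
*exposure-only* treatment forces decisions 2 and 3 to fail (additionally
removing proximity-dependent enhancement). Exposure itself — being led
to patches at all — is never removed; its effect is bounded instead by
the Zone-of-No-Exposure sweep, which reruns exposure-only cohorts at
reduced daily patch means.

## Calibration curves

All probabilities driving the model are age curves with field-anchored
parameters:

| curve | form | slope (log-odds/yr) | anchor |
|---|---|---|---|
| P(associated) | logistic | −0.4 | p(7) = 0.97, giving p(1–3) > 0.99 |
| P(close \| associated) | logistic | −0.339 | p(0) = 0.975; checks: p(6) ≈ 0.838, p(14) ≈ 0.255 |
| P(peer \| close) | logistic | −0.12 | intercept **tuned** (−2.410) |
| P(explore \| distant or alone) | hump c·(a/τ)·e^(1−a/τ) | — | τ = 2 yr; peak **tuned** (0.0803) |
| P(explore \| close) | same hump | — | τ = 2 yr; peak **tuned** (0.2223) |
| P(explore \| peering) | logistic | +0.12 | p(4.5) = 0.677 |

The slopes are published mixed-model age coefficients; the logistic
intercepts follow from the published anchor probabilities. The hump
replaces the smoothed (GAMM) exploration-age curves, which are not
published point-by-point: it is zero at birth, peaks at τ = 2 years
(inside the reported 1–3-year peak window) and decays exponentially. The
exploration rate when alone equals the distant-association rate, because
dependent immatures are essentially never observed alone and an
alone-specific rate cannot be estimated. The per-patch exploration
probability is taken equal to the per-scan probability, mirroring how
the field rates were translated into the model. Ages are continuous
(day/365) and curves are evaluated per day, not per integer age.

### The three free magnitudes

The two exploration peak heights and the peering intercept appear only
in unpublished supplementary material. They are identified against the
three published treatment means at the independence milestone (224,
224−11 and 224−72 items at 9 years). Identification is triangular: the
exposure-only mean responds only to the distant peak, the no-peering
mean additionally to the close peak, and the full-model mean
additionally to the peering intercept. `tune_free_parameters` therefore
solves three monotone 1-D root-finding problems in sequence (bisection
with common random numbers, cohorts of 150), which is cheaper and more
robust than a joint simplex search over a stochastic objective; a target
that does not respond to its parameter is flagged non-identifiable. The
tuned values are frozen as package defaults and re-derived by
`analysis/03_tune_exploration.py`. Every other published statistic then
serves as out-of-sample validation.

## The synthetic environment

The real encounter-frequency table of the 262 items is deposited
externally and not required. The default environment instead gives item
of rank r encounter probability ∝ r^(−s), with the tail exponent s the
one free parameter. It is calibrated (bisection, common random numbers)
so that the Michaelis–Menten asymptote V_max fitted to synthetic adult
accumulation curves — 95 adults × 4,232 draws, the published field
effort of 402,082 scans — equals the published adult repertoire size of
248 items; the result is s = 1.3583 (validation: V_max 247–250 across
seeds). 248/262 is the only published constraint on the distribution
tail, and the repertoire dynamics depend on the tail far more than on
the body of the distribution. A CSV loader accepts the real table when
available.

Complexity ranks are assigned rarity-biased (rarer items tend to carry
higher ranks, as complex foods are rarely encountered) using a noisy
rank with s.d. 0.15·n, under a default category mix of
(0.40, 0.25, 0.15, 0.10, 0.06, 0.04) for ranks 0–5. Neither the true mix
nor the exact rarity–complexity correlation is published; both are
config-overridable.

## Estimators

* `fit_logistic_age_curve` — trial-weighted binomial logistic fit
  (statsmodels GLM). The field analyses used quasibinomial/binomial
  mixed models; here random effects and dispersion are not estimated,
  because only the point predictions feed the simulator. Complete
  separation is flagged with a warning rather than an error.
* `fit_mm` — pooled nonlinear least squares for V(n) = V_max·n/(K+n)
  (scipy `curve_fit`; starting values V_max⁰ = max observed count,
  K⁰ = median effort), a fixed-effects approximation of the
  random-intercept fit used on the field data. At full saturation the
  hyperbolic form overshoots the universe size by a few percent — the
  accumulation curve flattens faster than the hyperbola — which is why
  calibration targets the *fitted* V_max, not the count of items seen.
* `estimate_peering_effect` — before/after exploration proportions
  around peering events (the after-rate restricted to events without
  prior exploration, as in the field analysis) with logit-scale normal
  CIs, plus a binomial logistic age trend.
* `compare_treatments_poisson` — Poisson log-linear model with treatment
  as a categorical predictor, fitted by IRLS implemented in-package (the
  statsmodels GLM serves as an independent oracle in the tests, never as
  the implementation), reporting Wald z and two-sided p per
  non-reference treatment plus raw mean differences in items.
* Milestone CIs are normal-approximation means ±1.96 s.e.; a percentile
  bootstrap is available behind a flag.

## Simulator internals

`simulate_immature` is vectorized but stream-equivalent to the per-patch
state machine, with a fixed draw order per agent (daily Poisson counts;
one uniform per patch for the item; three for the state hierarchy; one
for exploration). An exploration uniform is drawn for every patch and
ignored once the item is known — learning is unaffected because
counters only matter up to the threshold and repertoires never shrink —
which is what makes a closed-form (sort/cumsum) learning pass possible.
The brute-force oracles in the test suite replay the same stream and
must match exactly. Cohort agents use `SeedSequence(master_seed)`
spawned substreams, so agent i depends only on (master seed, i).

Running treatments on a *shared* master seed makes comparisons
pathwise-coupled: the same patch and uniform streams, with exploration
probabilities pointwise ordered across treatments, give repertoire
trajectories that are ordered day by day by construction. The ordering
property tests use this coupling; milestone statistics use independent
master seeds per treatment.

## What the synthetic data emulate — and what they do not

`synthetic_data` generates scan-level focal follows (2-minute-interval
instantaneous records with the associated/close/peering flag hierarchy),
all-occurrence peering events with explore-within-1-hour outcomes, and
per-adult accumulation curves, at the field dataset's scale. Individual
heterogeneity is a per-individual, per-curve log-odds shift (s.d. 0.3),
not a full random-effects structure; follow lengths and age coverage are
idealized (uniform) rather than matched to field sampling effort; there
is no observer error, no missing scans, and no full-day-follow filter.
Passing recovery tests therefore show that the fixed-effects estimators
recover generating truth under mild heterogeneity — not that they would
reproduce every property of mixed-model fits to the real, unbalanced
field data.

## Problem sizes

The packaged analyses use the published design throughout: 250 immatures
per treatment × 15 years × ~147,800 patches each, 95 synthetic adults ×
4,232 draws, 30 focal individuals × ~99,000 scans, 367 peering events.
The tuner uses cohorts of 150 (9 simulated years); tests exercise
reduced cohorts only where the full design adds nothing to the property
under test.

## Fidelity and limitations

With the calibrated environment and tuned defaults the model reproduces,
out of sample: the pooled patch statistic (≈147,820 ± ~380 per immature
over 15 years vs the published 147,807, s.d. 382), the full-model mean
at independence (inside the published 221–226 CI), the treatment
reductions (≈−11 and ≈−72 items; Wald z ≈ −8 and ≈ −58 vs the published
−8.3 and −58.3), the strict full > no-peering > exposure-only ordering
at every age, and zero exposure-only immatures reaching the adult-like
threshold.

Three emergent statistics are systematically high relative to the
published values: the full-model proportion adult-like by 15 years
(≈0.83–0.88 vs 0.784), the no-peering proportion (≈0.05–0.09 vs 0.016)
and the mean age of first reaching the adult-like threshold (≈8.2–8.5 y
vs 7.5 y, CI 7.25–7.84). All three depend on the precise shape of the
age-exploration curves between mid-dependency and independence, which
is exactly what the parametric hump cannot recover from the published
anchors alone: the simulated mean trajectory approaches its plateau more
gradually than the field-calibrated original, shifting threshold
crossings later and letting slightly more immatures cross eventually.
These deviations are reported as-is (see `analysis/04` output and the
acceptance checks); re-shaping the hump to chase them would amount to
fitting unpublished curves to downstream outcomes.

Known limitations beyond fidelity: no spatial movement or patch
revisitation structure, no seasonality or patch depletion, no food
sharing/solicitation, no hunger-driven upregulation of exploration, no
mother-identity bookkeeping (social partners exist only through the
state probabilities), and exploration counters are per item rather than
per species. Treatments change behaviour only through the state
hierarchy; everything else is held fixed.
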