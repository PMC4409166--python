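# Methods

This note records the modelling assumptions, simulator calibration and
numerical conventions of the package. Everything quantitative stated here
is computed by the test suite or by `scripts/acceptance.py`; nothing is
asserted that the code does not itself reproduce.

## Experimental design model

The random partitioned design splits a pool of `n` species (default 12)
into disjoint communities of equal richness, so each species occurs exactly
once per partition. Two independent partitions are drawn at each
intermediate richness level (default levels 2, 3, 6), plus all monocultures
and one full mixture: `n + Σ_L 2·(n/L) + 1` compositions, i.e. 37 for the
default pool. Each composition is replicated three times in each of three
environments (beech tea, pH5 beech tea, spruce tea): 333 microcosms.

Species carry colony-morphology labels (default: six morphologies, two
species each). Within a community of an intermediate level, two species may
not share a morphology (they could not be distinguished when plated out);
conflicts are resolved by swapping a conflicted member with a uniformly
chosen member of another community such that the swap removes the conflict
without creating a new one on either side. Infeasible demands (more copies
of one morphology than communities) are rejected by pigeonhole before any
swapping. Duplicate compositions between the two partitions of a level are
resolved by re-drawing the second partition (bounded retries); how the
original design handled duplicates is not documented, and re-drawing is the
simplest rule that guarantees distinctness.

## Yield and generation computations

Yield of a growth period is `max(OD) − OD_start`, clamped at zero: yields
are biomass gains and the additive sums downstream assume non-negativity.
Generations are `Σ log2(OD_end / OD_start)` over periods; periods in which
the culture shrank contribute negatively by default (the literal formula),
with an optional floor at zero per period (`floor_zero`) since the original
handling of shrinking periods is not documented. OD is kept as
dimensionless absorbance throughout; no conversion to cells or dry mass is
attempted.

## Synthetic experiment generator

The generator simulates exactly the quantities the analysis consumes, with
one switch per mechanism:

* **Monoculture yields.** `a_{i,t}(E) = base_i(E) · drift_i^(t/5)`. Base
  yields are drawn once per configuration, uniform 0.1–0.4 absorbance, with
  spruce scaled by 0.5 (yields on spruce tea are uniformly lower). `drift`
  is 1 except under additive evolution.
* **Community yields.** `A = θ(S,E,t) · Σ a_{i,t} d_ij (ε_ij at t=5) +
  noise`, with a single multiplicative interaction factor
  `θ(S,E) = θ1(E) · S^(−λ(E))` on the additive sum. A single factor rather
  than pairwise coefficients is used deliberately: it is exactly the
  quantity the ratio index and the slope-based counterfactual models
  identify, keeping the generator inside the inferential family. θ applies
  to true communities (S ≥ 2) only; a monoculture's yield *is* its
  monoculture yield.
* **Extinction.** Each member of an S-species community survives to the end
  with probability `logistic(α_E − γ_E · log S)`, independently; a draw in
  which every member dies is repeated (a tube that still grows cannot be
  sterile), which in particular makes monocultures immortal. Extinction is
  Bernoulli rather than abundance-mechanistic because the analysis consumes
  only the binary survival matrix and a binomial GLM. The plating detection
  limit (~1 in 10⁴) is recorded in the configuration for provenance; it is
  implicit in the calibrated rates rather than modelled through abundances.
* **Isolate assays.** For survivors,
  `b_{i,j,5} = a_{i,5}(E) · (1 + δ·log S_j) + noise` with decline slope
  δ ≤ 0 (default −0.05): isolates from more diverse communities yield less
  when regrown alone, a modest ~12 % deficit at twelve species.
* **OD trajectories.** Within-period growth curves are logistic from
  `OD_start` (default 0.02) to `OD_start + yield`, sampled daily for five
  days with absolute reading noise (sd 0.002). The logistic shape is an
  assumption used only to exercise the yield/generation computations — no
  within-transfer curve data exist to calibrate against. Endpoints are
  pinned so the yield computation inverts the target exactly at zero noise;
  with noise, the max-minus-start rule overshoots by under 0.5 % at default
  settings (tested by Monte-Carlo).

### Calibration

Defaults are solved from the published anchor rates, not tuned:

* θ(2,E) = 0.523 / 0.580 / 0.751 and θ(12,E) = 0.130 / 0.145 / 0.161 for
  beech / pH5 / spruce give `(θ1, λ)` per environment (power law through the
  two anchors). The spruce curve implies θ1 = 1.36 > 1 at S = 1, which is
  irrelevant because θ is never applied to monocultures.
* Survival intercept α = 4.6 in every environment (monoculture survival
  logistic(4.6) > 0.99); slopes γ solved so extinction at S = 12 is
  0.74 / 0.84 / 0.86 per environment. The all-members-dead resampling pulls
  the realised twelve-species extinction down slightly (≈0.73 in beech),
  well within the calibration tolerance.
* Scenario presets carry fixed pure effect sizes: `sorting_only` —
  extinction 50 % at S = 12 in all environments, nothing else changes;
  `additive_evolution` — per-species drift ~ N(1.30, 0.15), no extinction;
  `interaction_evolution` — θ doubled by week 5, no extinction;
  `neutral_additive` — θ ≡ 1 and nothing changes; `mixed` — all mechanisms
  at the default calibration (drift ~ N(1.10, 0.10), θ×1.5 in pH5 only).

### Noise model

Observation noise and the persistent per-microcosm (tube) effect are
parameterised as fractions of the **mean monoculture base yield** (defaults
0.05 and 0.03) and applied as constant absorbance noise to every
observation. Two reasons: plate-reader error is close to absolute in OD
units, and homoscedastic errors are what the analysis-stage linear and
mixed models assume — noise proportional to each observation's expected
yield (which spans ~0.05–3 absorbance across richness levels) makes the
likelihood-ratio test for time effects badly anticonservative through no
fault of the test. The tube effect is shared by the week-0 and week-5
observations of a microcosm, which is precisely the random intercept the
mixed models estimate.

### What the generator does not emulate

Real abundance dynamics within transfers, gradual (rather than end-point)
extinction, evolution of the *shape* of interactions (θ is a single
factor), phage, cross-feeding topology, and measurement artefacts beyond
additive noise. Passing tests therefore demonstrate that the inference
machinery attributes mechanisms correctly *when the data-generating process
matches the model family it probes* — they are a validation of the
pipeline, not evidence about any particular real community.

## Counterfactual partition

Models 0–5 are fitted on communities (richness ≥ 2) only; monocultures
enter through the species-level mean yields `a` (averaged over the three
replicate monoculture tubes per environment and week) and the isolate
yields `b`. Richness enters as continuous log(richness) interacting with
both intercept and additive-sum slope; the full baseline term set is
`additive * environment * log(richness)`, simplified by backward AIC
elimination respecting marginality (a main effect is kept while any of its
interactions remains; AIC ties drop the higher-order term first).

Counterfactual predictions never re-estimate coefficients: the week-0 fit
is applied to the scenario's additive sum (extinction masks by ε; additive
evolution substitutes week-5 yields; both can combine). For the
isolate-based sum without the extinction mask, extinct species — which left
no isolate — contribute their ancestral monoculture yield (no isolate, so
treated as unevolved); an isolate missing for a *surviving* species is an
error.

Model 4 refits the retained week-0 term structure with new coefficients on
week-5 data. Model 5 replaces log-richness with the composition factor;
because the additive sum is constant across the three replicates of a
composition within an environment, per-composition slopes are collinear
with per-composition intercepts and the model reduces to a
composition-by-environment cell-means fit — its predictions are the cell
means, which is the intended meaning (interaction change specific to
particular species combinations).

The evaluation regressions (observed change on predicted change) include an
intercept by default (suppressable); whether the original evaluation used
one is not documented. The additive model entering the ledger is the
lower-AIC of models 2 and 3. The ledger identity
`additive + systematic + composition + residual = 100 %` holds by
construction; the extinction share is nested inside the other components
(the combination models contain ε) and is therefore reported separately
rather than summed. Adjusted R² can invert the nesting order in small
samples; a negative increment is reported as-is with a warning, never
clipped.

**AIC convention.** Everywhere, `AIC = n·log(RSS/n) + n·log(2π) + n + 2k`
with `k` the number of mean parameters — the full Gaussian log-likelihood
form used by statsmodels — so values are comparable across
implementations.

**Attribution rule.** In recovery studies a scenario is "recovered" when
its ledger component is the largest of the four mechanism components
(extinction, additive, systematic interaction, composition-specific
interaction). The residual is replicate noise, not a mechanism, and is
excluded from the argmax.

## Time-interaction test

`A_{j,t} = β(E, S, t, Σ a_{i,5} d_ij)` with a per-microcosm random
intercept, fitted by maximum likelihood, against the same model without the
two time terms (week and week × additive); the statistic is referred to
χ²₂. Additive evolution is absorbed by the week-5 additive covariate, so a
significant time effect indicates changed interactions. When the gradient
optimizer abandons a fit (which happens when the null model is badly
misspecified, e.g. θ doubled), a direct-search (Powell) refit is accepted
if it improves the likelihood; if the mixed fit fails outright the test
falls back to a fixed-effects likelihood-ratio comparison and says so.
Under the neutral scenario the empirical rejection rate at the 5 % level is
5.0 % (500 seeds, reproduced in the acceptance tests).

## Trend battery

* Initial productivity–richness: OLS `yield ~ environment × log(richness)`
  on week-0 yields of all 333 microcosms, with the environment-by-richness
  interaction F-test.
* Yield trajectories: linear mixed model with fixed effects
  `week × environment × log(richness)` and a per-microcosm random
  intercept; ML for AIC-based backward elimination of fixed effects, REML
  refit for reporting. A boundary (zero) random-intercept variance is
  flagged, not fatal. Time is continuous in weeks.
* Extinction: binomial GLM at the microcosm level,
  `extinct/richness ~ environment × log(richness)`.
* Isolate trend: OLS of `b/ancestral` on log source-richness plus
  environment; zero-ancestral rows are excluded with a log entry.

Note on stepwise selection: AIC retains a pure-noise 2-df term with
probability ≈ e⁻² ≈ 0.135 regardless of sample size, so "all noise terms
eliminated" happens in roughly half of null datasets, not nearly always.
The selection tests assert majority behaviour and the contrast with
strong-effect data, which is what AIC stepwise can actually guarantee.

## Problem sizes used in validation

Validation suites run at the full experimental scale (333 microcosms, 225
community observations per week): mechanism recovery uses 100 seeded
experiments per scenario, the null calibration of the time-interaction test
500 seeds, the extinction calibration 50 seeds, and Monte-Carlo checks of
the OD round trip 1000 draws. These sizes give binomial standard errors
comfortably inside the asserted tolerances.

## Known limitations

* The partition is only as interpretable as the counterfactual family:
  mechanisms outside it (e.g. richness-dependent noise, abundance shifts
  without extinction) load onto the interaction components.
* Adjusted-R² increments are not variance components in the ANOVA sense;
  they inherit the evaluation-regression's shared-term correlation (the
  observed and predicted changes both contain −A_{j,0}).
* Model 5's cell-means structure needs ≥ 2 replicates per
  composition × environment cell; with fewer it degenerates to
  interpolation and the residual share loses meaning.
* The mixed models use a single random intercept; random slopes and
  autocorrelated residuals are out of scope, as is any multiple-testing
  correction across the trend battery.
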