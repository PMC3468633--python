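# Methods

This note documents the statistical models the package implements, the
numerical choices behind them, what the synthetic-data generator does and
does not emulate, and the known limitations.

## Multi-state Huggins closed robust-design model

**Data.** A one-year transect study with 12 primary occasions (months) and
46 secondary occasions (sampling days; two months have three days instead of
four). Each marked animal carries a state-coded history with one character
per secondary occasion: `0` not captured, `F` female, `N` non-caring male,
`C` caring male. Sexes never mix within a history, and state cannot change
within a primary occasion (closure).

**Model.** Each animal follows a hidden Markov chain over live states plus
an absorbing dead state, one chain per sex (transitions between sexes are
structurally zero). Between primaries the animal survives interval *t* with
apparent survival Φ (indexed by the state at the *start* of the interval —
the survive-then-transition convention; the alternative order is not
identifiable from these data and is not offered) and then, if male, switches
parental state with transition probability ψ. Within a primary the
population is closed and each secondary occasion is an independent
Bernoulli(p) detection; first capture and recapture share the same p.
Abundance is not a likelihood parameter (the Huggins formulation); it is
derived afterwards by Horvitz–Thompson: N̂ = captured / (1 − (1 − p̂)^k).

**Likelihood.** Conditional on first capture. Within the release primary,
secondary occasions *after* the first capture contribute Bernoulli(p) terms
(occasions before it contribute nothing; the full closed-session conditional
is a documented alternative that changes only a constant for fixed
structures). At later primaries, a detected animal contributes a
Binomial(k, p) probability of its detection count with the hidden state
pinned at the observed state; an undetected animal contributes the sum over
live states of (1 − p)^k plus the dead state's certain non-detection. The
forward recursion is vectorised over individuals; its correctness is checked
in the test suite against exhaustive hidden-path enumeration on small
instances, and post-release outcome probabilities are checked to sum to one.

**Temporary emigration** is fixed at zero — the robust-design emigration
parameters are not modelled. This is a restriction, documented here.

**Estimation.** All parameters are driven by coefficient vectors through a
logit link and design matrices (a logit per ψ row suffices with two male
states; no multinomial link is needed). The score is computed analytically
by the adjoint of the forward recursion (gradients with respect to the
per-interval transition matrices and per-primary emissions, chained through
the link), which is what makes sweeping the structure catalogue tractable.
Optimisation is multi-start bounded L-BFGS-B on the link scale: start at
zero (all probabilities 0.5), optionally a warm start, plus seeded jittered
restarts (5 by default; 2 during catalogue sweeps, where each candidate is
warm-started by least-squares projection of the incumbent's logit-scale
cells onto the new design). Gradient tolerance 10⁻⁶; coefficients bounded at
±15 so probabilities stay a hair inside (0, 1) (they are additionally
clipped at 10⁻¹² from the boundaries so the score stays finite on the
bound). Standard errors come from a central finite-difference Hessian of
the analytic gradient; Wald intervals are formed on the logit scale and
mapped to the probability scale.

**K counting.** K is the number of design columns. Boundary or confounded
estimates (e.g. terminal parameters in full-time structures) are not
"corrected"; the catalogue's column counts reproduce the published K values
for every structure combination.

## Candidate structures and model selection

Survival and recapture each have a 15-structure catalogue: constant; shared
time; category (♀ / ♂ non-caring / ♂ caring); additive time+category;
per-category constant/time mixtures; sex, parental-state, and their additive
and mixed forms. Transitions have six: constant, time, state, additive
time+state, and the two one-direction-constant mixtures. Four time
surrogates — full time factor, season (wet-warm October–March vs dry-cold
April–September), mean temperature, mean rainfall — multiply out to
4 × 6 × 15 × 15 = 5,400 candidate models. Continuous surrogates are z-scored
for optimiser conditioning; the interval season is the season of the
interval's starting month. All time+factor structures are additive (no
interaction columns), including the four general-model candidates.

Rather than fitting the full grid, step-down selection fixes the general
structure (Φ and p additive time+category, ψ additive time+state), picks the
time surrogate by QAICc, then optimises ψ, then p, then Φ, carrying each
stage's winner forward. An all-constant starting point is supported as a
robustness check; the two paths agree on the structures they both carry to
the end, though near-tied stages (ΔQAICc well under 1) can differ.

QAICc = −2 logL/ĉ + 2K + 2K(K+1)/(n−K−1). The effective sample size n is
the frequency-weighted number of releases (primaries at which an animal was
captured and released); total captures or individuals are available as
configurable alternatives since no convention is universal. ĉ < 1 is not
truncated by default (a truncation switch exists). K is not augmented when
ĉ is estimated. Ranking ties break by smaller K, then label order, so output
is deterministic.

**Overdispersion.** ĉ comes either from a supplied goodness-of-fit
deviance/df ratio (with the 1–3 adequacy classification) or from a
parametric bootstrap: simulate from the fitted model conditional on the
observed releases, refit, and take observed over mean simulated deviance.
The bootstrap deviance is computed on the multi-state m-array — every
detection is a release, the outcome is the primary and state of the next
detection (or never) — against the saturated multinomial. Aggregating to
these sufficient summaries keeps the cell count fixed, so the deviance has
roughly constant expected degrees of freedom and the ratio is an honest
variance-inflation estimate (a raw −2 logL ratio is not, when nearly every
46-occasion history is unique).

## Body condition

Body volume is the three-diameter ellipsoid V = (π/6)·TBL·BW·BH. The
formula is a reconstruction choice documented prominently: the three
measured dimensions are treated as the ellipsoid's diameters.

The caring period of a male is read from the oldest eggs in his batch via
the cumulative development schedule (stage 1 → 6.6 d … stage 6 → 32.0 d;
the cumulative value, not a range midpoint); non-caring males get zero.
Males whose nymphs have hatched are outside the schedule's domain and raise
an error rather than being silently extrapolated.

Candidate models are normal likelihoods with linear mean
μ = β₀ + β₁·size (+ β₂·care) and power standard deviation
sd = α·∏ⱼ(zⱼ + δⱼ)^θⱼ over the variance covariates, with offset δ = 1 for
care covariates (the caring period is exactly 0 for non-caring males, where
a pure power law is degenerate) and δ = 0 for the strictly positive size
covariates. The variance function takes the covariate, not the fitted mean,
as its argument (switchable in principle; the covariate form is what the
two-step catalogue describes). With an empty variance set the fit reduces
to OLS with the ML (divide-by-n) residual variance, which the tests verify
to 10⁻⁶. Optimisation is BFGS from the OLS solution with a Nelder–Mead
polish. K counts all free parameters including α and the θs; AICc uses
n = number of records.

Two-step selection: step 1 ranks the four size-only structures; every
structure within ΔAICc < 2 of the best is carried into step 2 (so two
near-tied bases are both carried, as happens for body mass), where care
effects — caring period or parental state, on the mean, variance, or both —
are added and all variants ranked together.

## Feeding activity

Monthly feeding counts per category are modelled as
Binomial(n_captured, logit⁻¹(η_category + u_month)) with
u_month ~ N(0, σ_u²). The four fixed-effect structures (null, sex, parental
state, three-level category) carry K = 2, 3, 3, 4 including σ_u. The month
intercept is integrated by adaptive Gauss–Hermite quadrature (15 nodes by
default): per month, a Newton search finds the integrand's mode, the grid is
rescaled by the curvature, and the tests verify the result against dense
trapezoid integration to 10⁻⁵ and its stability from 15 to 30 nodes. σ_u
fixed at 0 collapses to ordinary binomial regression (pooled MLE in the null
structure). A boundary estimate σ̂_u ≈ 0 is reported as is. AICc uses
n = table rows (months × categories).

## Movement

Displacements are absolute transect-position differences between successive
captures of individuals recaptured at least five times (beyond first
capture) and in at least two months; each pair is labelled with the state at
the earlier capture, and individuals are summarised by their median. The
group comparison is an analysis of deviance on the per-capture displacements
(individuals are reported alongside as the replication unit): null vs
grouping model under a negative binomial likelihood by default — exact zeros
rule out gamma, and Poisson is visibly overdispersed in simulation — with
2Δ logL on (levels − 1) df against chi-square. Poisson is available as an
option. The family, link and observation unit of such field analyses are
rarely fully determined; the configuration covers the plausible options.

## Synthetic data generator

The generator defines the study conditions the tests and acceptance runs
exercise. Defaults: the 12-month/46-day layout (August–July, two three-day
months); roughly 500 males and 350 females recruited, front-loaded with
extra arrivals in the wet-warm season; survival 0.75 with a fixed irregular
month-to-month course (±0.8 logit) shared by females and non-caring males
and constant 0.9 for caring males; detection around 0.35 with an additive
month course and a +0.8 logit caring offset (caring males sit on their
batches and are easy to find); transitions around 0.25 (N→C) and 0.30 (C→N)
with an additive shared month course. Movement is a per-secondary Gaussian
step on the 0–200 m transect, sd 6 m for females and non-caring males and
0.4 m for caring males, reproducing the observed medians (≈5 m vs 0 m).
Morphometrics: DSL ~ N(4.0, 0.3) mm; V = 10 + 10·DSL − 0.45·period with
sd = 8·(period+1)^−0.25 (condition declines and homogenises over the caring
period); TBM = 0.02 + 0.006·V − 0.03·caring with
sd = 0.004·V^0.3·(1+caring)^0.6. Feeding rates 0.025 / 0.014 / 0.0025
(females / non-caring / caring) with σ_u = 0.5 and monthly capture totals
around 110/130/45 — tens of feeders among thousands of captures. All draws
are reproducible from the config seed, and ground truth (parameters and
latent fates) is always emitted so tests never re-infer what the generator
knows.

What the generator does **not** emulate: home ranges or spatial structure
beyond the step-size contrast, egg predation or batch dynamics, observation
heterogeneity between individuals, tag loss, or temporary emigration.
Passing tests therefore demonstrate correctness of the estimators under the
models' own assumptions, not robustness to their violation in real field
data.

## Problem sizes used in tests and the acceptance script

Likelihood correctness runs 200+ random instances with ≤ 4 primaries and
≤ 2 secondaries (where exhaustive enumeration is exact and fast). Parameter
recovery uses 100 replicate studies of 500 males + 300 females in the test
suite and 50 in the acceptance script; step-down selection consistency uses
20 replicates in the test suite and 10 in the acceptance script; both sizes
give stable majorities. Mean–variance selection uses 20 samples of 93
males; recovery n = 2000. These sizes are the package's choices for stable,
repeatable statistics.

## Known limitations

* Apparent survival confounds mortality with permanent emigration; the
  model cannot separate them, and derived abundance inherits any detection
  heterogeneity bias.
* Terminal-interval parameters in full-time structures can sit on ridges;
  they are reported as estimated, with K counted from design columns.
* The all-constant step-down start is less powerful at its early stages and
  can pick a near-tied alternative structure; agreement of the carried
  classes, not full-model identity, is the reliable property.
* The GLMM uses a single random intercept (month); individual-level
  heterogeneity in feeding propensity is not modelled.
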