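# Methods

## Task designs

**MCG (convex time budget).** The default design crosses earlier dates
t ∈ {0, 35} days, delays k ∈ {35, 72, 90} days and twenty discount factors
(0.50, 0.525, …, 0.95, 0.99): 120 unique (t, k, d) combinations, each shown
twice, 240 trials split into 5 blocks of 48, presentation order shuffled by a
single integer seed. Two delay sets circulate for this task family (35/72/90
vs 35/70/95); we default to {35, 72, 90} — the operational task description —
and expose the set in `DesignConfig`.

**MGT (six-box guessing).** 250 trials per session, the pink-box count
n ∈ {1..5} balanced at 50 trials per level (a design choice: the original
composition is not published; balance maximizes information per level). The
token is hidden pink with probability n/6 per trial. The payoff schedule is
not published either; the default is the EV-constant schedule
payoff_pink(n) = round(60/n), payoff_blue(n) = payoff_pink(6−n), so either
guess has expected value 10 points and differences in the chosen lottery's
spread are attributable to risk attitude alone. The schedule is a parameter;
the per-trial risk score `X·sqrt(p(1−p))` ranges over [4.47, 22.36] under the
default schedule and over schedule-specific bounds otherwise.

## Structural choice model

Utility of allocating *a* of the 100-token endowment to the earlier option:

    U(a) = (d·a)^α + B·(100 − a)^α,   B = β^1[t=0] · δ^k

The β exponent follows the quasi-hyperbolic convention: β acts only when the
earlier option is immediate. A `beta_mode="always"` switch applies β on every
trial for users who prefer the unconditional reading; with t = 35 trials in
the design the two differ, and the indicator form is what makes β "the
now-versus-later distortion" while δ carries calendar-time discounting.

Interior demand: g = 100·ρ/(1+ρ), ρ = (1/d)·(B/d)^{1/(α−1)}, computed as
100·expit(log ρ) for numerical stability. At α = 1 utility is linear and the
optimum is a corner (all early iff d > B; ties to later).

**MGT choice rule.** Softmax over CRRA expected utilities
EU(color) = p_color · payoff^α at temperature `temp`; temp → 0 picks the
higher-EU (safer, for α < 1 and EV-constant payoffs) color, temp → ∞ is a
coin flip, and α = 1 with EV-constant payoffs gives exact indifference.

## Synthetic-data generator

Agents are drawn from independent truncated normals per parameter. Defaults
(chosen once): α ~ N(0.92, 0.04), β ~ N(1.01, 0.08), δ ~ N(0.995, 0.003),
σ_alloc ~ N(3, 1) tokens, temp ~ N(1, 0.3). The session-1 population is
slightly future-biased (mean β 1.01) and patient, matching CTB-style
elicitations. Draws are truncated to legal ranges; δ is additionally kept at
or below 0.999 because an agent at δ = 1 with β ≥ 1 puts every allocation at
the later corner and (β, δ) are no longer jointly identified from choices.

Session-2 parameters add (i) a common session drift (familiarity), (ii) the
treatment shifts for the treated group, and (iii) optionally a house-money
term: α rises by `payment_risk_slope` per euro received between sessions
(participation fee ~ 7.5 €/h × N(2, 0.25) hours, plus the immediate payment
from one seed-selected session-1 MCG trial, paid only if that trial's earlier
date was immediate, at 0.05 €/token). All shifts are clipped to legal ranges
with clip counts logged.

The calibrated configuration (`calibrated_study_config()`) uses
d_alpha = −0.08, d_beta = +0.15, d_delta = −0.004, session drift
β +0.02 / δ +0.002, payment slope 0.0012. These magnitudes are the package's
own synthetic study conditions, fixed once by prospective simulation so that
the intended signs (risk down, future bias up, discounting growth attenuated
in the treated group; session-2 risk rise driven by payments) are expressed
reliably at Monte-Carlo scale. They are not estimates of any real effect.

**MCG noise model.** Observed allocation = interior optimum + N(0, σ_alloc),
censored to [0, 100] — exactly the two-limit Tobit the estimator assumes, so
the recovery suite tests a correctly specified estimator. An optional
`grid10` mode snaps allocations to the 10-token box grid to probe robustness
to the interface's granularity; grid data are still fit with the continuous
Tobit, and the recovery harness quantifies the resulting (small) bias. The
task's 15-attempt adjustment mechanic is not modeled; one final allocation
per trial is recorded.

What the generator does **not** emulate: learning or order effects within a
session, response times, dropout/attrition, questionnaire outcomes, and any
dependence between parameters. Passing tests therefore show that the
estimation chain is correct under its assumed data-generating process, not
that real data satisfy those assumptions.

## Two-limit Tobit estimation

Log-likelihood: interior rows contribute ln φ((a−g)/σ) − ln σ; rows at 0
contribute ln Φ((0−g)/σ); rows at 100 contribute ln(1 − Φ((100−g)/σ)).
Corner detection uses a 1e-6-token tolerance. Tail logs go through
`scipy.special.log_ndtr`, which is finite for arbitrarily deep tails, so no
explicit probability floor is needed.

Maximization is direct nonlinear MLE on (α, β, δ, σ) through smooth
reparameterizations — α = 0.9999·expit(u), β = exp(u), δ = expit(u),
σ = exp(u) — rather than the log-allocation-ratio linear Tobit, because
corner allocations make the log consumption ratio unbounded while the
allocation-scale model keeps censoring finite; the two coincide at interior
points. The α cap (0.9999) keeps the mean function defined; a fit at the cap
means "risk neutral to numerical precision". Optimization is L-BFGS-B with
multi-start (default 8 starts; deterministic jitter from
`start_jitter_seed`); u is clipped to ±30 to keep exp() finite on optimizer
excursions. Standard errors come from the numerical Hessian of the
log-likelihood at the optimum on the natural scale; a non-positive-definite
Hessian yields NaN SEs with the estimate still reported.

**Identification diagnostics.** All observations at one corner → the fit is
refused with a "non-identified" flag. Separately, a strongly future-biased
participant (B > d on every t = 0 trial) allocates everything later on all
immediate-date trials and the likelihood becomes flat *upward* in β: β is
then only bounded from below. Each fit therefore reports `beta_identified`,
true only if both halving and doubling β̂ (other parameters at the optimum)
cost more than 2 log-likelihood points. The β mixed model uses identified
cells only; δ and α are unaffected. `estimate_all` fits each participant ×
session cell independently and records failures as non-converged rows
without aborting the batch.

## Group-level inference

All treatment tests are REML linear mixed models with treatment (dummy)
coding, placebo and session 1 as references, so the group×time coefficient
is the treated group's session-2 shift. The REML solve is statsmodels
`MixedLM` (default optimizer; the explicit lbfgs option proved unstable on
trial-level tables).

* Risk models run at trial level on the per-trial risk score; β/δ models run
  on the per-participant×session estimates. (Replicating session-level
  estimates to trial level only rescales degrees of freedom; the
  session-level fit is the statistically cleaner default and both
  granularities can be constructed from the estimates table.)
* Random effects: participant intercept by default. A crossed trial
  intercept (`include_trial_re=True`) is available via variance components
  in a single-group formulation; it is not the default because all
  participants share one trial design per session, making trial effects
  orthogonal to the group×time contrast, and the crossed solve is expensive
  at full scale.
* p-values use t statistics with a residual degrees-of-freedom
  approximation (n − #fixed-effects); the df convention for such models is
  not standardized and this choice is documented rather than asserted.
* Payment covariates are coded as session-2-only regressors (zero in
  session 1): money received *between* sessions can only act on session-2
  behavior, and a participant-constant coding would be absorbed by the
  participant intercept. Zero-variance covariates are dropped (and logged)
  so nested models agree exactly.

`null_and_power` simulates replicate studies through the *full* pipeline
(simulate → score/estimate → mixed model) and reports rejection rates of the
interaction with Monte-Carlo SEs; rates are withheld below 100 replicates.

## Problem sizes and numerical checks

The test suite validates, among others: closed-form demand against staged
brute-force grid maximization (1,000 random draws, 1e-4 tokens); the MLE
against an exhaustive parameter grid (20 datasets of 40 trials, pitch
0.01/0.01/0.001/0.5); recovery at (α=0.9, β=1.01, δ=0.995, σ=3) over 100
replicate 240-trial fits (MAE bounds 0.05/0.05/0.003 and RMSE shrinkage at
480 trials); type-I error of the interaction test over 500 replicate
reduced-size studies (20 participants, ~60 trials per task per session, the
package's standard Monte-Carlo scale); and sign reliability of the
calibrated treatment effects over 100 replicates. Monte-Carlo work uses the
reduced scale; full-scale (57 × 2 × 240/250) runs appear in single-study
checks and in the acceptance script.

## Known limitations

* β is set-identified (not point-identified) for strongly future-biased
  participants under this design; the diagnostic flags but cannot repair
  this — only immediate-date trials with higher discount-factor ceilings
  would.
* The Tobit treats `grid10` data as continuous; an interval-censored
  likelihood would be the exact model for box-granular interfaces.
* Mixed-model p-values use a residual-df approximation, not Satterthwaite or
  Kenward-Roger.
* The MGT payoff schedule and the real studies' token-to-euro conversion are
  configurable assumptions, not published values.
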