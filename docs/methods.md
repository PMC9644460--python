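# Methods

## Model

The population is split into people currently experiencing high to very
high psychological distress (the stock *M*, K10 ≥ 22) and everyone else
(*P − M*). Four flows move people in and out of the stock:

* **incidence** *i(t) (P − M)*, with per-capita rate
  *i(t) = i₀ e^{δ_i t}* — a constant fractional trend, so δ_i > 0 means
  rising individual-level risk. Incidence includes first onsets and
  recurrences: people who recover re-enter through this flow if symptoms
  return.
* **mortality** *γ k(t) M*, where *k(t)* is the background per-capita
  death rate and γ ≥ 1 the hazard ratio for the distressed stock. *k* is
  not a free parameter: it is defined by inverting the total-mortality
  identity *k (P − M) + γ k M = D(t)* at the instantaneous state, so the
  model's deaths always sum to the observed-trend total *D(t)*.
* **natural recovery** *s M*, a constant per-capita rate.
* **treatment-dependent recovery** *r(t) C(t)*: *C(t)* patients treated
  per year, of whom a proportion *r(t) = r₀ e^{δ_r t}* recover. Treatment
  volume is exogenous (services run at capacity, so provision does not
  depend on *M*), and so is its growth.

The exogenous drivers are linear in time — *P = P₀ + g t*,
*D = D₀ + h t*, *C = C₀ + u t* — matching the prior specification of the
level/slope pairs as linear-regression estimates. Time is measured in
years with *t = 0* at the start of 2008.

Two guards handle regimes the fitted model never reaches but arbitrary
parameters can: *r(t)* is clipped at 1 (with a warning flag), and if the
state-independent treatment outflow *r C* would overdraw the stock, *M* is
capped at zero and a flag is set.

Assumptions worth stating plainly: a single severity class (no
mild/moderate structure), no direct migration into the stock, incidence
and effectiveness trends that are log-linear over the whole window, and
treatment provision independent of prevalence.

## Observation model

Each record (stream, calendar year, count) is compared with the model at
mid-year, *t = year − 2008 + 0.5*: the population stream is a 30-June
snapshot, and under linear trends the yearly totals of the flow streams
equal their mid-year instantaneous rates. Counts are negative-binomial
with mean equal to the model output and per-stream inverse-scale
dispersion β, in the gamma-Poisson parameterisation with shape β·m and
inverse scale β, so E[y] = m and Var[y] = m (1 + 1/β). Records are
conditionally independent.

For dispersions above α = β·m ≈ 1e12 the log-pmf switches to the Poisson
limit, which is exact to working precision there; the direct gammaln form
loses all accuracy in that regime and, uncorrected, creates a spurious
high-likelihood region that can trap a sampler.

## Priors

The shipped prior set (also in `priors_default.toml`; any entry can be
overridden):

| parameter | prior | rationale |
|---|---|---|
| prev₀ | normal(0.1464, 0.0293) on [0, 1] | midpoint of the 2007 (14.80%) and 2009 (14.48%) survey prevalences; 20% relative sd |
| P₀, g | normal(16167328, 3233466) T[0,∞); normal(308538, 61708) | linear-regression level/slope of adult population, 20% sd |
| D₀, h | normal(136840, 27368) T[0,∞); normal(2228.7, 445.7) | same for total adult deaths |
| C₀, u | normal(305315, 61063) T[0,∞); normal(43696, 8739) | same for patients treated per year |
| γ − 1 | lognormal(−0.7733, 0.4701) | mode γ = 1.37, P(γ > 2) = 0.05, from published distress-mortality hazard ratios |
| i₀ | normal(0, 0.5) T[0,∞) | non-informative |
| δ_i | normal(0, 0.5) | non-informative |
| s | lognormal(−1.1315, 0.2024) | mode 0.31, 95th percentile 0.45 (spontaneous remission of untreated depression) |
| r₀ | normal(0.1845, 0.0369) on [0, 1] | 45% sustained response × 41% minimally adequate care |
| δ_r | normal(0, 0.0125) | symmetric about 0; \|δ_r\| ≲ 3.75%/yr at 3 sd |
| β (each stream) | normal(1, 1) on log₁₀ β | weakly informative: overdispersion factor 1 + 1/β spans near-Poisson to strongly overdispersed |

Truncated normals include their renormalisation constants. The dispersion
priors are a package choice (one β per stream), recorded in the config and
overridable.

## Numerics

**Integration.** `simulate_trajectory` uses adaptive RK45 with rtol 1e-8
and atol 1e-4 persons (the ODE is one-dimensional and non-stiff at
realistic parameters), with fixed-step classical RK4 at dt = 1/365 yr as
the alternative method. The MCMC likelihood path uses the fixed-step RK4
core (numba-compiled) at a weekly step, dt = 1/52: against the daily step
the difference is ~1e-12 relative, roughly nine orders of magnitude below
the observation noise, at a fifth of the cost. *k(t)* is recomputed from
the instantaneous state inside the derivative, never precomputed on a
grid, so the mortality identity holds exactly at every evaluation.

**Reparameterisation.** Sampling happens on an unconstrained scale chosen
per prior support: log for one-sided supports (log(γ − 1) for the hazard
ratio), scaled logit for the two proportions, identity for unbounded
parameters, with the corresponding Jacobian terms in the target density.

**Initialisation.** The joint posterior is extremely anisotropic — the
administrative streams pin their level/slope parameters about four orders
of magnitude tighter than the prior — and samplers started from prior
draws do not find the mass in any useful time. Both backends therefore
start from a deterministic Laplace approximation: a data-informed centre
(least-squares lines through the linear streams, the observed first-survey
prevalence, prior central values elsewhere, and i₀ solved from the
steady-state stock balance at the first survey point), a staged Powell
mode search (dynamics first with dispersions frozen — releasing β too
early lets the optimiser collapse it to zero, where the likelihood goes
flat — then dispersions, then a joint polish), and a finite-difference
Hessian with per-dimension calibrated steps, eigen-regularised so soft or
negative curvature is capped at the prior variance.

**Samplers.** The default backend is emcee's affine-invariant ensemble
with a DE/DE-snooker move mixture (0.8/0.2), which measurably outperforms
the stretch move in split R-hat and ESS on this correlated posterior at
equal cost. `chains` sets the number of walker groups used for the chain
axis (and split R-hat); `iterations` counts ensemble moves, with the
warmup fraction discarded. At the warmup boundary, walkers whose log
density sits more than 30 units below the ensemble median — stragglers
trapped in the negligible-mass β → 0 basin — are re-seated on cloned good
positions before the retained phase. The alternative backend is a
Haario-style adaptive random-walk Metropolis (scale tuned toward 23.4%
acceptance and covariance blended with the warmup history, both frozen
after warmup). Defaults mirror the study configuration: 4 chains, 4000
iterations, first half discarded. One master seed drives everything;
per-chain and per-stage seeds are derived deterministically.

**Diagnostics.** Rank-normalised split R-hat and bulk ESS per parameter
(arviz); any R-hat above 1.01 flags the run without failing it. Pinned
parameters report NaN.

## Analyses

**Counterfactual.** Every selected posterior draw is re-simulated with
δ_i := 0, all other components unchanged. The headline quantity is the
counterfactual prevalence at the start of 2008 minus at the end of 2019
(t = 0 minus t = 12; "2019" means end-of-year so the reference period
spans the full window — configurable). Persons averted multiply this
difference by that draw's P(t = 12); the relative reduction divides it by
the draw's 2008 prevalence. Because the phrase "decreased between 2008 and
2019" admits a second reading, the factual-minus-counterfactual difference
at t = 12 is computed and reported alongside. Summaries are posterior
medians with equal-tailed 50% and 95% credible intervals; bands and
counterfactuals default to 1000 draws.

**Constrained fits** pin δ_i = 0 or δ_r = 0 (excluded from sampling,
present verbatim in every stored draw) and are compared through
posterior-mean per-stream log-likelihoods.

**Posterior predictive checks** use the χ² discrepancy
T(y) = Σ (y − m)²/Var with the negative-binomial variance m (1 + 1/β)
(Pearson's m selectable); the Bayesian p-value is the fraction of draws
with T(y_rep) ≥ T(y), flagged outside (0.05, 0.95).

## Synthetic data

The generator simulates the model under a documented ground truth and
draws gamma-Poisson counts at the real observation design: six biennial
survey years (2009–2019) and twelve yearly records per administrative
stream (2008–2019). The default truth takes the prior central values for
every parameter that has one, and for the rest encodes the study's
qualitative regime: i₀ = 0.06/yr and δ_i = 0.02/yr hold prevalence near
0.146 while risk rises and treatment volume grows; δ_r = 0. Dispersions
are β = 400 for the survey stream and β = 1e5 for the administrative
streams, making the latter near-deterministic.

What the generator does **not** emulate: survey design effects (weights,
clustering, attrition), reporting-propensity drift in the K10, migration
age structure, or any model misspecification. Passing recovery tests
therefore show that the inference machinery is correct and well calibrated
*under the model's own assumptions* — they say nothing about whether those
assumptions hold for real survey data.

A consequence of the generator-plus-prior combination worth knowing: with
administrative β = 1e5, the likelihood is flat in β above ~100, so the
posterior for those dispersions is prior-dominated and their credible
intervals sit far below the generating value. The dynamic parameters —
the vector θ of the model proper — are recovered with close-to-nominal
coverage; the recovery study tracks exactly those 13 components.

## Problem sizes used in the shipped checks

The test suite and `scripts/acceptance.py` run reduced configurations
chosen for desk-scale runs: recovery studies use 4 × 1000-move ensemble
fits over 20 (suite) or 10 (script) replications; the single full analysis
in the script uses 4 × 2000 moves; counterfactual and predictive checks
use 400–1000 draws. The Euler oracle integrates at dt = 1e-4 yr.

## Known limitations

* Point identifiability is weak by design: six survey points inform seven
  shape parameters, so several posteriors (γ, s, r₀, δ_r) remain
  prior-dominated; conclusions about δ_i are the robust output.
* The ensemble "chains" are walker groups of one interacting ensemble,
  so split R-hat is slightly optimistic relative to independent chains;
  the adaptive-Metropolis backend provides truly independent chains when
  that matters.
* The Laplace initialisation assumes the mode found by the staged search
  is the dominant one. For the synthetic regime this is reliably so; for
  grossly misspecified data the β → 0 heavy-tail basin could in principle
  dominate, which the stuck-walker guard mitigates but does not prove
  away.
* Counts are treated as exactly negative-binomial; real survey estimates
  carry design-based error that this family only approximates.
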