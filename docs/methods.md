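# Methods

## Model and assumptions

`acsidm` implements the extended illness-death model for an
irreversible chronic disease: non-diseased (1) and diseased (2) living
states, with death split by prior disease status into dead without
disease (3) and dead with disease (4). The transition hazards depend on
a single time scale *t*, interpreted as age in a birth cohort; there is
no separate calendar-time dimension, no recovery, no covariates, and no
misclassification of the state recorded at a cross-section (a subject
dead at age 20 is still correctly counted among the dead 80 years
later).

The hazards are parametric: a hinge-linear incidence
*i*(*t*) = θ₂·max(0, *t*−θ₁), which is a coarse but serviceable shape for
adult-onset diseases such as type 2 diabetes, and two Gompertz
mortalities *m*₀(*t*) = exp(θ₃+θ₄*t*), *m*₁(*t*) = exp(θ₅+θ₆*t*), the
standard adult-mortality law. The functional forms are treated as
known; only the six numeric parameters are estimated.

Because subjects are independent and each is observed exactly once, the
count vector at monitoring age *t*ₖ is Multinomial(*N*ₖ, *p*(*t*ₖ)) with
*p* solving the generator ODE. This single fact underpins everything:
it justifies the likelihood, makes the ODE solution the exact
distributional oracle for the micro-simulator, and implies that the
sampling distribution of any estimator is fully determined by
(θ, *N*, monitoring design) — not by details of the simulation
algorithm.

## Key parameters and defaults

| quantity | default | unit | rationale |
|---|---|---|---|
| reference θ | (30, 1/2000, −10.7, 0.1, −10, 0.1) | years, 1/year², —, 1/year, —, 1/year | diabetes-like study conditions of the packaged experiment |
| population size N | 10,000 | subjects | reference study scale |
| monitoring ages | 0, 10, …, 100 | years | eleven cross-sections spanning the life course |
| RK4 step h | 0.1 | years | integer monitoring ages stay exactly on the grid; global error ~1e-10, far below sampling noise |
| Nelder–Mead budget | 5,000 iterations, 1 restart | — | ample for a smooth 6-dim objective; restart guards against simplex collapse |
| likelihood floor ε | 1e-12 | — | keeps ℓ finite when a positive count meets a vanishing modelled probability early in optimization |
| log-hazard cap | 50 | — | exp(50)/year is unphysical; beyond it a range error is raised rather than returning infinity |

Allocation of subjects to cross-sections is iid uniform (multinomial
totals, not a forced equal split), matching the independence premise of
the likelihood.

## Numerical choices

* **ODE solve.** Fixed-step classical RK4; deterministic, and
  monitoring times must be grid nodes — off-grid queries raise instead
  of interpolating. Probabilities are not clipped: if a component
  leaves [−1e−6, 1+1e−6] (or turns non-finite), a
  `NumericalInstabilityError` points at the step size. With h = 0.1 the
  scheme is stable for hazards up to ~28/year; a Gompertz slope θ₄ ≳
  0.14 pushes the age-100 hazard beyond that, and the solver refuses
  loudly rather than returning garbage. Inside the optimizer this
  error maps to a large penalty so the simplex retreats.
* **Cumulative hazards.** Both families have closed forms, written in
  `expm1`/`log1p` style so they stay accurate down to (sub)normal
  Gompertz slopes; inverse-transform sampling therefore needs no
  root-finding. Bisection and quadrature oracles validate both in the
  test suite.
* **Competing risks.** Independent latent times for onset and
  death-without-disease, earlier event wins (ties, a null event, break
  toward death). This construction induces exactly the cause-specific
  hazards *i* and *m*₀; agreement with the ODE law is verified by
  chi-square at N = 50,000.
* **Optimization.** Nelder–Mead on (θ₁, log θ₂, θ₃…θ₆); the log keeps
  the incidence slope positive without constraints. Scipy's absolute
  `fatol` is set to 1e−10·(1+|f(start)|) to emulate a relative
  tolerance. Derivative-based optimizers are avoided since the
  objective is defined through an ODE solve. Degenerate inputs:
  empty cross-sections are skipped by both objectives; zero counts
  contribute nothing to ℓ regardless of the modelled probability.
* **Starting values.** The data-driven default sets θ₁ one
  inter-monitoring interval before the first cross-section with any
  diseased subjects, θ₂ = 1e−4, θ₃ = θ₅ = −9, θ₄ = θ₆ = 0.08. The
  recovery experiment can instead start from the true vector perturbed
  by ±20% per coordinate, the convention used in its error-bound
  checks.

## What the simulator emulates — and what it does not

The generator reproduces the reference feasibility conditions: a closed
birth cohort, exact parametric hazards, perfectly classified states,
and one observation per subject. Real ACS data add survey weights,
two time scales (age × calendar time), state misclassification —
especially of disease status at death — and informative non-response.
Passing tests therefore demonstrate that the estimation machinery
recovers parameters when the model is correctly specified; they say
nothing about robustness to those real-data features, all of which are
out of scope here.

## Sampling variability of the recovery errors

The packaged reference table is one realization. Because the counts
are exactly multinomial, the distribution of the recovery error is
intrinsic; rerunning the experiment over many seeds at N = 10,000 shows
a median maximum relative error (across the six parameters) of about
6% for maximum likelihood (roughly a fifth of seeds land below 4%, ~87%
below 10%) and about 9% for least squares (~40% of seeds exceed 10%,
driven by θ₅/θ₆). The reference realization, at 3.3% for ML, sits in
the favourable tail. Maximum likelihood is consistently the more
efficient of the two, as expected from its full use of the
distributional assumption. A related observation: on the reference
table the fully-converged least-squares optimum has a *lower* residual
than parameter vectors with uniformly small recovery errors — at this
noise level the LS surface genuinely prefers a θ₆ about 15% off, so
looser optimizer settings can accidentally *look* more accurate.

## Known limitations

* No confidence intervals or standard errors (Fisher-information
  inversion and resampling are natural extensions but are not
  implemented).
* Only the hinge-linear + double-Gompertz rate family; no splines or
  alternative parametric families, and no model selection.
* Single time scale; the age × calendar-time generalization (a PDE
  reducible to ODEs along characteristics) is out of scope.
* The scalar prevalence ODE π′ = (1−π)[i − π(m₁−m₀)] is provided as a
  consistency check of the four-state solution, not as an estimation
  route: simple prevalence alone cannot identify all three rates.
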