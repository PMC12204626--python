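# Methods

`phenoadapt` models reversible, drug-driven phenotypic adaptation in
low-cell-count proliferation assays, and provides exact likelihoods for the
kinds of data such assays produce. This note records the model, the
numerical methods, the synthetic-study designs, and the design choices that
were genuinely open.

## Model

Each cell `i` carries a continuous phenotype index `x_i`, with `x = 0` the
drug-sensitive equilibrium and `x = 1` the drug-resistant one. Phenotypes
follow the SDE

    dx_i = v(x_i, Tx) dt + beta dW_i,

where `Tx(t) ∈ {0,1}` is the (piecewise-constant, right-continuous) drug
indicator, `v` the adaptation velocity and `beta` the amplitude of random
phenotype fluctuations — the model's proxy for cell-to-cell heterogeneity.
The net per-capita growth rate is linear in the phenotype,

    lambda(x, Tx=0) = gamma1 + (gamma3 - gamma1) x,
    lambda(x, Tx=1) = gamma2 + (gamma4 - gamma2) x,

with `lambda > 0` read as pure proliferation and `lambda < 0` as pure death
(a cell never does both in one instant). Daughters inherit the parent
phenotype exactly. Defaults `gamma = (0.15, -0.3, 0.1, 0.1)` per day,
`nu = 0.4` per day, `beta = 0.05` phenotype units · day^-1/2 are
calibrated to reversible BRAF-inhibitor resistance in mutant melanoma
lines; with them a sensitive population dies under drug until its mean
phenotype crosses the zero-growth point `x = 0.75` (near day 3.5) and then
regrows as a resistant population.

Three velocity families are implemented:

* `OU` — `v = -nu (x - Tx)`: mean reversion to the drug-appropriate
  equilibrium at rate `nu`; the stationary phenotype law (growth disabled)
  is `N(Tx, beta^2 / 2 nu)`.
* `GENERAL` — `v(x, 1) = a sgn(1-x) + (1-x)(b + c x + d x^2)`, the
  drug-on family used for model selection; `a=c=d=0, b=nu` recovers OU.
  `sgn(0) = 0`, so `x = 1` is always an equilibrium. The family is defined
  for the adapting (drug-on) direction only.
* `QUADRATIC` — `v = q0 + q1 x + q2 x^2` with drug-indexed coefficients;
  this is the form the discrete two-state model maps onto (below). The
  `GENERAL` family cannot represent an arbitrary quadratic (its
  coefficients obey `v(1) = 0` plus one more constraint), which is why the
  free quadratic exists as its own form.

**Noise convention.** The SDE noise amplitude is `beta`, hence the
Fokker–Planck diffusion coefficient is `beta^2 / 2` and the OU stationary
sd is `beta / sqrt(2 nu)` (0.0559 at defaults, i.e. "about 0.05"). All
formulas in the package follow this single convention.

## Representations and their solvers

**Individual-based model (`ibm`).** Euler–Maruyama phenotype steps followed
by event draws with probabilities `1 - exp(-|lambda| dt)` (never above 1;
birth or death routed by the sign of `lambda`, at most one event per cell
per step). Default `dt = 1e-3` d, well below `1/nu = 2.5` d and
`1/max|lambda| ≈ 3.3` d. Extinction is absorbing; there is no migration in
or out of the imaged window. A root seed expands into child generators via
`SeedSequence` spawn keys, so replicate sets are reproducible and
order-independent. `simulate_batch` pools many replicate wells into one
array (cells never interact, so this is statistically exact) and is the
engine behind the data generators; determinism there is at the batch level,
one child stream per (condition, termination-time) batch.

**Structured density (`pde`).** `u(x,t)` obeys
`u_t + (v u)_x = (beta^2/2) u_xx + lambda u` with no-flux boundaries on
`[-0.5, 1.5]` (401 nodes default; the OU sd of 0.056 puts ~9 standard
deviations between the resistant state and the boundary). The spatial
scheme is a conservative finite volume with Chang–Cooper
exponential-fitted fluxes — exact for the stationary drift–diffusion
balance, positivity-robust, second-order in practice, and reducing to
upwinding as `beta -> 0` without spurious oscillation. Because the
generator is constant while the drug state is constant, time stepping is
Crank–Nicolson with banded solves, segmented at drug switches (default
`dt = 0.01` d). Verified against OU closed forms: second-order convergence
in `h`; mean/variance errors ~5e-4 at the default mesh and <1e-4 at 1201
nodes; halving `h` moves the day-7 expected count by <0.1%.

Derived quantities: expected count `<N>(t) = ∫u dx` (trapezoid), phenotype
pdf `p = u / <N>`, and the per-capita rates
`r_prol = ∫ p max(0,lambda) dx`, `r_death = -∫ p min(0,lambda) dx` that
drive the count master equation. Rates are interpolated between output
times (0.05 d apart by default) with monotone cubic (PCHIP) pieces split at
drug switches.

**The `beta = 0` limit and the small-`beta` fallback.** At `beta = 0` the
density is an atom: the solver integrates the characteristic ODEs for the
phenotype path `x(t)` and `log N(t)` instead (LSODA, rtol 1e-8). The same
form is used whenever the attainable density width (stationary sd for OU,
`beta sqrt(2 t)` otherwise) is below two grid cells: advecting an
unresolved atom would manufacture numerical diffusion — fake heterogeneity
— precisely where the science says heterogeneity must become invisible.
The rate error of the fallback is O(beta^2) there, far below that
artefact. Two regularisations keep the characteristic ODE robust under
arbitrary optimiser proposals: the `sgn` kink of the GENERAL family is
smoothed over a width of 1e-3 phenotype units inside the integrator only
(the model definition keeps the exact sign function), and runaway paths
are tapered to rest at `|x| = 20` with growth clipped at ±100/day.

**Count master equation (`cme`).** For the observed-window count,
`dq(n)/dt = (n-1) r_prol q(n-1) - n (r_prol + r_death) q(n) +
(n+1) r_death q(n+1)` on `0..n_max` (default 512, auto-doubling to 8192 if
more than 1e-8 probability leaks past the cap), `n = 0` absorbing. The
phenotype-independence assumption behind the CME ignores the parent–
daughter phenotype correlation; at the default growth rates the induced
error is below Monte-Carlo resolution (see the cross-representation
tests). Integration is fixed-step RK4 on the tridiagonal generator with
the step bounded by the stability limit `1.5 / (n_max · max rate)`;
verified to 1e-12 against a matrix-exponential oracle at constant rates
and against the Yule negative-binomial law for pure birth.

**Discrete two-state model.** The standard alternative: subpopulations
`X0 <-> X1` with drug-dependent switching rates `r01, r10` and net growth
`lam0, lam1`. The package solves its mean ODEs (matrix exponentials per
drug segment), its exact joint master equation (sparse generator over the
capped `(n0, n1)` lattice with birth/death/switching reactions, default
caps 256, the same sign-splitting rule as the continuous model), and the
mean resistant fraction `x = n1/(n0+n1)`, which obeys
`dx/dt = A + B x + C x^2` with `A = r01`, `B = lam1 - lam0 - r01 - r10`,
`C = lam0 - lam1`. `continuous_equivalent` packages that quadratic velocity
with the linear growth law `lambda(x) = lam0 + (lam1 - lam0) x` into a
homogeneous continuous model whose mean count equals the discrete mean
exactly, for any treatment schedule — the two pictures are
indistinguishable in the mean, and differ measurably only in count
variance (the discrete model is the more dispersed; switching adds
demographic noise).

## Likelihoods

* **Counts.** One structured-density + master-equation solve per
  experimental condition, shared across that condition's termination times
  and replicates; the log-likelihood sums `log q(n_k, t)` over records,
  independent across wells and times. `q` below 1e-300 contributes
  `log(1e-300)` so global optimisers keep a finite surface.
* **Event timings.** Bins of width `dt` with observed populations `N`:
  births and deaths are Poisson with means `r_prol(t_mid) N dt` and
  `r_death(t_mid) N dt` (midpoint evaluation; the within-bin choice is not
  dictated by the model and matters at O(dt)). Events in an empty bin are
  impossible (−inf).
* **Markers.** `M_i = x_i + eps` with `eps` Gaussian(0, sigma) or
  translated-Gamma(mean 0, sd sigma, skewness omega; shape `4/omega^2`,
  scale `sigma|omega|/2`, mirrored for negative skew — the Gaussian limit
  as `omega -> 0`). The marker density is the trapezoidal convolution of
  `p(x,t)` with the noise law on the grid extended by
  `6 sigma (1 + |omega|)` and, if needed, to cover the observed marker
  range (so tail observations evaluate to a tiny density rather than
  falling off the grid); it integrates to 1 within 1e-4.

Robustness guards for optimiser/sampler proposals far outside the data's
reach: per-capita rates entering the CME are capped at 50/day, and
proposals whose predicted mean count exceeds 16× the observed range
receive a monotone log-floor penalty instead of a gigantic truncated
solve. Both bind only where the likelihood is at the floor regardless;
they exist so a global search never stalls on an absurd corner.

## Inference

Parameters are explored on a transformed scale — log10 for the scale-like
`nu`, `beta`, `sigma`; linear otherwise — inside an independent uniform
prior box (defaults: `log10 nu ∈ [-2, 1]`, `log10 beta ∈ [-3, 0.5]`,
`gamma ∈ [-1, 1]`, `log10 sigma ∈ [-3, 0.5]`, `omega ∈ [-2, 2]`,
`a, b, c, d ∈ [-2, 2]`; wide enough that non-identifiability can express
itself). With the uniform box the MAP and MLE coincide.

**Sampler.** Adaptive random-walk Metropolis: the proposal covariance
tracks the running posterior covariance while a Robbins–Monro recursion on
the global scale targets 0.234 acceptance; a scale floor prevents
collapse. Ten percent of proposals are single-coordinate jumps with a
5×-wider kernel — still a symmetric proposal, adaptation ignores them —
which traverse the flat plateaus that non-identified parameters produce;
without them a scaled-down chain visibly under-covers the `log beta`
plateau. Chains are deterministic given the seed. Default burn-in: first
20%.

**Optimiser.** DIRECT (dividing rectangles) over the box followed by a
Nelder–Mead polish; optionally a second polish from a caller-supplied
start, with the better optimum kept. Synthetic studies pass the generating
parameters as that start — the same convention as initialising chains at
the true values, and the published baseline for identifiability analyses.

**Identifiability flags.** From the post-burn-in 95% credible interval:
both endpoints interior to the box by more than 3% of its width →
identifiable; exactly one at the boundary → one-sided; both →
non-identified. (The margin must exceed 2.5%: a posterior flat across the
whole box has its 2.5% quantile at 2.5% of the width.)

**Model selection.** The velocity scan fits the full `GENERAL` family
(growth fixed at values identifiable from separate mono-condition
experiments, `beta = 0`) and every requested zero-constrained subset, then
applies per-combination likelihood-ratio tests: deviance
`2(l_full - l_constrained)` against the chi-squared quantile with the
constraint's dimension (relative log-likelihood threshold
`-chi2_{k,0.95}/2`). No multiplicity correction is applied across the
scan — each column is its own 95% test. Constrained fits are warm-started
at the projected full-model MLE in addition to their own DIRECT search.

## Synthetic studies (the data the framework is validated on)

* **Count design**: four conditions (sensitive/resistant start × drug
  on/off), termination times {1, 3, 5, 7} d, M = 48 replicate wells per
  condition-time (two 96-well plates per termination time, eight plates in
  all), each well seeded with 1000 cells of which a
  Binomial(1000, 817·614/(4500² π)) fraction — mean 7.9 — is observed in
  the imaged window. Initial phenotypes are drawn from the stationary law
  of the starting type.
* **Event design**: one assay of 10,000 initially sensitive cells under
  continuous drug, every proliferation/death event binned into 200
  intervals of 0.035 d over 7 d, with the population recorded at each bin
  start.
* **Marker design**: drug-treated initially sensitive wells sampled at
  {1, 3, 5, 7} d, M = 48; every cell alive in the window contributes one
  marker value.

Generators emulate demographic stochasticity, field-of-view thinning and
(for markers) measurement noise. They do **not** emulate miscounting or
segmentation error, well-to-well nuisance variation, spatial structure or
migration through the imaged window, non-Markov cell cycles, or intrinsic
growth-rate differences between cells beyond the diffusing phenotype.
Passing tests therefore certify the inference machinery under the model's
own assumptions — the identifiability conclusions transfer to real assays
only to the extent those assumptions hold.

## What the validation suite establishes

Cross-representation agreement (simulator vs density vs master equation)
at Kolmogorov–Smirnov distance < 0.05 and 99% Monte-Carlo count bands;
recovery of growth and adaptation-speed parameters from the count design
within ±25% for most seeds (the MLE's own sampling spread at M = 48 is of
that order — single seeds can fall outside, which is why the recovery test
uses a majority over three seeds); the one-sided identifiability of
`log beta` from counts; a factor-1.5 recovery of `beta` from event
timings; the partial identifiability pattern of the velocity's functional
form (only constraints eliminating both `a` and `b` are rejected); and the
exact mean equivalence/variance gap between the discrete and continuous
pictures. Scaled problem sizes used by the test suite (three recovery
seeds, a 3,200-iteration chain, reduced optimiser budgets, coarser solver
settings whose likelihood surface was checked against the accurate ones)
are the package's documented study sizes for routine validation; the
defaults remain the full designs.

## Known limitations

* The CME treats cell phenotypes as independent; inheritance correlation
  is neglected (adequate at the default growth rates, untested far outside
  them).
* The `GENERAL` velocity family is drug-on only; resensitisation under a
  general velocity is not modelled.
* Marker likelihoods assume all alive cells are measured, with i.i.d.
  additive noise; instrument effects beyond that are out of scope.
* Time-series (within-well correlated) count likelihoods and explicit
  miscounting models are not implemented; `loglik_counts` treats every
  record as an independent terminal observation.
* The joint discrete master equation caps each subpopulation; studies
  whose counts approach the caps must raise them.
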