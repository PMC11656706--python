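# Methods

## The model family

`gutspulse` implements a family of GUTS (General Unified Threshold model of
Survival) stochastic-death models for zebrafish-embryo toxicity data in
which the abstract toxicodynamic damage state is proxied by the measured
*nrf2* fold-change. The full model, `guts_rna_pulse`, couples four states
per treatment (exposure is constant unless a piecewise profile is given;
the model clock is hours post exposure, with exposure starting at 24 hpf):

```
dC_i/dt = k_i C_e − k_m P* C_i                     internal concentration
dR/dt   = r_rt a(C_i/C_i,max) − k_rd max(0, R−R_0)  nrf2 fold-change
dP*/dt  = k_p (R − P*)                              scaled protein proxy
dH/dt   = k_k max(0, R − z) + h_b                   cumulative hazard
S(t)    = exp(−H(t))                                survival probability
```

with `a(c) = 1/(1+exp(−v_rt (c − z_ci)))`, a logistic threshold activation
on the scaled internal concentration. Any sigmoid mapping to (0, 1) is
admissible; the logistic form is the simplest that is 0.5 exactly at the
threshold, monotone in the concentration and steepening in `v_rt`.

Structural choices worth making explicit:

- **No passive elimination.** Removal of the chemical happens only through
  the protein-mediated bilinear term `k_m P* C_i` (the low-substrate limit
  of Michaelis–Menten kinetics). With `k_m = 0` the internal concentration
  grows linearly under constant exposure — this is used as a solver oracle.
- **RNA floor.** Decay acts only on the excess over the baseline
  (`max(0, R − R_0)`), so with `R(0) = R_0` the fold-change never drops
  below baseline without needing a discrete event. `R_0 = 1` makes the
  state identical to the measured fold-change.
- **Protein proxy.** `P*` is a first-order tracker of `R` with a single
  dominant rate constant `k_p`; it is scaled (fold-change-equivalent), not
  an absolute protein concentration, because no protein measurements enter
  the fit. Its slow turnover relative to RNA decay is what lets
  metabolization persist after the expression pulse has subsided.
- **Hazard driver.** The hazard reads the *nrf2* state `R` itself (not
  `P*`): the non-monotone fold-change is the damage proxy.
- **Initial conditions.** `C_i = 0`, `R = P* = R_0`, `H = 0` — the
  untreated baseline equilibrium of all three differential equations.
- **Scaling constant.** `C_i,max` is a fixed constant of the model, not a
  fitted parameter. When fitting external data it is the maximum observed
  internal concentration (`compute_scaling`); the synthetic generator
  instead calibrates it to the deterministic model's own maximum by
  fixed-point iteration (`calibrate_scaling`) and stores it with the
  ground truth, since noise-free "observations" are not available before
  the noise is drawn.

Three standard comparison variants are provided as one-compartment
GUTS-SD reconstructions (`guts_reduced`: damage driven by the external
concentration, survival only; `guts_scaled_damage`: internal concentration
plus damage; `guts_rna`: the *nrf2* fold-change as a linear damage state
with baseline 1). Their exact published supplementary forms were not
available to this implementation; the reconstructions match the standard
GUTS literature and the published per-variant parameter counts (4, 6, 7
deterministic parameters; the pulse model has 10).

## Error models and the joint likelihood

Internal concentrations and fold-changes are strictly positive and carry
log-normal errors whose **median** is the deterministic prediction, with
endpoint-global log-scale standard deviations `sigma_cint`, `sigma_nrf2`
(shared across substances). Survivor counts follow a conditional-binomial
chain: survivors at each observation time are binomial given the survivors
at the previous observation with probability `S(t)/S(t_prev)`. This is
algebraically identical to the multinomial death-interval likelihood (the
test suite verifies the identity exhaustively for groups of up to 4
organisms), and conditioning on the *observed* previous count is the
appropriate likelihood for small groups observed repeatedly.

Records are independent given the trajectory, so the joint log-likelihood
over a fragmented multi-endpoint table is a plain sum; grid cells without
an observation contribute nothing. Survival ratios are floored at 1e−12
(and capped at 1) before the binomial pmf because adaptive solvers can
return `S` marginally above its previous value; clips are counted and
surfaced in diagnostics.

BIC is `k ln n − 2 ln L̂` with `n` the total number of observations in the
fitted table and `k` the number of fitted free parameters. Deterministic
parameter counts follow the sharing map (`shared + n_substances ×
specific`); the two error sigmas are always shared and are reported on top
of the deterministic count, matching the convention of quoting model sizes
"excluding error parameters".

## Parameter sharing

The default sharing map for the pulse model marks the uptake,
metabolization and activation-threshold parameters (`k_i`, `k_m`, `z_ci`)
substance-specific and shares the RNA–protein and death-module parameters
(`v_rt`, `r_rt`, `k_rd`, `k_p`, `z`, `k_k`, `h_b`) across substances: for
three substances 7 + 3×3 = 16 deterministic parameters versus 3×10 = 30
for the fully substance-specific model. Note that in an unscaled
activation `v_rt` would be substance-dependent; sharing it is only
meaningful with the scaled activation used here.

## Priors, initialization and engines

Every free parameter gets a log-normal prior with log-sd 2 (weakly
informative) centered on a biologically anchored median: notably `k_rd` at
2 h⁻¹ (RNA half-life ≈ 20 min) and `k_p` at 0.03 h⁻¹ (protein half-life
≈ 23 h); uptake/metabolization anchors are round order-of-magnitude values
for µM-range exposures. All anchors are overridable per fit.

Multi-start initialization draws `u ~ U(−1, 1)` per parameter and maps it
to `median · exp(u · log_sd)`. This bounded initializer spans the central
prior mass but is *not* a prior draw (the push-forward is a bounded
distribution; a test checks it differs from the prior). Each start is
optimized with L-BFGS-B on the log scale against the negative
log-posterior; per-start losses and endpoints are retained — the endpoint
cloud in standardized log-parameter space is the input of the
density-based (DBSCAN, default radius 0.5) posterior-cluster
identifiability diagnostic. Dimensions whose endpoint spread is below
1e−3 log units are treated as constant rather than rescaled, so a single
converged mode is reported as one cluster.

Two posterior engines share one interface:

- `variational` — a Gaussian approximation at the best mode with
  inverse-Hessian covariance (finite-difference Hessian,
  eigenvalue-floored to be positive definite), sampled for draws. It is
  fast and adequate for well-identified, near-Gaussian posteriors.
- `mcmc` — affine-invariant ensemble sampling (emcee), with the ensemble
  initialized from the mode's Gaussian approximation so that flat
  posterior directions are overdispersed from the first step.

The Gaussian engine systematically under-represents curved, weakly
identified ridges — in this model family most prominently the
`r_rt`–`k_rd` direction, where only the pulse equilibrium
`R_0 + r_rt a/k_rd` is well determined. The recovery experiment therefore
defaults to the MCMC engine. Credible envelopes of trajectories
(`posterior_trajectory_bci`) are pointwise quantiles of deterministic
solutions over posterior draws; residual observation error is deliberately
excluded, so they quantify parametric uncertainty only.

## Numerics

Two solver paths exist with a cross-checking test:

- `simulate`: adaptive, stiff-capable LSODA with dense output
  (rtol 1e−7 / atol 1e−9 by default), segment restarts at breakpoints of
  piecewise-constant exposure profiles, and a ×10 tolerance-refinement
  convergence contract of 1e−6 relative. The cumulative hazard is carried
  as an extra state rather than integrated post hoc, so survival inherits
  the solver's accuracy.
- the likelihood path: a numba-compiled fixed-step RK4 that integrates all
  treatments of a substance in one call. The base step (0.05 h for
  one-shot evaluations, 0.1 h inside fits, 0.02 h when generating ground
  truth) is additionally bounded by the fastest first-order rate in the
  parameter set for RK4 stability; parameter regions that would need an
  unreasonable number of steps, or that overflow, return NaN and are
  treated as infeasible (log-likelihood −∞, a large finite penalty inside
  the optimizer). At the default steps the two paths agree to ~1e−5
  relative, far below the observation noise.

## What the synthetic generator emulates — and what it does not

The generator mirrors the structure of the underlying exposure study:
three substances in serial dilution over a 96 h window, internal
concentrations sampled at 1.5–96 h post exposure (13 times), survival
observed at 24/48/72/96 h on triplicate treatments of 3 organisms (6
replicate controls), *nrf2* fold-change on its own grid, strongly
unbalanced endpoint totals, and — the structurally hard property — no
treatment ever carries more than one endpoint, so the joint likelihood
must stitch fragmented fragments together. The `paper_scale` preset
reproduces the published bookkeeping exactly: 202 treatments × 23 distinct
times × 3 endpoints, 941 realized observations (539 internal
concentration, 169 *nrf2*, 233 survival), hence 12,997 missing cells. The
*nrf2* sampling grid is not printed in the source study; the preset uses
10 *nrf2* times disjoint from the concentration grid so the distinct-time
union is 23.

Ground-truth parameters are the prior anchors (a deliberately
"plausible" organism); substances differ in `k_i`, `k_m`, `z_ci` (factors
1.0/0.6/1.6). For *substance-specific* truths the RNA/death block also
varies, and the variation is chosen to move identifiable quantities —
pulse height and hazard response — not just transient speeds, because a
truth that differs only in directions the data cannot see is
operationally a shared truth. Observation noise: sigma 0.1 (toy), 0.15
(multi-substance toy), 0.25 (paper scale).

What the generator does **not** emulate: experiment/batch-level error
layers (the data are exchangeable given the treatment), microarray batch
effects, time-varying baselines in the developing embryo, measured
external-concentration time series (exposure is nominal-constant), and
organism growth. Passing recovery tests on these data therefore
demonstrate the correctness and internal calibration of the machinery
under the model's own assumptions — not robustness to the nested error
structure of real laboratory data.

## Benchmark experiment sizes

The recovery experiment refits 20 fresh-noise replicates of the toy design
(1 substance, 4 concentrations, ~100 observations, 12 free parameters)
with 4 multistarts and 600 retained MCMC draws per fit; the BIC comparison
uses the 3-substance toy (57 treatments, 333 observations) with 3
multistarts per fit. These sizes keep a full run in the minutes range on a
single CPU while leaving the checks informative. The survival arm of the
multi-substance toy (12 treatments per substance) is deliberately the
largest arm: the sharing comparison draws most of its discriminating power
from survival, and the underlying study allocates its treatments the same
way (62 of 202 to survival). With a much smaller survival arm the
specific-vs-shared likelihood gap falls below the BIC penalty of 14
parameters and the comparison becomes undecidable.

## Known limitations

- The Gaussian ("variational") engine is a mode-based approximation; its
  intervals under-cover on curved ridges (use `engine="mcmc"` when
  interval calibration matters).
- Complete pooling only: no hierarchical/partial-pooling error structure
  across experiments.
- The comparison-variant ODE bodies are reconstructions (see above), and
  the full protein-dynamics extension (for use when protein measurements
  exist) is not implemented.
- `ExposureScenario` supports piecewise-constant exposure profiles in
  `simulate`, but the batched likelihood path assumes constant exposure
  per treatment (renewal), matching the study design.
- BIC comparisons require identical observation tables (enforced via a
  data fingerprint); `n` is the total observation count of the fitted
  subset, so models fitted to different endpoint subsets are not
  comparable.
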