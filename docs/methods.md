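# Methods

## Problem

Given a short, noisy, oscillatory multivariate record — the motivating case
is the classic hare–lynx abundance series, 91 yearly observations of two
species — estimate a deterministic dynamical model du/dt = F(u; θ) whose
trajectory matches the data, and quantify confidence in the fit and in
forecasts beyond the observed window. The package implements the complete
workflow: data smoothing, fitting through a differential-equation solver,
approximate-posterior sampling, and posterior predictive trajectory
ensembles.

## Model families

Both families define a smooth field on n state variables. The first
`n_obs` variables are observed; the remaining n − n_obs are *dummy*
variables, unobserved factors that lift the trajectory geometry into a
higher-dimensional phase space (a two-dimensional model cannot fit data
whose true dynamics trace paths in three dimensions).

- **ODE family**: du/dt = f(S u − b), with S an n×n matrix and b an
  n-vector: n² + n parameters. f is an elementwise activation, tanh by
  default (zero-centered, signed output, steep gradient near zero).
- **NODE family** (neural ODE): du/dt = W₂ f(W₁ u + b₁) + b₂, a two-layer
  network with N hidden nodes and a linear output layer:
  (n + 1)N + n(N + 1) parameters. With the default N = 20 this gives 102,
  143, 184 parameters for n = 2, 3, 4.

Initial conditions: the observed dimensions start at the smoothed data's
first value; dummy dimensions draw Uniform(−1, 1) starts (seeded) — the
working scale is log-centered, so data live within roughly one log unit of
zero. Treating the dummy starts as free parameters is supported
(`optimize_u0_dummy`-style workflows) but off by default; in practice it
buys little.

## Preprocessing

Deterministic models track trends, not noise, and optimizers want a smooth
loss surface, so the raw counts are transformed before fitting:

1. natural log, then per-variable mean subtraction (means stored so
   trajectories can be mapped back to abundances);
2. midpoint augmentation: one interpolated point between each pair of
   observations, from a natural cubic spline fitted per variable on the
   log-centered scale; T points become 2T − 1 (91 → 181);
3. Gaussian filtering on the augmented grid.

Choices that were genuinely open, and how they were fixed:

- **Spline boundary condition**: natural (zero second derivative). Only
  midpoints are consumed, and away from the ends the natural spline
  reproduces smooth signals to high accuracy; the tests exclude the
  boundary-affected points when checking against an exactly-cubic signal.
- **Filter boundary handling**: the truncated kernel (radius ⌈4σ⌉) is
  renormalized over its in-range support. No padding values are invented,
  and a constant series passes through exactly.
- **Filter width**: σ = 1.0 augmented-grid units (half a year on the
  standard grid) by default, exposed as a knob. Large enough to suppress
  point-to-point wiggle, small enough that a decade-period cycle loses
  only a few percent of its amplitude.
- **Order of operations**: transform first, then interpolate and smooth.
- Non-uniform input grids are allowed; midpoints sit at the arithmetic
  mean of adjacent times.

## Loss and gradients

The loss is the plain weighted quadratic deviation summed over target
times and **observed** dimensions only (dummy dimensions are never
compared to data). On the standard two-species, 181-point grid a loss
evaluation therefore compares 362 trajectory points, each requiring the
numerical solver.

Gradients are exact up to solver tolerance, obtained by **continuous
forward sensitivity analysis**: the state is augmented with the
sensitivity matrix dU/dθ, which satisfies a linear matrix ODE driven by
the analytic Jacobians ∂F/∂u and ∂F/∂θ of the model family, and the
augmented system (n + nP states for P parameters) is integrated together
with the state. The initial sensitivity is zero. Forward sensitivities are
the right regime here: parameter counts are at most a few hundred, the
augmented systems stay modest, and the method avoids the storage/replay
machinery of adjoints. Agreement with central finite differences to 1e-4
relative error is enforced by tests for both families.

Solvers: oscillatory fits wander through stiff parameter regions, so the
defaults are implicit — a fully implicit Runge–Kutta method (Radau) for
the ODE family and BDF for the NODE family, with the analytic state
Jacobian supplied. LSODA (stiff/non-stiff switching) and explicit RK
methods are available by name; the test suite and worked examples use
LSODA for speed on the small, mostly non-stiff fixture problems. Default
tolerances rtol 1e-6 / atol 1e-8, configurable. A solver failure raises an
error carrying the offending parameter snapshot.

## Sequential curriculum fitting

Fitting all points simultaneously from random parameters often converges
to a phase-averaged, nearly-flat trajectory. The curriculum instead
activates the target points in `segments` stages (segment k activates the
first ⌈kT/segments⌉ points) and ramps newly activated points' weights
linearly 0 → 1 over `ramp_iters` iterations, avoiding the discontinuity
that full-weight activation would inject into the optimization. The ramp
shape is linear — the minimal reading of "slowly increase". The final
schedule entry is always all-ones, and the returned `final_loss` is the
all-ones loss recomputed at the returned parameters.

The optimizer is Adam (defaults lr 0.01, betas 0.9/0.999; the suite's
small fixtures use lr 0.05–0.1 with a few hundred iterations per segment,
sizes chosen so a full paired comparison runs in minutes on one core). A
step whose solve diverges is treated as an infinite-loss candidate: the
previous iterate is kept and the step retried with a halved learning rate
for that iteration. Parameter initialization: ODE entries ~ Normal(0, 0.1);
NODE layers use uniform fan-in scaling. Multi-restart is a thin loop over
seeds (`fit.restarts` in the CLI), keeping the best final loss.

On the oscillatory synthetic fixture the curriculum's benefit is large and
reproducible: with equal iteration budgets, the sequential fit's final
loss beat simultaneous fitting on 10 of 10 paired seeds in the frozen test
configuration.

## pSGLD posterior sampling

From the fitted optimum, preconditioned stochastic gradient Langevin
dynamics approximately samples the posterior implied by treating the
quadratic loss as a negative log-posterior under a non-informative prior.
Per coordinate: V ← αV + (1−α)g², G = 1/(λ + √V), then
θ ← θ − (ε/2)Gg + Normal(0, εG). Near the optimum ε|g| ≪ 1 and the noise
dominates, so the chain explores the basin rather than descending.

- The curvature-correction (Γ) term of the original scheme is omitted;
  with α close to 1 the preconditioner drifts slowly and the term is
  negligible. This is a documented approximation, standard in practice.
- With α → 1, V₀ = 0, λ = 1 the update reduces exactly to unpreconditioned
  SGLD; on a 1-D quadratic loss the chain's stationary variance matches
  the analytic value (unit variance for L = θ²/2) within a few percent
  over a 300k-step run — both are test assertions.
- Defaults: ε = 1e-4, α = 0.99, λ = 1e-5, 5000 warm-up and 10,000
  collected samples (the run sizes of the motivating study); a temperature
  knob (default 1) rescales the loss. No thinning — every generated set is
  kept. ε, α, λ have no published reference values; they are exposed.
- A non-integrable proposal is rejected: the chain backs off to the
  previous state and redraws; if more than `max_fail_frac` of all steps
  fail, sampling aborts.

Convergence is judged by the **split-half diagnostic**: the loss
distribution over the first half of collected samples is compared with the
second half via the two-sample Kolmogorov–Smirnov statistic, with a
configurable closeness threshold (default 0.1) — "reasonably close" is
inherently a judgment call, so the threshold is explicit rather than
baked in. Summaries (mean, SD, quantiles per half) are reported alongside.

## Prediction assessment

Train/test split at a time boundary (training keeps the boundary point;
the standard protocol trains on years 0–60 — 121 augmented points — and
tests on 60–90). Ensemble members are drawn uniformly **without
replacement** from the posterior, and each is integrated from the
*training* initial state over the full grid, so trajectories cross the
split continuously. Members whose solve diverges are excluded and counted,
never silently dropped.

- `loss_summary`: mean ± unbiased sample SD of M drawn members' unweighted
  losses over a window (train, test, or full — the window is an argument
  because published summaries are ambiguous on this point).
- `compare_repeated`: the repeated-sampling protocol for two models —
  fix one model's reference mean from a single M-member draw, then count
  the fraction of `reps` fresh M-member means of the other model that fall
  below it. The fraction is dominated by the reference-mean draw, so
  individual runs fluctuate widely around the symmetric value of one half;
  this mirrors the protocol it implements. It operates on precomputed
  per-member loss vectors (`member_losses`) so the trajectories are solved
  once per member, not once per repetition.
- `phase_export`: phase-space paths (variables as coordinates). For
  three-dimensional views the data path borrows the model's dummy
  coordinate, lifting the observed two-species path into the model's
  state space.

## Synthetic data

The generator integrates the Lotka–Volterra system
du₁/dt = αu₁ − βu₁u₂, du₂/dt = δu₁u₂ − γu₂ on a yearly grid (DOP853,
rtol 1e-8, so fixture solver error is negligible against every test
tolerance; the conserved quantity δu₁ − γ ln u₁ + βu₂ − α ln u₂ is used as
an independent drift oracle) and applies multiplicative lognormal
observation noise — additive Gaussian on the log working scale, positive
abundances on the original scale.

Default rates α=0.55, β=0.028, γ=0.76, δ=0.024, u0=(38, 19): cycles of
roughly a decade over the 90-year span, amplitude ≈0.4 peak-to-trough on
the log scale. The amplitude keeps the cycles near-sinusoidal, so the
default smoothing distorts the noise-free signal by under 0.05 on the
working scale (a tested bound).

What the fixture does **not** emulate: demographic/environmental process
noise (the dynamics are deterministic; noise is observation-only),
irregular sampling, missing values, amplitude modulation across cycles, or
the heavier distortions of real survey data. Passing tests therefore show
that the machinery is correct and that the method behaves as documented
under clean conditions; they do not certify performance on real records.

## Numerical/degenerate-input policy

σ = 0 smoothing, zero-weight losses, single-sample ensembles (diagnostic
undefined, reported as absent), `segments = 1, ramp_iters = 0` (plain
simultaneous fitting) are all exact special cases. The curriculum requires
`ramp_iters < iters_per_segment` so every segment reaches full weight.
CSV round trips are bit-exact (shortest-round-trip float formatting on
write, round-trip parsing on read); parameter JSON serialization is
bit-exact the same way.

## Scale of the shipped experiments

The test suite and examples run minutes-scale problems on one core:
fixtures of 61–91 yearly points, a few hundred to ~1500 Adam iterations,
pSGLD chains of ~1k steps, 30-member ensembles. These sizes are the
package's chosen demonstration scale; every one of them is a config knob,
and the defaults for production-style runs (5000/10,000 pSGLD samples,
3000-member loss summaries) match the motivating study's run sizes.

## Known limitations

- Forward sensitivities scale linearly in parameter count; beyond a few
  thousand parameters an adjoint method would be preferable. Not needed at
  this architecture's sizes.
- The pSGLD Γ-term omission (above) slightly biases the stationary
  distribution when α is small.
- The posterior is local: the chain explores one basin around the fitted
  optimum and says nothing about other modes.
- No missing-data handling; grids must be strictly increasing and complete.
- Losses across models are comparable only on identical grids and windows.
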