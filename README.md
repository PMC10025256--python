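# nodefit

Fit ordinary differential equation (ODE) and neural-ODE (NODE) models to
short, noisy, oscillatory time series — the kind ecologists meet in
multi-decade predator–prey records such as the hare–lynx abundance data —
and quantify confidence in fits and forecasts with approximate-Bayesian
trajectory ensembles.

The package is for practitioners who want to compare a simple
low-dimensional dynamical model against a flexible neural parameterization
*on the same data with the same machinery*: one switch changes the model
family, everything else (smoothing, loss, solver, curriculum, sampler,
prediction assessment) stays fixed.

## The method

Given observations y(t) on n_obs variables, the pipeline estimates a
smooth field du/dt = F(u; θ) on n ≥ n_obs variables (extra *dummy*
dimensions lift the trajectory geometry into higher-dimensional phase
space), where F is one of

- **ODE**: du/dt = f(S u − b), S ∈ ℝⁿˣⁿ, b ∈ ℝⁿ — n² + n parameters;
- **NODE**: du/dt = W₂ f(W₁ u + b₁) + b₂ with N hidden nodes —
  (n + 1)N + n(N + 1) parameters (102, 143, 184 for N = 20, n = 2, 3, 4);

with f = tanh elementwise by default. The stages:

1. **Smooth** the raw series: log transform, per-variable mean-centering,
   cubic-spline midpoint augmentation (T → 2T − 1 points; 91 yearly
   observations become 181 half-yearly targets), Gaussian filtering.
2. **Fit** θ by Adam on the quadratic loss L(θ) = Σₜ wₜ Σᵥ (uᵥ(tₜ; θ) −
   yₜᵥ)², computed through a stiff initial-value solver with exact
   gradients from forward sensitivity equations. A sequential curriculum
   activates later time points stepwise, ramping their weights wₜ from 0
   to 1 to keep the optimization continuous.
3. **Sample** an approximate posterior around the optimum with
   preconditioned stochastic gradient Langevin dynamics (pSGLD), treating
   L as a negative log-posterior under a non-informative prior; a
   split-half Kolmogorov–Smirnov diagnostic checks chain convergence.
4. **Predict**: split the record into training and test windows, draw
   parameter sets from the posterior, integrate each over the full span,
   and summarize member losses (mean ± SD) and trajectory spread per
   window; phase-plot exports trace the paths in state space.

A synthetic-data module generates Lotka–Volterra series with
multiplicative lognormal observation noise so the whole pipeline is
testable without any data download. See `docs/methods.md` for assumptions,
defaults, and limitations.

## Worked example

```python
import numpy as np
from nodefit import synthetic_data as sd, preprocess as pp
from nodefit import models, trajectory, training, psgld, prediction

# 91 yearly observations of a noisy predator-prey oscillation
raw = sd.add_noise(sd.simulate_lv(sd.default_params()),
                   sd.NoiseSpec(sigma=0.05, seed=1))
target = pp.preprocess(raw, sigma=1.0)          # 181 half-yearly points
train, test = prediction.split(target, prediction.SplitSpec(60.0))

spec = models.ModelSpec("ode", n=2, n_obs=2)    # 6 parameters
solver = trajectory.SolverConfig(method="LSODA")
fits = [training.fit(spec, train,
                     training.FitConfig(segments=4, ramp_iters=30,
                                        iters_per_segment=120, lr=0.05,
                                        seed=s, solver=solver))
        for s in range(3)]                      # small multi-restart
fit = min(fits, key=lambda f: f.final_loss)
print(f"best final training loss: {fit.final_loss:.3f}")

ens = psgld.sample(fit, train,
                   psgld.PsgldHyper(epsilon=1e-5, n_warmup=200,
                                    n_collect=400, seed=1), solver)
print(f"split-half KS: {ens.diagnostic['ks_statistic']:.3f}")

for name, win in (("train", (-1.0, 60.0)), ("test", (60.0, 90.0))):
    mean, sdv = prediction.loss_summary(ens, spec, fit.u0, target, M=200,
                                        seed=2, solver=solver, window=win)
    print(f"{name}-window loss: {mean:.2f} +/- {sdv:.2f}")
```

Output:

```
best final training loss: 1.090
split-half KS: 0.825
train-window loss: 2.09 +/- 0.42
test-window loss: 1.83 +/- 0.21
```

Reading the numbers: the restarts land at 4.33, **1.09** and 4.43 — the
loss surface of an oscillatory fit is rugged, and restarts matter. The
best fit's training loss of 1.09 is the sum of 242 squared deviations on
the log-centered scale (≈ 0.067 RMS per point). The split-half KS of 0.83
*fails* the convergence check (threshold 0.1): a 400-sample demonstration
chain is far shorter than the 10,000-sample production default, and the
diagnostic says so. The posterior loss summaries put the test window in
the same range as training — at this noise level the 6-parameter model is
not overfitting.

The same workflow is scriptable from the shell (`simulate`, `preprocess`,
`fit`, `sample`, `predict`, `report`), driven by one YAML config with a
global seed; every run appends a manifest with the config snapshot, seeds
and timings:

```sh
nodefit --show-config > config.yaml   # edit as needed
nodefit simulate   --config config.yaml --out run --seed 7
nodefit preprocess --config config.yaml --out run --seed 7
nodefit fit        --config config.yaml --out run --seed 7
nodefit sample     --config config.yaml --out run --seed 7
nodefit predict    --config config.yaml --out run --seed 7
nodefit report     --config config.yaml --out run --seed 7   # figures
```

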