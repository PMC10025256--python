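"""Preconditioned stochastic gradient Langevin dynamics (pSGLD) sampling.

Starting from a fitted optimum, pSGLD adds calibrated Gaussian noise to
RMSProp-preconditioned gradient steps.  Near the optimum, where the step
size times the gradient is much smaller than one, the stochastic force
dominates and the chain approximately samples the Bayesian posterior
implied by treating the quadratic loss as a negative log-posterior under a
non-informative prior (optionally rescaled by a temperature).

Update (Li et al. 2016 style), per coordinate:

    V   <- alpha V + (1 - alpha) g^2
    G   <- 1 / (lam + sqrt(V))
    d   <- theta - (eps / 2) G g + eta,   eta ~ Normal(0, eps G)

The curvature-correction (Gamma) term of the original scheme is omitted;
with the preconditioner decay alpha close to 1 the preconditioner changes
slowly and the term is negligible (a documented approximation).

Convergence is judged by the split-half diagnostic: the loss distribution
over the first half of the collected samples is compared with the second
half by a two-sample Kolmogorov–Smirnov statistic.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
from scipy import stats

from .models import ParameterVector
from .series import SmoothedSeries
from .trajectory import IntegrationError, SolverConfig, loss_and_gradient
from .training import FitResult

__all__ = [
    "PsgldHyper",
    "PosteriorEnsemble",
    "SamplingError",
    "psgld_step",
    "sample",
    "split_half_diagnostic",
]


class SamplingError(RuntimeError):
    """Raised when too many sampling steps fail to integrate."""


@dataclass
class PsgldHyper:
    """pSGLD hyperparameters.

    epsilon : step size (the noise dominates when epsilon * |g| << 1).
    alpha : preconditioner decay, in (0, 1).
    lam : preconditioner damping, > 0.
    n_warmup : discarded warm-up samples.
    n_collect : retained samples.
    temperature : divides the loss used as negative log-posterior.
    seed : RNG seed.
    max_fail_frac : tolerated fraction of non-integrable steps.
    """

    epsilon: float = 1e-4
    alpha: float = 0.99
    lam: float = 1e-5
    n_warmup: int = 5000
    n_collect: int = 10_000
    temperature: float = 1.0
    seed: int = 0
    max_fail_frac: float = 0.1

    def __post_init__(self) -> None:
        if self.epsilon <= 0:
            raise ValueError("epsilon must be > 0")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must lie in (0, 1)")
        if self.lam <= 0:
            raise ValueError("lam must be > 0")
        if self.n_warmup < 1 or self.n_collect < 1:
            raise ValueError("n_warmup and n_collect must be >= 1")
        if self.temperature <= 0:
            raise ValueError("temperature must be > 0")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class PosteriorEnsemble:
    """Collected parameter samples with per-sample all-ones losses."""

    samples: np.ndarray  # (n_collect, P)
    losses: np.ndarray  # (n_collect,)
    hyper: PsgldHyper
    diagnostic: dict | None = None
    n_failed_steps: int = 0

    @property
    def size(self) -> int:
        return self.samples.shape[0]

    def save(self, directory: str | Path) -> None:
        """Persist as a directory: samples CSV, losses CSV, hyper/diag JSON."""
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        np.savetxt(d / "samples.csv", self.samples, delimiter=",")
        np.savetxt(d / "losses.csv", self.losses, delimiter=",")
        (d / "hyper.json").write_text(json.dumps(self.hyper.to_dict()), "utf-8")
        if self.diagnostic is not None:
            (d / "diagnostic.json").write_text(json.dumps(self.diagnostic), "utf-8")

    @classmethod
    def load(cls, directory: str | Path) -> "PosteriorEnsemble":
        d = Path(directory)
        samples = np.loadtxt(d / "samples.csv", delimiter=",", ndmin=2)
        losses = np.atleast_1d(np.loadtxt(d / "losses.csv", delimiter=","))
        hyper = PsgldHyper(**json.loads((d / "hyper.json").read_text("utf-8")))
        diag_path = d / "diagnostic.json"
        diag = json.loads(diag_path.read_text("utf-8")) if diag_path.exists() else None
        return cls(samples, losses, hyper, diag)


def psgld_step(
    theta: np.ndarray,
    g: np.ndarray,
    V: np.ndarray,
    hyper: PsgldHyper,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """One pSGLD update; V is updated first, then the noisy step is taken.

    Returns the new (theta, V); inputs are not modified.
    """
    if theta.shape != g.shape or theta.shape != V.shape:
        raise ValueError("theta, gradient and preconditioner shapes must agree")
    if not np.all(np.isfinite(g)):
        raise SamplingError(f"non-finite gradient at theta={theta!r}")
    V = hyper.alpha * V + (1 - hyper.alpha) * g * g
    G = 1.0 / (hyper.lam + np.sqrt(V))
    noise = rng.normal(0.0, np.sqrt(hyper.epsilon * G))
    return theta - 0.5 * hyper.epsilon * G * g + noise, V


def sample(
    fit: FitResult,
    target: SmoothedSeries,
    hyper: PsgldHyper | None = None,
    solver: SolverConfig | None = None,
) -> PosteriorEnsemble:
    """Run warm-up then collection from the fitted optimum.

    All loss/gradient evaluations use all-ones weights (the curriculum is a
    training device only).  A step whose gradient evaluation fails to
    integrate is skipped (the chain stays put); if more than
    ``hyper.max_fail_frac`` of all steps fail, a :class:`SamplingError` is
    raised.  Deterministic given ``hyper.seed``.
    """
    hyper = hyper or PsgldHyper()
    solver = solver if solver is not None else fit.config.solver
    if not np.isfinite(fit.final_loss):
        raise ValueError("cannot sample from a diverged fit")
    spec = fit.params.spec
    rng = np.random.default_rng(hyper.seed)
    theta = fit.params.flat.copy()
    V = np.zeros_like(theta)
    prev_theta, prev_V = theta.copy(), V.copy()
    total = hyper.n_warmup + hyper.n_collect
    samples = np.empty((hyper.n_collect, theta.size))
    losses = np.empty(hyper.n_collect)
    last_loss = fit.final_loss
    n_failed = 0
    for step_i in range(total):
        collecting = step_i >= hyper.n_warmup
        k = step_i - hyper.n_warmup
        try:
            loss, g = loss_and_gradient(
                ParameterVector(spec, theta), fit.u0, target, None, solver
            )
            g = g / hyper.temperature
            last_loss = loss
            if collecting:
                samples[k] = theta
                losses[k] = loss
            prev_theta, prev_V = theta, V
            theta, V = psgld_step(theta, g, V, hyper, rng)
        except IntegrationError:
            # non-integrable proposal: back off and redraw the noise next step
            n_failed += 1
            theta, V = prev_theta, prev_V
            if collecting:
                samples[k] = theta
                losses[k] = last_loss
            if n_failed > hyper.max_fail_frac * total:
                raise SamplingError(
                    f"{n_failed}/{step_i + 1} pSGLD steps failed to integrate"
                )
    ensemble = PosteriorEnsemble(samples, losses, hyper, None, n_failed)
    if ensemble.size >= 2:
        ensemble.diagnostic = split_half_diagnostic(ensemble)
    return ensemble


def _summary(x: np.ndarray) -> dict:
    q = np.quantile(x, [0.05, 0.25, 0.5, 0.75, 0.95])
    return {
        "mean": float(np.mean(x)),
        "sd": float(np.std(x, ddof=1)) if x.size > 1 else 0.0,
        "quantiles": {p: float(v) for p, v in zip(("q05", "q25", "q50", "q75", "q95"), q)},
    }


def split_half_diagnostic(
    ensemble: PosteriorEnsemble, threshold: float = 0.1
) -> dict:
    """Compare the loss distribution of the first vs second half of samples.

    A chain run long enough produces 'reasonably close' halves; closeness is
    the two-sample Kolmogorov–Smirnov statistic against ``threshold``.
    Returns half summaries (mean, SD, quantiles), the KS statistic and
    p-value, and a pass flag (statistic <= threshold).
    """
    losses = ensemble.losses
    if losses.size < 2:
        raise ValueError("need at least 2 samples for the split-half diagnostic")
    half = losses.size // 2
    first, second = losses[:half], losses[half : 2 * half]
    if np.array_equal(first, second):
        ks_stat, p_value = 0.0, 1.0
    else:
        res = stats.ks_2samp(first, second)
        ks_stat, p_value = float(res.statistic), float(res.pvalue)
    return {
        "first_half": _summary(first),
        "second_half": _summary(second),
        "ks_statistic": ks_stat,
        "ks_pvalue": p_value,
        "threshold": threshold,
        "passed": bool(ks_stat <= threshold),
    }
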