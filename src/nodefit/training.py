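"""Sequential curriculum fitting with Adam.

Fitting all points of an oscillatory series simultaneously from random
parameters often fails: the loss surface is too rugged.  The curriculum
fits the early part of the series first and adds later points stepwise; to
avoid the discontinuity of switching new points on at full weight, newly
activated points ramp linearly from 0 to 1 over a configurable number of
iterations, which keeps the optimization continuous.

The optimizer is plain Adam on the exact solver-propagated gradient.  A
solver failure during a step marks that candidate as infinite loss: the
step is rejected, the previous iterate restored, and the effective learning
rate for the retry is halved for that iteration.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np

from .models import (
    InitialState,
    ModelSpec,
    ParameterVector,
    init_params,
    initial_state,
)
from .series import SmoothedSeries
from .trajectory import (
    IntegrationError,
    SolverConfig,
    loss_and_gradient,
    solve,
    weighted_loss,
)

__all__ = ["FitConfig", "FitResult", "weight_schedule", "fit", "FittingError"]


class FittingError(RuntimeError):
    """Raised when optimization cannot produce a finite-loss result."""


@dataclass
class FitConfig:
    """Curriculum and optimizer settings.

    segments : number of sequential stages; segment k (1-based) activates
        the first ceil(k T / segments) target points.
    ramp_iters : iterations over which newly activated points ramp 0 -> 1.
    iters_per_segment : Adam iterations per stage (> ramp_iters).
    lr : Adam learning rate.
    adam_betas : Adam momentum constants.
    seed : seeds both the parameter init and the dummy initial values.
    solver : integrator settings used for every loss/gradient evaluation.
    """

    segments: int = 4
    ramp_iters: int = 100
    iters_per_segment: int = 500
    lr: float = 0.01
    adam_betas: tuple[float, float] = (0.9, 0.999)
    seed: int = 0
    solver: SolverConfig = dc_field(default_factory=SolverConfig)

    def __post_init__(self) -> None:
        if self.segments < 1:
            raise ValueError("segments must be >= 1")
        if self.ramp_iters < 0:
            raise ValueError("ramp_iters must be >= 0")
        if self.iters_per_segment <= self.ramp_iters:
            raise ValueError(
                "iters_per_segment must exceed ramp_iters so every segment "
                "reaches full weight"
            )
        if self.lr <= 0:
            raise ValueError("lr must be > 0")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["adam_betas"] = list(self.adam_betas)
        return d


@dataclass
class FitResult:
    """Optimized parameters plus everything needed to reproduce the run."""

    params: ParameterVector
    u0: InitialState
    loss_trace: np.ndarray
    final_loss: float
    config: FitConfig

    def save(self, path: str | Path) -> None:
        """JSON (params, u0, config, final loss) + CSV loss trace sidecar."""
        path = Path(path)
        doc = {
            "params": json.loads(self.params.to_json()),
            "u0": [float(x) for x in self.u0.u0],
            "u0_seed": self.u0.seed,
            "n_obs": self.u0.n_obs,
            "final_loss": self.final_loss,
            "config": self.config.to_dict(),
        }
        path.write_text(json.dumps(doc, indent=1), encoding="utf-8")
        np.savetxt(
            path.with_suffix(".trace.csv"),
            np.column_stack([np.arange(self.loss_trace.size), self.loss_trace]),
            delimiter=",",
            header="iteration,loss",
            comments="",
        )

    @classmethod
    def load(cls, path: str | Path) -> "FitResult":
        path = Path(path)
        doc = json.loads(path.read_text(encoding="utf-8"))
        params = ParameterVector.from_json(json.dumps(doc["params"]))
        cfg_d = dict(doc["config"])
        cfg_d["adam_betas"] = tuple(cfg_d["adam_betas"])
        cfg_d["solver"] = SolverConfig(**cfg_d["solver"])
        trace_path = path.with_suffix(".trace.csv")
        trace = (
            np.loadtxt(trace_path, delimiter=",", skiprows=1, ndmin=2)[:, 1]
            if trace_path.exists()
            else np.zeros(0)
        )
        return cls(
            params=params,
            u0=InitialState(np.asarray(doc["u0"]), doc["n_obs"], doc["u0_seed"]),
            loss_trace=trace,
            final_loss=float(doc["final_loss"]),
            config=FitConfig(**cfg_d),
        )


def weight_schedule(
    T: int, segments: int, ramp_iters: int, iters_per_segment: int
) -> list[np.ndarray]:
    """Per-iteration weight vectors for the sequential curriculum.

    Segment k (1-based) activates the first ceil(k T / segments) points.
    Points active in an earlier segment keep weight 1; points newly
    activated in this segment ramp linearly 0 -> 1 over ``ramp_iters``
    iterations (weight min(1, j / ramp_iters) at iteration j of the
    segment).  The final entry is always all-ones.
    """
    schedule: list[np.ndarray] = []
    prev_active = 0
    for k in range(1, segments + 1):
        active = int(np.ceil(k * T / segments))
        for j in range(iters_per_segment):
            w = np.zeros(T)
            w[:prev_active] = 1.0
            ramp = 1.0 if ramp_iters == 0 else min(1.0, j / ramp_iters)
            w[prev_active:active] = ramp
            schedule.append(w)
        prev_active = active
    schedule[-1] = np.ones(T)
    return schedule


def fit(
    spec: ModelSpec,
    target: SmoothedSeries,
    cfg: FitConfig | None = None,
    params0: ParameterVector | None = None,
) -> FitResult:
    """Fit the model to the smoothed target with the ramped-weight curriculum.

    Deterministic given ``cfg.seed`` (which also seeds the dummy initial
    values).  Returns the best-seen parameters as judged by the all-ones
    (uncurriculum) loss, evaluated whenever the current weights are already
    all-ones; ``final_loss`` is that loss at the returned parameters.
    """
    cfg = cfg or FitConfig()
    params = (
        ParameterVector(spec, params0.flat.copy())
        if params0 is not None
        else init_params(spec, cfg.seed)
    )
    u0 = initial_state(target, spec, seed=cfg.seed + 1)
    T = target.n_points
    schedule = weight_schedule(T, cfg.segments, cfg.ramp_iters, cfg.iters_per_segment)

    theta = params.flat.copy()
    m = np.zeros_like(theta)
    v = np.zeros_like(theta)
    b1, b2 = cfg.adam_betas
    eps = 1e-8
    trace = np.full(len(schedule), np.inf)
    best_theta = theta.copy()
    best_full_loss = np.inf
    any_finite = False

    for it, w in enumerate(schedule):
        all_ones = bool(np.all(w == 1.0))
        lr = cfg.lr
        pv = ParameterVector(spec, theta)
        try:
            loss, g = loss_and_gradient(pv, u0, target, w, cfg.solver)
            if not np.all(np.isfinite(g)):
                raise IntegrationError("non-finite gradient", pv)
        except IntegrationError:
            # infinite-loss candidate: keep previous iterate, damp the step
            trace[it] = np.inf
            lr = cfg.lr * 0.5
            loss, g = None, None
        if g is not None:
            any_finite = True
            trace[it] = loss
            if all_ones and loss < best_full_loss:
                best_full_loss = loss
                best_theta = theta.copy()
            m = b1 * m + (1 - b1) * g
            v = b2 * v + (1 - b2) * g * g
            t = it + 1
            mhat = m / (1 - b1**t)
            vhat = v / (1 - b2**t)
            theta = theta - lr * mhat / (np.sqrt(vhat) + eps)

    if not any_finite:
        raise FittingError(
            f"every iteration diverged (trace: {trace[:10]} ...)"
        )
    if not np.isfinite(best_full_loss):
        # no all-ones iteration survived; fall back to the last finite iterate
        best_theta = theta
    # re-evaluate with a plain solve so final_loss is exactly the all-ones
    # loss at the returned parameters
    pv = ParameterVector(spec, best_theta)
    try:
        traj = solve(pv, u0, target.times, cfg.solver)
        best_full_loss = weighted_loss(traj, target, None, spec.n_obs)
    except IntegrationError as exc:
        raise FittingError("final parameters do not integrate") from exc

    return FitResult(
        params=ParameterVector(spec, best_theta),
        u0=u0,
        loss_trace=trace,
        final_loss=float(best_full_loss),
        config=cfg,
    )
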