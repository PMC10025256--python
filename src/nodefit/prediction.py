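"""Train/test splitting, posterior trajectory ensembles, and model comparison.

The prediction workflow mirrors the usual single-series protocol: fit on
the early portion of the record (e.g. the first 61 yearly observations,
times 0–60), then judge each model by how its posterior trajectory
ensemble behaves over the held-out remainder (60–90).  Ensemble members
are parameter sets drawn without replacement from the pSGLD posterior and
integrated from the training-period initial state over the *full* grid, so
trajectories are continuous across the split.  Prediction quality is
summarized as the mean ± SD of member losses over a window, and two models
are compared by repeatedly resampling one model's mean loss against the
other's reference mean.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .models import InitialState, ModelSpec, ParameterVector
from .psgld import PosteriorEnsemble
from .series import SmoothedSeries
from .trajectory import IntegrationError, SolverConfig, Trajectory, solve, weighted_loss

__all__ = [
    "SplitSpec",
    "TrajectoryEnsemble",
    "split",
    "window_mask",
    "ensemble_predict",
    "member_losses",
    "loss_summary",
    "compare_repeated",
    "phase_export",
]


@dataclass
class SplitSpec:
    """Train/test boundary: training takes times <= t_split."""

    t_split: float


@dataclass
class TrajectoryEnsemble:
    """K posterior trajectories sharing one time grid.

    trajectories : (K, T, n) array of member states.
    member_indices : indices into the posterior ensemble that produced them.
    n_failed : members excluded because their solve diverged (reported,
        never silently dropped).
    """

    times: np.ndarray
    trajectories: np.ndarray
    member_indices: np.ndarray
    n_failed: int = 0

    @property
    def size(self) -> int:
        return self.trajectories.shape[0]


def split(
    target: SmoothedSeries, spec: SplitSpec
) -> tuple[SmoothedSeries, SmoothedSeries]:
    """Partition the target grid at ``t_split`` (train keeps the boundary).

    The two parts concatenate back to the original grid exactly.
    """
    t = spec.t_split
    if not (target.times[0] < t < target.times[-1]):
        raise ValueError(
            f"t_split={t} must lie strictly inside "
            f"[{target.times[0]}, {target.times[-1]}]"
        )
    mask = target.times <= t
    if mask.all() or not mask.any():
        raise ValueError("split leaves one side empty")
    mk = lambda m: SmoothedSeries(
        target.times[m],
        target.values[m],
        target.names,
        log_means=target.log_means,
        smoothing_sigma=target.smoothing_sigma,
    )
    return mk(mask), mk(~mask)


def window_mask(times: np.ndarray, window: tuple[float, float] | None) -> np.ndarray:
    """Boolean mask for times in (lo, hi]; ``None`` selects everything."""
    if window is None:
        return np.ones(times.size, dtype=bool)
    lo, hi = window
    return (times > lo) & (times <= hi)


def _draw(ensemble: PosteriorEnsemble, K: int, seed: int) -> np.ndarray:
    if K > ensemble.size:
        raise ValueError(f"requested {K} members from an ensemble of {ensemble.size}")
    rng = np.random.default_rng(seed)
    return rng.choice(ensemble.size, size=K, replace=False)


def ensemble_predict(
    ensemble: PosteriorEnsemble,
    spec: ModelSpec,
    u0: InitialState | np.ndarray,
    times: np.ndarray,
    K: int = 30,
    seed: int = 0,
    solver: SolverConfig | None = None,
) -> TrajectoryEnsemble:
    """Solve K posterior draws (uniform, without replacement) over ``times``.

    Diverging members are excluded and counted in ``n_failed``.
    """
    idx = _draw(ensemble, K, seed)
    times = np.asarray(times, dtype=float)
    kept_traj, kept_idx, n_failed = [], [], 0
    for i in idx:
        pv = ParameterVector(spec, ensemble.samples[i])
        try:
            kept_traj.append(solve(pv, u0, times, solver).states)
            kept_idx.append(i)
        except IntegrationError:
            n_failed += 1
    if not kept_traj:
        raise IntegrationError("every ensemble member diverged")
    return TrajectoryEnsemble(
        times, np.stack(kept_traj), np.asarray(kept_idx), n_failed
    )


def member_losses(
    ensemble: PosteriorEnsemble,
    spec: ModelSpec,
    u0: InitialState | np.ndarray,
    target: SmoothedSeries,
    solver: SolverConfig | None = None,
    window: tuple[float, float] | None = None,
    indices: np.ndarray | None = None,
) -> np.ndarray:
    """Unweighted loss of each member over the window, solving the full grid.

    Trajectories start from the (training) initial state and run over the
    whole target grid; the loss is then restricted to the window's times.
    Diverging members get loss +inf.
    """
    idx = np.arange(ensemble.size) if indices is None else np.asarray(indices)
    mask = window_mask(target.times, window)
    if not mask.any():
        raise ValueError("window selects no target points")
    sub_target = SmoothedSeries(
        target.times[mask],
        target.values[mask],
        target.names,
        log_means=target.log_means,
        smoothing_sigma=target.smoothing_sigma,
    )
    out = np.empty(idx.size)
    for j, i in enumerate(idx):
        pv = ParameterVector(spec, ensemble.samples[i])
        try:
            traj = solve(pv, u0, target.times, solver)
            sub = Trajectory(target.times[mask], traj.states[mask])
            out[j] = weighted_loss(sub, sub_target, None, spec.n_obs)
        except IntegrationError:
            out[j] = np.inf
    return out


def loss_summary(
    ensemble: PosteriorEnsemble,
    spec: ModelSpec,
    u0: InitialState | np.ndarray,
    target: SmoothedSeries,
    M: int = 3000,
    seed: int = 0,
    solver: SolverConfig | None = None,
    window: tuple[float, float] | None = None,
) -> tuple[float, float]:
    """Mean and unbiased sample SD of M drawn members' window losses."""
    idx = _draw(ensemble, M, seed)
    losses = member_losses(ensemble, spec, u0, target, solver, window, idx)
    finite = losses[np.isfinite(losses)]
    if finite.size == 0:
        raise IntegrationError("all sampled members diverged")
    sd = float(np.std(finite, ddof=1)) if finite.size > 1 else 0.0
    return float(np.mean(finite)), sd


def compare_repeated(
    losses_a: np.ndarray,
    losses_b: np.ndarray,
    reps: int = 80,
    M: int = 3000,
    seed: int = 0,
) -> float:
    """Fraction of ``reps`` M-subsample means of A below B's reference mean.

    ``losses_a``/``losses_b`` are per-member window losses (see
    :func:`member_losses`).  B's reference mean is one seeded M-sample mean
    of B's losses; each rep draws M members of A without replacement and
    compares the mean.  With A and B identically distributed the fraction
    is near one half.
    """
    losses_a = np.asarray(losses_a, dtype=float)
    losses_b = np.asarray(losses_b, dtype=float)
    if M > losses_a.size or M > losses_b.size:
        raise ValueError("M exceeds an ensemble's member count")
    rng = np.random.default_rng(seed)
    ref_b = float(np.mean(losses_b[rng.choice(losses_b.size, M, replace=False)]))
    wins = 0
    for _ in range(reps):
        mean_a = float(np.mean(losses_a[rng.choice(losses_a.size, M, replace=False)]))
        if mean_a < ref_b:
            wins += 1
    return wins / reps


def phase_export(
    data: SmoothedSeries,
    model_traj: Trajectory | None,
    dims: list[int],
) -> pd.DataFrame:
    """Phase-path table: selected coordinates per time for data and model.

    ``dims`` are 1-based state coordinates.  Observed coordinates of the
    data path come from the data; dummy coordinates (beyond the data's
    variables) are copied from the model trajectory, which lifts the
    observed path into the model's state space.  Model coordinates always
    come from the trajectory.
    """
    dims = list(dims)
    needs_model = any(d > data.n_vars for d in dims)
    if model_traj is None:
        if needs_model:
            raise ValueError(
                "requested a dummy dimension for the data path without a "
                "model trajectory to copy it from"
            )
        times, n_model = data.times, 0
    else:
        if model_traj.times.shape != data.times.shape or not np.allclose(
            model_traj.times, data.times
        ):
            raise ValueError("data and model trajectory grids differ")
        times, n_model = model_traj.times, model_traj.states.shape[1]
    for d in dims:
        if d < 1 or d > max(data.n_vars, n_model):
            raise ValueError(f"dimension {d} out of range")
    cols: dict[str, np.ndarray] = {"time": times}
    for d in dims:
        if d <= data.n_vars:
            cols[f"data_dim{d}"] = data.values[:, d - 1]
        else:
            cols[f"data_dim{d}"] = model_traj.states[:, d - 1]
    if model_traj is not None:
        for d in dims:
            cols[f"model_dim{d}"] = model_traj.states[:, d - 1]
    return pd.DataFrame(cols)
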