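"""Derivative-field families: the low-dimensional ODE and the two-layer NODE.

Both families define a smooth vector field du/dt = F(u; theta) on n state
variables, of which the first ``n_obs`` are observed (hare and lynx in the
motivating data) and the remaining n - n_obs are *dummy* variables —
unobserved factors that lift the trajectory geometry into higher dimensions.

ODE family
    du/dt = f(S u - b), with an n x n matrix S and n-vector b
    (n^2 + n parameters); f is an elementwise activation, tanh by default.

NODE family
    du/dt = W2 f(W1 u + b1) + b2, a two-layer network with N hidden nodes
    and no activation on the output layer; (n + 1) N + n (N + 1) parameters
    (102, 143, 184 for N = 20 and n = 2, 3, 4).

Besides the field itself, each family exposes analytic Jacobians with
respect to the state and the flat parameter vector; the trajectory module
propagates these through the solver as forward sensitivity equations to get
exact loss gradients.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Callable

import numpy as np

from .series import SmoothedSeries

__all__ = [
    "ModelSpec",
    "ParameterVector",
    "InitialState",
    "ACTIVATIONS",
    "count_parameters",
    "ode_field",
    "node_field",
    "field",
    "jac_u",
    "jac_theta",
    "initial_state",
    "init_params",
]

# name -> (f, f') pairs; fields stay smooth so sensitivities exist
ACTIVATIONS: dict[str, tuple[Callable, Callable]] = {
    "tanh": (np.tanh, lambda z: 1.0 - np.tanh(z) ** 2),
    "identity": (lambda z: z, lambda z: np.ones_like(z)),
}


@dataclass(frozen=True)
class ModelSpec:
    """Family, dimensions and activation of a derivative field.

    family : "ode" or "node".
    n : total state dimension (observed + dummy).
    n_obs : observed dimension (2 for a two-species record).
    N : hidden-node count, NODE only (ignored for ODE).
    activation : elementwise nonlinearity, default "tanh".
    """

    family: str
    n: int
    n_obs: int = 2
    N: int = 20
    activation: str = "tanh"

    def __post_init__(self) -> None:
        if self.family not in ("ode", "node"):
            raise ValueError(f"unknown family {self.family!r}; use 'ode' or 'node'")
        if not (self.n >= self.n_obs >= 1):
            raise ValueError(f"need n >= n_obs >= 1, got n={self.n}, n_obs={self.n_obs}")
        if self.family == "node" and self.N < 1:
            raise ValueError("NODE needs at least one hidden node")
        if self.activation not in ACTIVATIONS:
            raise ValueError(
                f"unknown activation {self.activation!r}; "
                f"choose from {sorted(ACTIVATIONS)}"
            )

    @property
    def n_dummy(self) -> int:
        return self.n - self.n_obs


def count_parameters(spec: ModelSpec) -> int:
    """Total free parameters: n^2 + n (ode) or (n+1)N + n(N+1) (node)."""
    if spec.family == "ode":
        return spec.n * spec.n + spec.n
    return (spec.n + 1) * spec.N + spec.n * (spec.N + 1)


@dataclass
class ParameterVector:
    """Flat parameter array with structured views into the family's blocks.

    Flat ordering — ode: row-major S then b; node: row-major W1, b1,
    row-major W2, b2.  The views share memory with ``flat``, so the
    round trip is exact by construction.
    """

    spec: ModelSpec
    flat: np.ndarray

    def __post_init__(self) -> None:
        self.flat = np.asarray(self.flat, dtype=float)
        expected = count_parameters(self.spec)
        if self.flat.shape != (expected,):
            raise ValueError(
                f"flat parameter vector must have length {expected} for "
                f"{self.spec.family} n={self.spec.n}, got shape {self.flat.shape}"
            )

    # --- ode views -------------------------------------------------------
    @property
    def S(self) -> np.ndarray:
        if self.spec.family != "ode":
            raise AttributeError("S is an ode-family view")
        n = self.spec.n
        return self.flat[: n * n].reshape(n, n)

    @property
    def b(self) -> np.ndarray:
        if self.spec.family != "ode":
            raise AttributeError("b is an ode-family view")
        n = self.spec.n
        return self.flat[n * n :]

    # --- node views ------------------------------------------------------
    def _offsets(self) -> tuple[int, int, int, int]:
        n, N = self.spec.n, self.spec.N
        return N * n, N * n + N, N * n + N + n * N, N * n + N + n * N + n

    @property
    def W1(self) -> np.ndarray:
        if self.spec.family != "node":
            raise AttributeError("W1 is a node-family view")
        n, N = self.spec.n, self.spec.N
        return self.flat[: N * n].reshape(N, n)

    @property
    def b1(self) -> np.ndarray:
        if self.spec.family != "node":
            raise AttributeError("b1 is a node-family view")
        o1, o2, _, _ = self._offsets()
        return self.flat[o1:o2]

    @property
    def W2(self) -> np.ndarray:
        if self.spec.family != "node":
            raise AttributeError("W2 is a node-family view")
        _, o2, o3, _ = self._offsets()
        n, N = self.spec.n, self.spec.N
        return self.flat[o2:o3].reshape(n, N)

    @property
    def b2(self) -> np.ndarray:
        if self.spec.family != "node":
            raise AttributeError("b2 is a node-family view")
        _, _, o3, o4 = self._offsets()
        return self.flat[o3:o4]

    # --- serialization ---------------------------------------------------
    def to_json(self) -> str:
        """JSON document with the spec header and flat parameters.

        Floats are emitted via ``repr`` (Python's shortest round-trip form),
        so deserialization is bit-exact.
        """
        doc = {
            "spec": {
                "family": self.spec.family,
                "n": self.spec.n,
                "n_obs": self.spec.n_obs,
                "N": self.spec.N,
                "activation": self.spec.activation,
            },
            "flat": [float(x) for x in self.flat],
        }
        return json.dumps(doc)

    @classmethod
    def from_json(cls, text: str) -> "ParameterVector":
        doc = json.loads(text)
        return cls(ModelSpec(**doc["spec"]), np.asarray(doc["flat"], dtype=float))

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json(), encoding="utf-8")

    @classmethod
    def load(cls, path: str | Path) -> "ParameterVector":
        return cls.from_json(Path(path).read_text(encoding="utf-8"))


@dataclass
class InitialState:
    """Initial condition policy: observed dims from data, dummies random.

    The first n_obs entries equal the smoothed target at its first time;
    the remaining entries are random draws recorded with their seed so runs
    are reproducible.
    """

    u0: np.ndarray
    n_obs: int
    seed: int | None = None

    def __post_init__(self) -> None:
        self.u0 = np.asarray(self.u0, dtype=float)


def initial_state(target: SmoothedSeries, spec: ModelSpec, seed: int = 0) -> InitialState:
    """Build the initial state: data for observed dims, Uniform(-1, 1) dummies.

    The uniform range matches the scale of log-centered data, which after
    mean removal mostly lies within about one log unit of zero.
    """
    if target.n_vars < spec.n_obs:
        raise ValueError(
            f"target has {target.n_vars} variables, model observes {spec.n_obs}"
        )
    u0 = np.empty(spec.n)
    u0[: spec.n_obs] = target.values[0, : spec.n_obs]
    if spec.n_dummy:
        rng = np.random.default_rng(seed)
        u0[spec.n_obs :] = rng.uniform(-1.0, 1.0, size=spec.n_dummy)
    return InitialState(u0, spec.n_obs, seed)


def init_params(spec: ModelSpec, seed: int = 0) -> ParameterVector:
    """Random parameter initialization for fitting.

    ode: entries ~ Normal(0, 0.1).  node: uniform fan-in scaling,
    U(-1/sqrt(fan_in), 1/sqrt(fan_in)) per layer (weights and biases),
    the usual default for small dense networks.
    """
    rng = np.random.default_rng(seed)
    P = count_parameters(spec)
    if spec.family == "ode":
        return ParameterVector(spec, rng.normal(0.0, 0.1, size=P))
    n, N = spec.n, spec.N
    flat = np.empty(P)
    pv = ParameterVector(spec, flat)
    lim1 = 1.0 / np.sqrt(n)
    lim2 = 1.0 / np.sqrt(N)
    pv.W1[...] = rng.uniform(-lim1, lim1, size=(N, n))
    pv.b1[...] = rng.uniform(-lim1, lim1, size=N)
    pv.W2[...] = rng.uniform(-lim2, lim2, size=(n, N))
    pv.b2[...] = rng.uniform(-lim2, lim2, size=n)
    return pv


def ode_field(params: ParameterVector, u: np.ndarray) -> np.ndarray:
    """du/dt = f(S u - b), activation applied elementwise."""
    f, _ = ACTIVATIONS[params.spec.activation]
    return f(params.S @ u - params.b)


def node_field(params: ParameterVector, u: np.ndarray) -> np.ndarray:
    """du/dt = W2 f(W1 u + b1) + b2; no activation on the output layer."""
    f, _ = ACTIVATIONS[params.spec.activation]
    return params.W2 @ f(params.W1 @ u + params.b1) + params.b2


def field(params: ParameterVector, u: np.ndarray) -> np.ndarray:
    """Dispatch on the family."""
    u = np.asarray(u, dtype=float)
    if u.shape != (params.spec.n,):
        raise ValueError(f"state must have shape ({params.spec.n},), got {u.shape}")
    if params.spec.family == "ode":
        return ode_field(params, u)
    return node_field(params, u)


def jac_u(params: ParameterVector, u: np.ndarray) -> np.ndarray:
    """d(du/dt)/du, shape (n, n)."""
    _, fp = ACTIVATIONS[params.spec.activation]
    if params.spec.family == "ode":
        z = params.S @ u - params.b
        return fp(z)[:, None] * params.S
    a = params.W1 @ u + params.b1
    return params.W2 @ (fp(a)[:, None] * params.W1)


def jac_theta(params: ParameterVector, u: np.ndarray) -> np.ndarray:
    """d(du/dt)/dtheta in flat order, shape (n, P)."""
    spec = params.spec
    n = spec.n
    P = count_parameters(spec)
    _, fp = ACTIVATIONS[spec.activation]
    J = np.zeros((n, P))
    if spec.family == "ode":
        z = params.S @ u - params.b
        g = fp(z)
        for i in range(n):
            J[i, i * n : (i + 1) * n] = g[i] * u
            J[i, n * n + i] = -g[i]
        return J
    N = spec.N
    f, _ = ACTIVATIONS[spec.activation]
    a = params.W1 @ u + params.b1
    h = f(a)
    g = fp(a)  # (N,)
    W2 = params.W2
    o1, o2, o3, _ = N * n, N * n + N, N * n + N + n * N, P
    # dF_i/dW1[k,l] = W2[i,k] g[k] u[l]; dF_i/db1[k] = W2[i,k] g[k]
    Wg = W2 * g[None, :]  # (n, N)
    J[:, :o1] = (Wg[:, :, None] * u[None, None, :]).reshape(n, N * n)
    J[:, o1:o2] = Wg
    # dF_i/dW2[k,l] = delta_ik h[l]; dF_i/db2[k] = delta_ik
    for i in range(n):
        J[i, o2 + i * N : o2 + (i + 1) * N] = h
        J[i, o3 + i] = 1.0
    return J
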