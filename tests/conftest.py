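import numpy as np
import pytest

from nodefit import models, preprocess, synthetic_data, trajectory
from nodefit.series import SmoothedSeries

# fast non-stiff solves dominate the suite; the stiff defaults are exercised
# explicitly in test_trajectory
FAST_SOLVER = trajectory.SolverConfig(method="LSODA")


@pytest.fixture(scope="session")
def lv_raw():
    """Noise-free Lotka–Volterra fixture: 91 yearly points, 2 species."""
    return synthetic_data.simulate_lv(synthetic_data.default_params())


@pytest.fixture(scope="session")
def lv_target(lv_raw):
    """Smoothed fitting target from the noise-free fixture (181 points)."""
    return preprocess.preprocess(lv_raw, sigma=1.0)


@pytest.fixture(scope="session")
def rotation_target():
    """Noise-free target generated from a known n=2 ODE (S, b).

    The true field du/dt = tanh(S u - b) with S = [[0, 1], [-1, 0]], b = 0
    traces a gentle rotation; solved tightly so the target is effectively
    exact.
    """
    spec = models.ModelSpec("ode", n=2, n_obs=2)
    flat = np.array([0.0, 1.0, -1.0, 0.0, 0.0, 0.0])
    pv = models.ParameterVector(spec, flat)
    times = np.linspace(0.0, 8.0, 17)
    traj = trajectory.solve(
        pv,
        np.array([0.5, 0.0]),
        times,
        trajectory.SolverConfig(method="LSODA", rtol=1e-10, atol=1e-12),
    )
    return SmoothedSeries(times, traj.states, ["x", "y"]), pv
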