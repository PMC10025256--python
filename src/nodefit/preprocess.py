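"""Raw series -> smoothed fitting target.

Deterministic models can only track trends, and the optimizer benefits from
a smooth loss surface, so the raw counts are transformed before fitting:

1. natural log, then per-variable mean-centering (``log_center``);
2. one interpolated point between each pair of observations, from a natural
   cubic spline per variable (``insert_midpoints``) — a T-point series
   becomes 2T-1 points (91 yearly observations -> 181 half-yearly targets);
3. Gaussian smoothing on the augmented grid (``gaussian_smooth``).

``preprocess`` composes the three, recording the subtracted log means and
the filter width so trajectories can be mapped back to abundances.
Midpoints are inserted on the log-centered scale, i.e. after the transform.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.interpolate import CubicSpline

from .series import RawSeries, SmoothedSeries

__all__ = [
    "log_center",
    "insert_midpoints",
    "gaussian_smooth",
    "gaussian_kernel",
    "preprocess",
    "DEFAULT_SIGMA",
]

#: Default Gaussian filter width, in units of the augmented (half-step) grid.
DEFAULT_SIGMA = 1.0


def log_center(series: RawSeries) -> tuple[RawSeries, np.ndarray]:
    """Log-transform and subtract the per-variable mean of the logs.

    Returns the working-scale series and the vector of subtracted means
    (log units).  Each output column has mean zero to machine precision.
    """
    bad = np.argwhere(series.values <= 0)
    if bad.size:
        t, v = bad[0]
        raise ValueError(
            f"non-positive value for variable '{series.names[v]}' "
            f"at time {series.times[t]:g}: log transform undefined"
        )
    logs = np.log(series.values)
    means = logs.mean(axis=0)
    return RawSeries(series.times, logs - means, series.names), means


def insert_midpoints(series: RawSeries) -> RawSeries:
    """Insert one cubic-spline midpoint between each pair of observations.

    Values at the original times are kept exactly; midpoints (arithmetic
    mean of adjacent times, so the grid need not be uniform) come from a
    natural cubic spline fitted per variable.  T points become 2T-1.
    """
    T = series.n_points
    if T < 4:
        raise ValueError(f"need at least 4 points for a cubic spline, got {T}")
    mids = 0.5 * (series.times[:-1] + series.times[1:])
    out_times = np.empty(2 * T - 1)
    out_times[0::2] = series.times
    out_times[1::2] = mids
    out_values = np.empty((2 * T - 1, series.n_vars))
    out_values[0::2] = series.values
    for v in range(series.n_vars):
        spline = CubicSpline(series.times, series.values[:, v], bc_type="natural")
        out_values[1::2, v] = spline(mids)
    return RawSeries(out_times, out_values, series.names)


def gaussian_kernel(sigma: float) -> np.ndarray:
    """Normalized discrete Gaussian weights truncated at radius ceil(4*sigma)."""
    if sigma <= 0:
        return np.ones(1)
    radius = max(1, math.ceil(4.0 * sigma))
    k = np.arange(-radius, radius + 1)
    w = np.exp(-0.5 * (k / sigma) ** 2)
    return w / w.sum()


def _smooth_columns(values: np.ndarray, sigma: float) -> np.ndarray:
    """Convolve each column with the Gaussian kernel.

    Boundaries use the truncated kernel renormalized over the in-range
    support, so no padding values are invented and a constant column stays
    exactly constant.
    """
    if sigma == 0:
        return values.copy()
    w = gaussian_kernel(sigma)
    ones = np.ones(values.shape[0])
    norm = np.convolve(ones, w, mode="same")
    out = np.empty_like(values)
    for v in range(values.shape[1]):
        out[:, v] = np.convolve(values[:, v], w, mode="same") / norm
    return out


def gaussian_smooth(series: RawSeries, sigma: float) -> RawSeries:
    """Gaussian-filter each column; sigma is in grid-spacing units.

    sigma = 0 is the identity.
    """
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    return RawSeries(series.times, _smooth_columns(series.values, sigma), series.names)


def preprocess(series: RawSeries, sigma: float = DEFAULT_SIGMA) -> SmoothedSeries:
    """log-center -> insert midpoints -> Gaussian smooth; keep the metadata."""
    centered, log_means = log_center(series)
    augmented = insert_midpoints(centered)
    smoothed = gaussian_smooth(augmented, sigma)
    return SmoothedSeries(
        smoothed.times,
        smoothed.values,
        smoothed.names,
        log_means=log_means,
        smoothing_sigma=sigma,
    )
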