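"""Time-series containers and their CSV dialect.

Two containers travel through the pipeline: :class:`RawSeries` holds values
on whatever scale they were produced (abundances, or log-centered values),
and :class:`SmoothedSeries` is the fitting target — log-transformed,
mean-centered, midpoint-augmented and Gaussian-smoothed — together with the
transform metadata needed to map model trajectories back to abundances.

CSV dialect: a header row ``time,<var1>,<var2>,...``, times in the first
column, one column per variable, floats, UTF-8, no index column.  A smoothed
series written to CSV carries a YAML sidecar (``<name>.meta.yaml``) with the
per-variable log means and the smoothing width.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "RawSeries",
    "SmoothedSeries",
    "SeriesParseError",
    "read_csv",
    "write_csv",
    "read_smoothed",
    "write_smoothed",
]


class SeriesParseError(ValueError):
    """Raised when a series file violates the CSV dialect."""


def _validate(times: np.ndarray, values: np.ndarray, names: list[str]) -> None:
    if times.ndim != 1:
        raise ValueError("times must be one-dimensional")
    if values.ndim != 2:
        raise ValueError("values must be a T x V matrix")
    if values.shape[0] != times.shape[0]:
        raise ValueError(
            f"times ({times.shape[0]}) and values ({values.shape[0]} rows) disagree"
        )
    if len(names) != values.shape[1]:
        raise ValueError("one name per variable column required")
    if times.shape[0] >= 2 and not np.all(np.diff(times) > 0):
        raise ValueError("times must be strictly increasing")
    if not np.all(np.isfinite(times)) or not np.all(np.isfinite(values)):
        raise ValueError("times and values must be finite")


@dataclass
class RawSeries:
    """An observed (or transformed) multivariate time series.

    Attributes
    ----------
    times : (T,) strictly increasing time grid, in years.
    values : (T, V) matrix, one column per variable.
    names : V variable labels.
    """

    times: np.ndarray
    values: np.ndarray
    names: list[str]

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim == 1:
            self.values = self.values[:, None]
        self.names = list(self.names)
        _validate(self.times, self.values, self.names)

    @property
    def n_points(self) -> int:
        return self.times.shape[0]

    @property
    def n_vars(self) -> int:
        return self.values.shape[1]


@dataclass
class SmoothedSeries:
    """The fitting target on the working (log-centered, smoothed) scale.

    ``times`` is the midpoint-augmented grid (2T-1 points for a T-point
    input); ``log_means`` are the per-variable means subtracted on the log
    scale, needed to back-transform trajectories to abundances;
    ``smoothing_sigma`` is the Gaussian filter width in augmented-grid units.
    """

    times: np.ndarray
    values: np.ndarray
    names: list[str]
    log_means: np.ndarray = field(default_factory=lambda: np.zeros(0))
    smoothing_sigma: float = 0.0

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim == 1:
            self.values = self.values[:, None]
        self.names = list(self.names)
        self.log_means = np.asarray(self.log_means, dtype=float)
        _validate(self.times, self.values, self.names)
        if self.log_means.size == 0:
            self.log_means = np.zeros(self.values.shape[1])
        if self.log_means.shape[0] != self.values.shape[1]:
            raise ValueError("one log mean per variable required")

    @property
    def n_points(self) -> int:
        return self.times.shape[0]

    @property
    def n_vars(self) -> int:
        return self.values.shape[1]

    def to_abundance(self) -> RawSeries:
        """Back-transform to the original abundance scale."""
        return RawSeries(
            self.times, np.exp(self.values + self.log_means), self.names
        )


def write_csv(series: RawSeries | SmoothedSeries, path: str | Path) -> None:
    """Write a series in the package CSV dialect (full float precision)."""
    df = pd.DataFrame(series.values, columns=series.names)
    df.insert(0, "time", series.times)
    df.to_csv(path, index=False, float_format="%.17g")


def read_csv(path: str | Path) -> RawSeries:
    """Read a series written by :func:`write_csv`.

    Raises
    ------
    SeriesParseError
        On a missing/invalid header, non-numeric cells (named by line), or
        non-monotone times.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except Exception as exc:  # malformed CSV structure
        raise SeriesParseError(f"{path}: cannot parse CSV ({exc})") from exc
    if df.shape[1] < 2 or df.columns[0] != "time":
        raise SeriesParseError(
            f"{path}: header must start with a 'time' column, got {list(df.columns)}"
        )
    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            # +2: header line and 1-based numbering
            line = int(np.nonzero(bad.to_numpy())[0][0]) + 2
            raise SeriesParseError(
                f"{path}: non-numeric value in column '{col}' at line {line}"
            )
        df[col] = coerced
    if df.isna().any().any():
        raise SeriesParseError(f"{path}: missing values are not supported")
    times = df["time"].to_numpy(dtype=float)
    if times.size >= 2 and not np.all(np.diff(times) > 0):
        line = int(np.nonzero(np.diff(times) <= 0)[0][0]) + 3
        raise SeriesParseError(f"{path}: times not strictly increasing at line {line}")
    return RawSeries(times, df.iloc[:, 1:].to_numpy(dtype=float), list(df.columns[1:]))


def write_smoothed(series: SmoothedSeries, path: str | Path) -> None:
    """Write a smoothed series plus its metadata sidecar."""
    path = Path(path)
    write_csv(series, path)
    meta = {
        "log_means": [float(x) for x in series.log_means],
        "smoothing_sigma": float(series.smoothing_sigma),
        "names": list(series.names),
    }
    path.with_suffix(path.suffix + ".meta.yaml").write_text(
        yaml.safe_dump(meta), encoding="utf-8"
    )


def read_smoothed(path: str | Path) -> SmoothedSeries:
    """Read a smoothed series and its metadata sidecar."""
    path = Path(path)
    raw = read_csv(path)
    meta_path = path.with_suffix(path.suffix + ".meta.yaml")
    if not meta_path.exists():
        raise SeriesParseError(f"missing metadata sidecar: {meta_path}")
    meta = yaml.safe_load(meta_path.read_text(encoding="utf-8"))
    return SmoothedSeries(
        raw.times,
        raw.values,
        raw.names,
        log_means=np.asarray(meta["log_means"], dtype=float),
        smoothing_sigma=float(meta["smoothing_sigma"]),
    )
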