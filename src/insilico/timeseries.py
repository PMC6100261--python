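"""Equispaced multi-species time series and their CSV dialect.

A :class:`TimeSeries` holds either an *ideal* (model-calculated) series or a
*noisy* one (ideal plus superposed measurement error); the ``is_noisy`` flag
distinguishes the two.  Sampling times are ``t_i = t0 + i * dt`` and must be
exactly equispaced — correlated-error generation relies on a single lag-one
correlation coefficient, which only exists on a uniform grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

#: Column order used for transesterification series.
TRANSESTER_SPECIES = ("TG", "DG", "MG", "GL", "MeOH", "E1", "E2", "E3")

#: Tolerance (s) on grid equispacing.
GRID_ATOL = 1e-9

TIME_COLUMN = "time_s"


class TimeSeriesError(ValueError):
    """Raised for malformed series or files (message carries the line/row)."""


@dataclass(frozen=True)
class TimeSeries:
    """Concentration-versus-time data on a uniform sampling grid.

    Parameters
    ----------
    t0 : float
        Time origin in seconds.
    dt : float
        Sampling interval in seconds, > 0 (ignored and may be 0 only for a
        single-row series).
    species_names : tuple of str
        Ordered column labels, e.g. ``("TG", "DG", ...)``.
    values : ndarray, shape (n_times, n_species)
        Concentrations in mol/L; one row per sampling time.
    is_noisy : bool
        False for the ideal model output p_i, True once measurement error
        has been superposed (M_i = p_i + X_i).
    """

    t0: float
    dt: float
    species_names: tuple[str, ...]
    values: np.ndarray
    is_noisy: bool = False

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 2:
            raise TimeSeriesError(f"values must be 2-D, got shape {values.shape}")
        if values.shape[0] < 1:
            raise TimeSeriesError("a series needs at least one time point")
        if values.shape[1] != len(self.species_names):
            raise TimeSeriesError(
                f"{len(self.species_names)} species names but "
                f"{values.shape[1]} value columns"
            )
        if values.shape[0] > 1 and not self.dt > 0:
            raise TimeSeriesError(f"dt must be positive, got {self.dt}")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "species_names", tuple(self.species_names))

    @property
    def n_times(self) -> int:
        return self.values.shape[0]

    @property
    def n_species(self) -> int:
        return self.values.shape[1]

    @property
    def times(self) -> np.ndarray:
        return self.t0 + self.dt * np.arange(self.n_times)

    def column(self, name: str) -> np.ndarray:
        try:
            j = self.species_names.index(name)
        except ValueError:
            raise KeyError(f"no species named {name!r}") from None
        return self.values[:, j]

    def with_values(self, values: np.ndarray, *, is_noisy: bool) -> "TimeSeries":
        """Same grid and labels, new values (used by the noise engine)."""
        return TimeSeries(self.t0, self.dt, self.species_names, values, is_noisy)

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(self.values, columns=list(self.species_names))
        frame.insert(0, TIME_COLUMN, self.times)
        return frame


def _validate_grid(times: np.ndarray, source: str) -> tuple[float, float]:
    """Check strict increase and equispacing; return (t0, dt)."""
    if times.size == 1:
        return float(times[0]), 0.0
    steps = np.diff(times)
    if np.any(steps <= 0):
        i = int(np.argmax(steps <= 0))
        raise TimeSeriesError(
            f"{source}: times not strictly increasing at row {i + 2} "
            f"(t={times[i + 1]!r} after t={times[i]!r})"
        )
    dt = float(steps[0])
    bad = np.abs(steps - dt) > GRID_ATOL
    if np.any(bad):
        i = int(np.argmax(bad))
        raise TimeSeriesError(
            f"{source}: non-equispaced sampling at row {i + 2} "
            f"(step {steps[i]!r}, expected {dt!r})"
        )
    return float(times[0]), dt


def from_arrays(
    times: np.ndarray,
    values: np.ndarray,
    species_names: tuple[str, ...],
    *,
    is_noisy: bool = False,
) -> TimeSeries:
    """Build a TimeSeries from an explicit time vector, validating the grid."""
    times = np.asarray(times, dtype=float)
    t0, dt = _validate_grid(times, "time vector")
    return TimeSeries(t0, dt, species_names, np.asarray(values, float), is_noisy)


def read_timeseries(path: str | Path, *, is_noisy: bool = False) -> TimeSeries:
    """Read a series from the package CSV dialect.

    Header ``time_s,<name>,...``; comma-separated; concentrations in mol/L.
    Non-numeric cells, ragged rows, unsorted or non-equispaced times are
    rejected with the offending line number.
    """
    path = Path(path)
    try:
        frame = pd.read_csv(path, sep=",", header=0)
    except pd.errors.ParserError as exc:  # ragged rows etc.
        raise TimeSeriesError(f"{path}: {exc}") from exc
    if frame.shape[1] < 2 or frame.columns[0] != TIME_COLUMN:
        raise TimeSeriesError(
            f"{path}: header must start with '{TIME_COLUMN}' and have at least "
            f"one value column, got {list(frame.columns)!r}"
        )
    numeric = frame.apply(pd.to_numeric, errors="coerce")
    if numeric.isna().any().any():
        row = int(np.argmax(numeric.isna().any(axis=1).to_numpy()))
        raise TimeSeriesError(f"{path}: non-numeric cell at line {row + 2}")
    times = numeric.iloc[:, 0].to_numpy(float)
    t0, dt = _validate_grid(times, str(path))
    return TimeSeries(
        t0=t0,
        dt=dt,
        species_names=tuple(frame.columns[1:]),
        values=numeric.iloc[:, 1:].to_numpy(float),
        is_noisy=is_noisy,
    )


def write_timeseries(series: TimeSeries, path: str | Path) -> None:
    """Write in the CSV dialect; read ∘ write round-trips to ~1e-12 relative."""
    series.to_frame().to_csv(path, index=False, float_format="%.17g")
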