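"""Uniform time grids and concentration curves.

All kinetic quantities in this package live on a uniform time grid in
minutes.  The canonical acquisition grid is 120 samples spaced 0.5 s
(1/120 min) apart, i.e. one minute of dynamic imaging at two frames per
second, which covers the first pass and the early recirculation of a
contrast bolus.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Canonical frame spacing: 0.5 s expressed in minutes.
DEFAULT_DT_MIN = 0.5 / 60.0
#: Canonical number of dynamic frames.
DEFAULT_N_POINTS = 120


@dataclass(frozen=True)
class TimeGrid:
    """Uniformly spaced sample times in minutes, starting at 0."""

    n_points: int = DEFAULT_N_POINTS
    dt: float = DEFAULT_DT_MIN

    def __post_init__(self) -> None:
        if self.n_points < 2:
            raise ValueError("a time grid needs at least 2 points")
        if self.dt <= 0:
            raise ValueError("time step must be positive")

    @property
    def values(self) -> np.ndarray:
        return np.arange(self.n_points) * self.dt

    @property
    def duration(self) -> float:
        return (self.n_points - 1) * self.dt

    @classmethod
    def from_times(cls, times: np.ndarray, rtol: float = 1e-6) -> "TimeGrid":
        """Build a grid from explicit sample times, checking uniformity."""
        times = np.asarray(times, dtype=float)
        if times.ndim != 1 or times.size < 2:
            raise ValueError("times must be a 1-D array with >= 2 samples")
        steps = np.diff(times)
        dt = steps.mean()
        if dt <= 0 or not np.allclose(steps, dt, rtol=rtol, atol=rtol * abs(dt)):
            raise ValueError("times are not uniformly spaced")
        if abs(times[0]) > rtol * dt:
            raise ValueError("grid must start at t = 0")
        return cls(n_points=times.size, dt=float(dt))


@dataclass
class ConcentrationCurve:
    """A sampled concentration (or signal) time course on a :class:`TimeGrid`.

    ``values`` holds gadolinium concentration in mM for kinetic curves; the
    same container is reused for signal-intensity curves (arbitrary units).
    """

    grid: TimeGrid
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.grid.n_points,):
            raise ValueError(
                f"curve has {self.values.shape} values for a "
                f"{self.grid.n_points}-point grid"
            )

    @property
    def peak(self) -> float:
        """Maximum sample value (the discrete curve peak)."""
        return float(self.values.max())

    @property
    def peak_time(self) -> float:
        return float(self.grid.values[int(np.argmax(self.values))])

    def copy(self) -> "ConcentrationCurve":
        return ConcentrationCurve(self.grid, self.values.copy())
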