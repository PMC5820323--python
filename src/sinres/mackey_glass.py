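"""Mackey-Glass teacher series.

The Mackey-Glass system is a scalar delay differential equation originally
proposed as a model of blood-cell regulation; with delay ``tau_m = 17`` it is
a standard chaotic benchmark for one-step and free-run time-series
prediction.  This module generates the series with the time-discrete map

    y[n+1] = y[n] + dt * (0.2 * y_tau / (1 + y_tau**10) - 0.1 * y[n]),

where ``y_tau`` is the value ``tau_m / dt`` iterations in the past.  The map
is iterated at stepsize ``dt`` and every ``subsample``-th iterate is
retained, so one retained sample spans ``dt * subsample`` Mackey-Glass time
units (exactly 1 at the defaults).  The retained series is shifted to
oscillate around zero before being used as a teacher signal.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

__all__ = [
    "MGConfig",
    "MGSeries",
    "generate_mg",
    "center",
    "save_series",
    "load_series",
]


@dataclass(frozen=True)
class MGConfig:
    """Parameters of the discrete Mackey-Glass generator.

    Attributes
    ----------
    tau_m : float
        Feedback delay in Mackey-Glass time units.
    stepsize : float
        Integration step of the discrete map, in the same time units.
    subsample : int
        Keep every ``subsample``-th iterate.
    length : int
        Number of retained samples returned.
    history_value : float
        Constant value filling the initial delay buffer.
    transient : int
        Number of retained samples discarded before output.
    """

    tau_m: float = 17.0
    stepsize: float = 0.1
    subsample: int = 10
    length: int = 5000
    history_value: float = 1.2
    transient: int = 1000

    def __post_init__(self) -> None:
        if self.tau_m <= 0:
            raise ValueError("tau_m must be positive")
        if not 0 < self.stepsize < 1:
            raise ValueError("stepsize must lie in (0, 1)")
        if self.subsample < 1:
            raise ValueError("subsample must be >= 1")
        if self.transient < 0:
            raise ValueError("transient must be >= 0")
        if self.length <= 0:
            raise ValueError("length must be positive")
        lag = self.tau_m / self.stepsize
        if abs(lag - round(lag)) > 1e-9:
            raise ValueError(
                f"delay buffer length tau_m/stepsize = {lag} is not an integer"
            )

    @property
    def delay_steps(self) -> int:
        """Delay buffer length in map iterations (170 at defaults)."""
        return int(round(self.tau_m / self.stepsize))

    @property
    def increment_units(self) -> float:
        """Mackey-Glass time units spanned by one retained sample."""
        return self.stepsize * self.subsample


@dataclass
class MGSeries:
    """A retained Mackey-Glass sample sequence with sampling metadata."""

    values: np.ndarray
    centered: bool = False
    increment_units: float = 1.0
    config: MGConfig | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("values must be one-dimensional")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("values must be finite")
        if self.centered and len(self.values):
            scale = max(self.values.std(), 1.0)
            if abs(self.values.mean()) > 1e-12 * scale:
                raise ValueError("centered series has nonzero mean")

    def __len__(self) -> int:
        return len(self.values)


def generate_mg(config: MGConfig) -> MGSeries:
    """Iterate the discrete Mackey-Glass map and return the retained series.

    The delay buffer is filled with ``config.history_value``; the first
    ``config.transient`` retained samples are discarded.  The returned series
    is uncentered.

    Raises
    ------
    FloatingPointError
        If the iteration overflows or produces a NaN (the message names the
        failing iteration index).
    """
    lag = config.delay_steps
    n_iter = (config.length + config.transient) * config.subsample
    buf = np.empty(lag + 1 + n_iter)
    buf[: lag + 1] = config.history_value
    dt = config.stepsize
    for n in range(lag, lag + n_iter):
        y = buf[n]
        y_tau = buf[n - lag]
        buf[n + 1] = y + dt * (0.2 * y_tau / (1.0 + y_tau**10) - 0.1 * y)
        if not np.isfinite(buf[n + 1]):
            raise FloatingPointError(
                f"Mackey-Glass iteration diverged at step {n - lag + 1}"
            )
    kept = buf[lag + config.subsample :: config.subsample][
        : config.length + config.transient
    ]
    values = kept[config.transient :].copy()
    return MGSeries(
        values=values,
        centered=False,
        increment_units=config.increment_units,
        config=config,
    )


def center(series: MGSeries) -> MGSeries:
    """Shift a series to oscillate around zero (idempotent)."""
    if len(series) == 0:
        raise ValueError("cannot center an empty series")
    return MGSeries(
        values=series.values - series.values.mean(),
        centered=True,
        increment_units=series.increment_units,
        config=series.config,
    )


def save_series(series: MGSeries, csv_path: str | Path) -> None:
    """Write a series as a single-column CSV plus a JSON sidecar."""
    csv_path = Path(csv_path)
    np.savetxt(csv_path, series.values, header="value", comments="")
    meta = {
        "centered": series.centered,
        "increment_units": series.increment_units,
        "config": asdict(series.config) if series.config else None,
    }
    csv_path.with_suffix(".json").write_text(json.dumps(meta, indent=2))


def load_series(csv_path: str | Path) -> MGSeries:
    """Read a series written by :func:`save_series`, re-validating invariants."""
    csv_path = Path(csv_path)
    values = np.loadtxt(csv_path, skiprows=1)
    meta = json.loads(csv_path.with_suffix(".json").read_text())
    config = MGConfig(**meta["config"]) if meta.get("config") else None
    return MGSeries(
        values=np.atleast_1d(values),
        centered=meta["centered"],
        increment_units=meta["increment_units"],
        config=config,
    )
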