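"""Linear readout training, closed-loop prediction, and output diagnostics.

The output layer is y_out[n] = tanh(w_out . x[n]); only w_out is trained.
The tanh keeps the free-running output bounded at large mu.  Because the
centered teacher lies strictly inside (-1, 1), the nonlinear least-squares
problem

    min_w || tanh(w . x[n]) - y[n] ||

is solved exactly by regressing atanh(y[n]) on the states with the SVD
pseudoinverse; errors are then reported through the tanh output.

Closed-loop (free-run) prediction replaces the teacher input with the
network's own output, scaled by alpha exactly as the teacher was, and runs
for a fixed horizon; the autonomous amplitude-variation index sigma_alpha0
instead switches the input off entirely and measures how much output
variance the trained weights let through — i.e. how well learning has
suppressed the network's spontaneous dynamics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .mackey_glass import MGSeries
from .reservoir import ReservoirConfig, ReservoirWeights, StateTrajectory, run, step

__all__ = [
    "TrainingConfig",
    "ReadoutWeights",
    "PredictionResult",
    "train_readout",
    "nmse",
    "predict_closed_loop",
    "sigma_alpha0",
    "variance_ratio",
]


@dataclass(frozen=True)
class TrainingConfig:
    """Teacher length, washout, free-run horizon and sigma windowing."""

    n_train: int = 2000
    alpha: float = 0.8
    washout: int = 100
    horizon: int = 35
    sigma_discard: int = 10
    sigma_window: int = 25

    def __post_init__(self) -> None:
        if not self.n_train > self.washout >= 0:
            raise ValueError("need n_train > washout >= 0")
        if self.horizon != self.sigma_discard + self.sigma_window:
            raise ValueError("horizon must equal sigma_discard + sigma_window")


@dataclass
class ReadoutWeights:
    """Trained output vector with its training residual."""

    w_out: np.ndarray
    training_nmse: float
    effective_rank: int


@dataclass
class PredictionResult:
    """Free-run output, aligned truth and the resulting NMSE."""

    free_run: np.ndarray
    truth: np.ndarray
    nmse: float
    mu: float
    seed: int
    diverged: bool = False


def nmse(output, target) -> float:
    """Mean squared error normalized by the population variance of the target."""
    output = np.asarray(output, dtype=float).ravel()
    target = np.asarray(target, dtype=float).ravel()
    if len(output) != len(target) or len(target) == 0:
        raise ValueError("output and target must have equal nonzero lengths")
    var = target.var()
    if var == 0:
        raise ValueError("target is constant; NMSE undefined")
    return float(np.mean((output - target) ** 2) / var)


def train_readout(
    traj: StateTrajectory, targets: MGSeries | np.ndarray, tc: TrainingConfig
) -> ReadoutWeights:
    """Fit w_out by SVD pseudoinverse on the post-washout training block.

    Row ``t`` of the trajectory is paired with teacher sample ``t`` (the
    update producing row ``t`` consumed sample ``t - 1``).
    """
    y = targets.values if isinstance(targets, MGSeries) else np.asarray(targets, float)
    n = min(len(traj.states), tc.n_train)
    if len(y) < n:
        raise ValueError("teacher shorter than the training block")
    if np.max(np.abs(y[: n])) >= 1:
        raise ValueError("targets must lie strictly inside (-1, 1) for the tanh readout")
    A = traj.states[tc.washout : n]
    z = np.arctanh(y[tc.washout : n])
    w_out, _, rank, _ = np.linalg.lstsq(A, z, rcond=None)
    fitted = np.tanh(A @ w_out)
    return ReadoutWeights(
        w_out=w_out,
        training_nmse=nmse(fitted, y[tc.washout : n]),
        effective_rank=int(rank),
    )


def _teacher_force(
    w: ReservoirWeights,
    c: ReservoirConfig,
    teacher: MGSeries,
    n_train: int,
) -> StateTrajectory:
    return run(w, c, teacher, n_steps=n_train)


def predict_closed_loop(
    w: ReservoirWeights,
    ro: ReadoutWeights,
    c: ReservoirConfig,
    tc: TrainingConfig,
    teacher: MGSeries,
    traj: StateTrajectory | None = None,
) -> PredictionResult:
    """Teacher-force through the training block, then free-run the horizon.

    During the free run, the input consumed at each step is the network's
    own previous output (scaled by alpha like the teacher was).  Saturation
    of the tanh output (|y_out| > 0.999) for more than half the horizon
    flags divergence; the NMSE is reported regardless.
    """
    y = teacher.values
    if len(y) < tc.n_train + tc.horizon:
        raise ValueError("teacher too short for training block plus horizon")
    if traj is None:
        traj = _teacher_force(w, c, teacher, tc.n_train)
    act_cfg = c.with_alpha(tc.alpha)
    x = traj.states[-1].copy()
    u = float(np.tanh(ro.w_out @ x))
    free = np.empty(tc.horizon)
    saturated = 0
    max_sat = 0
    for h in range(tc.horizon):
        x = step(x, u, w, act_cfg)
        u = float(np.tanh(ro.w_out @ x))
        free[h] = u
        saturated = saturated + 1 if abs(u) > 0.999 else 0
        max_sat = max(max_sat, saturated)
    truth = y[tc.n_train : tc.n_train + tc.horizon]
    return PredictionResult(
        free_run=free,
        truth=truth.copy(),
        nmse=nmse(free, truth),
        mu=c.mu,
        seed=w.seed,
        diverged=max_sat > tc.horizon // 2,
    )


def variance_ratio(outputs, reference) -> float:
    """Squared ratio of standard deviations, sigma(outputs)^2 / sigma(ref)^2."""
    outputs = np.asarray(outputs, dtype=float)
    reference = np.asarray(reference, dtype=float)
    ref_sd = reference.std()
    if ref_sd == 0:
        raise ValueError("reference window has zero variance")
    return float((outputs.std() / ref_sd) ** 2)


def sigma_alpha0(
    w: ReservoirWeights,
    ro: ReadoutWeights,
    c: ReservoirConfig,
    tc: TrainingConfig,
    teacher: MGSeries,
    traj: StateTrajectory | None = None,
) -> float:
    """Autonomous output amplitude variation of the trained readout.

    Continue from the post-training state with the input switched off
    (alpha = 0, no feedback), read out for ``horizon`` steps, drop the first
    ``sigma_discard`` as transient, and return the squared ratio of the
    remaining output standard deviation to that of the aligned teacher
    continuation.  Near zero means learning has silenced the spontaneous
    network dynamics in the output.
    """
    y = teacher.values
    if len(y) < tc.n_train + tc.horizon:
        raise ValueError("teacher too short for training block plus horizon")
    if traj is None:
        traj = _teacher_force(w, c, teacher, tc.n_train)
    auto_cfg = c.with_alpha(0.0)
    x = traj.states[-1].copy()
    outs = np.empty(tc.horizon)
    for h in range(tc.horizon):
        x = step(x, 0.0, w, auto_cfg)
        outs[h] = np.tanh(ro.w_out @ x)
    ref = y[tc.n_train + tc.sigma_discard : tc.n_train + tc.horizon]
    return variance_ratio(outs[tc.sigma_discard :], ref)
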