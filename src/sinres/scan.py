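"""Orchestration of mu-scans with realization averaging.

A scan repeats, for every mu on a grid and every weight realization: build
the network, teacher-force it on the (single, deterministic) Mackey-Glass
series, train the readout, and measure the requested complexity indices —
closed-loop prediction NMSE, the autonomous output variation sigma_alpha0,
driven and autonomous synchronization errors, the mutual-information sum C,
the network's maximal Lyapunov exponent and the autonomous regime label.
Rows are aggregated per mu with mean, standard deviation and standard
error.  Every cell derives its own seed from (base_seed, mu index,
realization index), so refining the grid never reshuffles existing cells.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dynamics import (
    EmbeddingParams,
    classify_regime,
    estimate_delay,
    group_windows,
    network_lyapunov,
    sync_error,
    RegimeLabel,
)
from .information import memory_capacity
from .mackey_glass import MGConfig, MGSeries, center, generate_mg
from .readout import TrainingConfig, predict_closed_loop, sigma_alpha0, train_readout
from .reservoir import ReservoirConfig, StateTrajectory, build_weights, run

logger = logging.getLogger("sinres.scan")

ALL_METRICS = ("nmse", "sigma", "delta", "capacity", "lyapunov")

__all__ = ["ScanConfig", "ScanResult", "run_scan", "detect_windows", "cell_seed"]


@dataclass(frozen=True)
class ScanConfig:
    """Grid, averaging depth and sub-configurations of a mu-scan."""

    mu_grid: tuple = tuple(np.round(np.arange(0.1, 10.01, 0.1), 3))
    n_realizations: int = 10
    base_seed: int = 0
    metrics: tuple = ALL_METRICS
    training: TrainingConfig = field(default_factory=TrainingConfig)
    reservoir: ReservoirConfig = field(default_factory=ReservoirConfig)
    mg: MGConfig = field(default_factory=lambda: MGConfig(length=2100))
    autonomous_transient: int = 1000
    autonomous_samples: int = 200

    def __post_init__(self) -> None:
        if self.n_realizations < 1:
            raise ValueError("n_realizations must be >= 1")
        grid = np.asarray(self.mu_grid, dtype=float)
        if grid.size == 0 or not np.all(np.diff(grid) > 0):
            raise ValueError("mu_grid must be nonempty and strictly increasing")
        unknown = set(self.metrics) - set(ALL_METRICS)
        if unknown:
            raise ValueError(f"unknown metrics: {sorted(unknown)}")
        if self.mg.length < self.training.n_train + self.training.horizon:
            raise ValueError("MG series shorter than training block plus horizon")


@dataclass
class ScanResult:
    """Raw per-(mu, realization) rows and per-mu summary statistics."""

    rows: pd.DataFrame
    summary: pd.DataFrame
    config: ScanConfig
    labels_by_mu: list[RegimeLabel] = field(default_factory=list)


def cell_seed(base_seed: int, mu_index: int, realization: int) -> int:
    """Stable per-cell seed below 2**31."""
    ss = np.random.SeedSequence([int(base_seed), int(mu_index), int(realization)])
    return int(ss.generate_state(1)[0] % (2**31))


def _cell(
    cfg: ScanConfig, teacher: MGSeries, mu: float, mu_index: int, realization: int
) -> dict:
    tc = cfg.training
    seed = cell_seed(cfg.base_seed, mu_index, realization)
    rc = ReservoirConfig(
        n_nodes=cfg.reservoir.n_nodes,
        mu=float(mu),
        offset_b=cfg.reservoir.offset_b,
        alpha=tc.alpha,
        connectivity=cfg.reservoir.connectivity,
        activation=cfg.reservoir.activation,
        seed=seed,
    )
    row: dict = {"mu": float(mu), "seed": seed, "realization": realization, "error": ""}
    t0 = time.perf_counter()
    weights = build_weights(rc)
    need_driven = {"nmse", "sigma", "delta", "capacity"} & set(cfg.metrics)
    traj = None
    if need_driven:
        traj = run(weights, rc, teacher, n_steps=tc.n_train)
    if {"nmse", "sigma"} & set(cfg.metrics):
        readout = train_readout(traj, teacher, tc)
        row["training_nmse"] = readout.training_nmse
        if "nmse" in cfg.metrics:
            pred = predict_closed_loop(weights, readout, rc, tc, teacher, traj=traj)
            row["nmse"] = pred.nmse
            row["diverged"] = pred.diverged
        if "sigma" in cfg.metrics:
            row["sigma_alpha0"] = sigma_alpha0(weights, readout, rc, tc, teacher, traj=traj)
    if "delta" in cfg.metrics and mu > 0:
        row["delta_mean_driven"] = sync_error(
            _tail(traj, tc.washout)
        ).mean_delta
    if "capacity" in cfg.metrics:
        row["capacity"] = memory_capacity(
            _tail(traj, tc.washout), teacher.values[tc.washout : tc.n_train]
        ).capacity
    # autonomous continuation for regime label / delta / lyapunov
    auto_rc = rc.with_alpha(0.0)
    warm = run(weights, auto_rc, None, n_steps=cfg.autonomous_transient)
    n_auto = max(cfg.autonomous_samples + 1, 1)
    if "lyapunov" in cfg.metrics:
        n_auto = max(n_auto, 1500)
    tail = run(weights, auto_rc, None, n_steps=n_auto, x0=warm.states[-1])
    node_vals = tail.states[:, min(34, rc.n_nodes - 1)]
    label = classify_regime(
        node_vals[: cfg.autonomous_samples + 1], lyap=None, mu=float(mu)
    )
    row["regime"] = label.label
    if "delta" in cfg.metrics and mu > 0:
        row["delta_mean_autonomous"] = sync_error(tail).mean_delta
    if "lyapunov" in cfg.metrics:
        row.update(_auto_lyapunov(tail, label))
    row["runtime_s"] = time.perf_counter() - t0
    return row


def _tail(traj, washout):
    return StateTrajectory(
        states=traj.states[washout:], mu=traj.mu, driven=traj.driven
    )


def _auto_lyapunov(tail, label: RegimeLabel) -> dict:
    """Network exponent of the autonomous run, delay re-estimated per mu."""
    node_vals = tail.states[:, 34 % tail.states.shape[1]]
    if label.label == "fixed_point":
        return {"lambda_max": np.nan, "lambda_valid": False}
    try:
        delay = estimate_delay(node_vals, max_lag=30)
    except ValueError:
        delay = 1
    est = network_lyapunov(
        tail, EmbeddingParams(delay=max(delay, 1), dim=4), node_sample=16
    )
    return {
        "lambda_max": est.lambda_max if est.valid else np.nan,
        "lambda_valid": est.valid,
    }


def run_scan(cfg: ScanConfig) -> ScanResult:
    """Execute the full scan; per-cell failures are recorded, not fatal."""
    teacher = center(generate_mg(cfg.mg))
    grid = np.asarray(cfg.mu_grid, dtype=float)
    rows = []
    for i, mu in enumerate(grid):
        for r in range(cfg.n_realizations):
            try:
                row = _cell(cfg, teacher, mu, i, r)
            except Exception as exc:  # pragma: no cover - defensive
                logger.warning("cell (mu=%s, r=%d) failed: %s", mu, r, exc)
                row = {
                    "mu": float(mu),
                    "seed": cell_seed(cfg.base_seed, i, r),
                    "realization": r,
                    "error": str(exc),
                }
            else:
                logger.info(
                    "mu=%.3f r=%d done in %.2fs", mu, r, row.get("runtime_s", 0.0)
                )
            rows.append(row)
    df = pd.DataFrame(rows)
    numeric = [
        c
        for c in df.columns
        if c
        not in ("mu", "seed", "realization", "error", "regime", "diverged", "lambda_valid")
    ]
    grouped = df.groupby("mu")[numeric]
    summary = grouped.mean().add_suffix("_mean")
    summary = summary.join(grouped.std(ddof=0).add_suffix("_std"))
    n_per_mu = df.groupby("mu").size()
    for col in numeric:
        summary[f"{col}_sem"] = summary[f"{col}_std"] / np.sqrt(n_per_mu)
    summary = summary.reset_index()
    labels_by_mu = _majority_labels(df, grid)
    return ScanResult(rows=df, summary=summary, config=cfg, labels_by_mu=labels_by_mu)


def _majority_labels(df: pd.DataFrame, grid: np.ndarray) -> list[RegimeLabel]:
    labels = []
    for mu in grid:
        sub = df[(df["mu"] == mu) & (df["error"] == "")]
        if len(sub) == 0 or "regime" not in sub:
            labels.append(RegimeLabel("chaotic", {"note": "no data"}))
            continue
        frac_ok = (sub["regime"].isin(["fixed_point", "periodic"])).mean()
        modal = sub["regime"].mode().iloc[0]
        labels.append(
            RegimeLabel(
                modal if frac_ok > 0.5 else "chaotic", {"nonchaotic_fraction": frac_ok}
            )
        )
    return labels


def detect_windows(result: ScanResult, min_width: int = 2) -> list[tuple[float, float]]:
    """Maximal runs of consecutive non-chaotic grid points as mu intervals."""
    grid = np.asarray(result.config.mu_grid, dtype=float)
    return group_windows(grid, result.labels_by_mu, min_width=min_width)
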