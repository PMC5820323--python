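"""Spatio-temporal and stability diagnostics.

Four families of diagnostics characterize a network trajectory or a scalar
series:

* **Synchronization error** — the across-node standard deviation of the
  instantaneous state, normalized by the feedback amplification ``mu`` so it
  reads as a phase error of the sinusoidal activation.  Small values mean
  the nodes move in spatial synchrony.
* **Delay embedding** — Takens reconstruction of a scalar series, with the
  lag chosen at the first local minimum of the lagged self mutual
  information and the dimension by the Kennel false-nearest-neighbor
  criterion.
* **Maximal Lyapunov exponent** — Rosenstein's nearest-neighbor divergence
  method: track the mean log separation of initially close embedded states
  and fit its initial slope.  Positive slope = chaos.
* **Regime classification** — fixed point / periodic / chaotic labels for
  post-transient samples, used to delimit the regular windows of the
  bifurcation scan.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import TYPE_CHECKING

import numpy as np
from scipy.spatial import cKDTree

from .information import mutual_information
from .mackey_glass import MGSeries

if TYPE_CHECKING:  # pragma: no cover
    from .reservoir import StateTrajectory

__all__ = [
    "SyncProfile",
    "EmbeddingParams",
    "LyapunovEstimate",
    "RegimeLabel",
    "sync_error",
    "delay_embed",
    "estimate_delay",
    "estimate_dimension",
    "max_lyapunov",
    "network_lyapunov",
    "classify_regime",
    "group_windows",
]


@dataclass
class SyncProfile:
    """Per-time-step synchronization error and its time average."""

    delta: np.ndarray
    mean_delta: float
    mu: float


@dataclass(frozen=True)
class EmbeddingParams:
    """Takens embedding lag (samples) and dimension."""

    delay: int = 12
    dim: int = 4

    def __post_init__(self) -> None:
        if self.delay < 1:
            raise ValueError("delay must be >= 1")
        if self.dim < 1:
            raise ValueError("dim must be >= 1")


@dataclass
class LyapunovEstimate:
    """Largest Lyapunov exponent per sample step, with fit metadata."""

    lambda_max: float
    valid: bool
    fit_range: tuple[int, int]
    reason: str = ""


@dataclass
class RegimeLabel:
    """Dynamical regime of a post-transient sample block."""

    label: str  # fixed_point | periodic | chaotic | hyper_chaotic_flag
    evidence: dict = field(default_factory=dict)


def _series_values(series) -> np.ndarray:
    if isinstance(series, MGSeries):
        return series.values
    return np.asarray(series, dtype=float).ravel()


def sync_error(traj: "StateTrajectory") -> SyncProfile:
    """Across-node standard deviation per step, normalized by mu."""
    if traj.mu == 0:
        raise ValueError("sync error is undefined at mu = 0 (normalization)")
    states = traj.states
    if len(states) == 0:
        raise ValueError("empty trajectory")
    delta = states.std(axis=1) / traj.mu
    return SyncProfile(delta=delta, mean_delta=float(delta.mean()), mu=traj.mu)


def delay_embed(series, p: EmbeddingParams) -> np.ndarray:
    """Takens delay embedding.

    Returns ``L - (D-1)*tau`` points; row ``t`` is the tuple
    ``(s[n], s[n-tau], ..., s[n-(D-1)tau])`` with ``n = (D-1)*tau + t``.
    """
    s = _series_values(series)
    span = (p.dim - 1) * p.delay
    n_points = len(s) - span
    if n_points < 1:
        raise ValueError(
            f"series of length {len(s)} too short for delay {p.delay}, dim {p.dim}"
        )
    return np.column_stack(
        [s[span - k * p.delay : span - k * p.delay + n_points] for k in range(p.dim)]
    )


def estimate_delay(series, max_lag: int = 50, bins: int = 32) -> int:
    """First local minimum of the lagged self mutual information.

    A lag ``k`` is a local minimum when MI(k) < MI(k-1) and MI(k) <= MI(k+1);
    lag 1 qualifies when MI(1) <= MI(2) (the MI is already at its floor, as
    for white noise).
    """
    s = _series_values(series)
    if len(s) < 1000:
        raise ValueError("need at least 1000 samples to estimate the delay")
    mi = np.array(
        [mutual_information(s[:-k], s[k:], bins=bins) for k in range(1, max_lag + 2)]
    )
    if mi[0] <= mi[1]:
        return 1
    for i in range(1, max_lag):
        if mi[i] < mi[i - 1] and mi[i] <= mi[i + 1]:
            return i + 1
    raise ValueError(f"no local MI minimum within max_lag={max_lag}")


def _nearest_nontrivial(tree, points, theiler, k_extra=5):
    """Nearest neighbor of each point at temporal distance > theiler."""
    n = len(points)
    k = min(2 * theiler + k_extra, n)
    dists, idx = tree.query(points, k=k)
    nn_idx = np.full(n, -1)
    nn_dist = np.full(n, np.inf)
    for i in range(n):
        for d, j in zip(dists[i, 1:], idx[i, 1:]):
            if abs(j - i) > theiler:
                nn_idx[i] = j
                nn_dist[i] = d
                break
    return nn_idx, nn_dist


def estimate_dimension(
    series,
    delay: int,
    rtol: float = 15.0,
    atol: float = 2.0,
    threshold: float = 0.01,
    max_dim: int = 10,
    theiler: int | None = None,
) -> int:
    """Smallest embedding dimension by the Kennel false-nearest-neighbor test.

    A neighbor pair in dimension D is *false* when the extra coordinate of
    dimension D+1 either stretches the pair by more than ``rtol`` relative
    to its D-dimensional distance, or pushes the pair beyond ``atol`` times
    the attractor size (the series' standard deviation).  The first D whose
    false fraction falls below ``threshold`` is returned.
    """
    s = _series_values(series)
    sd = s.std()
    if sd == 0:
        return 1
    if theiler is None:
        theiler = delay
    for dim in range(1, max_dim + 1):
        X = delay_embed(s, EmbeddingParams(delay=delay, dim=dim))
        n = len(X) - delay  # the (D+1)-th coordinate must exist
        if n < 10:
            raise ValueError("series too short for the FNN test")
        pts = X[:n]
        tree = cKDTree(pts)
        nn_idx, nn_dist = _nearest_nontrivial(tree, pts, theiler)
        ok = nn_idx >= 0
        i = np.arange(n)[ok]
        j = nn_idx[ok]
        d = nn_dist[ok]
        extra = np.abs(s[dim * delay + i] - s[dim * delay + j])
        # multiplicative form of the Kennel ratio tests: exact-copy neighbors
        # (d = 0, extra = 0, as on a perfectly periodic orbit) are true
        stretched = extra > rtol * d
        lifted = np.sqrt(d**2 + extra**2)
        escaped = lifted / sd > atol
        # pairs separated by mere rounding noise cannot be false neighbors
        degenerate = lifted < 1e-12 * sd
        frac = float(np.mean((stretched | escaped) & ~degenerate))
        if frac < threshold:
            return dim
    raise ValueError(f"FNN fraction never fell below {threshold} up to dim {max_dim}")


def max_lyapunov(
    series,
    p: EmbeddingParams,
    fit_range: tuple[int, int] | None = None,
    theiler: int | None = None,
    min_valid_fraction: float = 0.5,
) -> LyapunovEstimate:
    """Rosenstein estimate of the largest Lyapunov exponent per sample step.

    For every embedded point, find its nearest neighbor at temporal distance
    beyond the Theiler window (default ``delay * dim``), then average the log
    separation of the pairs as both are advanced step by step.  The slope of
    this mean divergence curve over ``fit_range`` is the exponent.  The
    default fit window ``(1, max(2*delay, 5))`` spans two embedding delays,
    averaging over the delay-period ripple the curve exhibits for strongly
    oscillatory signals.
    """
    s = _series_values(series)
    if fit_range is None:
        fit_range = (1, max(2 * p.delay, 5))
    lo, hi = fit_range
    if s.std() < 1e-12 * max(1.0, abs(s.mean())) or s.std() == 0:
        return LyapunovEstimate(0.0, False, fit_range, "constant series")
    X = delay_embed(s, p)
    n = len(X) - hi
    if n < 100:
        return LyapunovEstimate(0.0, False, fit_range, "series too short")
    if theiler is None:
        theiler = p.delay * p.dim
    pts = X[:n]
    tree = cKDTree(pts)
    nn_idx, _ = _nearest_nontrivial(tree, pts, theiler)
    ok = nn_idx >= 0
    if ok.mean() < min_valid_fraction:
        return LyapunovEstimate(0.0, False, fit_range, "insufficient neighbors")
    i = np.arange(n)[ok]
    j = nn_idx[ok]
    curve = np.empty(hi + 1)
    for t in range(hi + 1):
        sep = np.linalg.norm(X[i + t] - X[j + t], axis=1)
        pos = sep > 0
        if pos.sum() < 10:
            return LyapunovEstimate(0.0, False, fit_range, "degenerate separations")
        curve[t] = np.mean(np.log(sep[pos]))
    if np.ptp(curve) < 1e-8:
        # separations never grow: no exponential divergence to measure
        return LyapunovEstimate(0.0, False, fit_range, "flat divergence curve")
    t_fit = np.arange(lo, hi + 1)
    slope = float(np.polyfit(t_fit, curve[lo : hi + 1], 1)[0])
    return LyapunovEstimate(slope, True, fit_range)


def network_lyapunov(
    traj: "StateTrajectory",
    p: EmbeddingParams,
    node_sample: int | None = 32,
    seed: int = 0,
    max_invalid_fraction: float = 0.5,
    **kwargs,
) -> LyapunovEstimate:
    """Network exponent: the maximum of per-node Rosenstein estimates.

    ``node_sample`` limits the number of nodes evaluated (seeded choice;
    ``None`` evaluates all).  The estimate is flagged invalid when more than
    ``max_invalid_fraction`` of the evaluated nodes fail individually.
    """
    states = traj.states
    n_nodes = states.shape[1]
    if node_sample is not None and node_sample < n_nodes:
        rng = np.random.default_rng(seed)
        nodes = rng.choice(n_nodes, node_sample, replace=False)
    else:
        nodes = np.arange(n_nodes)
    estimates = [max_lyapunov(states[:, i], p, **kwargs) for i in nodes]
    valid = [e.lambda_max for e in estimates if e.valid]
    fit_range = estimates[0].fit_range
    if not valid:
        return LyapunovEstimate(0.0, False, fit_range, "all nodes invalid")
    invalid_frac = 1 - len(valid) / len(estimates)
    if invalid_frac > max_invalid_fraction:
        return LyapunovEstimate(
            max(valid), False, fit_range, f"{invalid_frac:.0%} of nodes invalid"
        )
    return LyapunovEstimate(max(valid), True, fit_range)


def classify_regime(
    node_samples,
    lyap: LyapunovEstimate | None = None,
    mu: float = 1.0,
    tol_fp: float = 1e-6,
    tol_chaos: float = 0.005,
    period_max: int = 80,
    period_tol: float = 1e-3,
) -> RegimeLabel:
    """Label post-transient samples as fixed point, periodic or chaotic.

    Amplitude below ``tol_fp * mu`` peak-to-peak is a fixed point.  With a
    valid Lyapunov estimate, ``lambda_max <= tol_chaos`` is periodic and
    anything larger chaotic; an invalid estimate on a high-amplitude signal
    is flagged hyper-chaotic.  Without an estimate, an exact recurrence test
    (a period ``p <= period_max`` matching to ``period_tol`` of the
    amplitude) separates periodic from chaotic — cheap enough for dense
    bifurcation scans where per-point exponents would dominate the cost.
    """
    s = np.asarray(node_samples, dtype=float).ravel()
    ptp = float(np.ptp(s))
    evidence = {"ptp": ptp, "mu": mu}
    if ptp <= tol_fp * mu:
        return RegimeLabel("fixed_point", evidence)
    if lyap is not None:
        evidence["lambda_max"] = lyap.lambda_max
        if lyap.valid:
            label = "periodic" if lyap.lambda_max <= tol_chaos else "chaotic"
            return RegimeLabel(label, evidence)
        return RegimeLabel("hyper_chaotic_flag", evidence)
    window = max(len(s) - period_max, len(s) // 2)
    for period in range(1, min(period_max, len(s) - window) + 1):
        err = np.max(np.abs(s[:window] - s[period : period + window]))
        if err < period_tol * ptp:
            evidence["period"] = period
            return RegimeLabel("periodic", evidence)
    return RegimeLabel("chaotic", evidence)


def group_windows(
    mu_grid: np.ndarray, labels: list[RegimeLabel], min_width: int = 2
) -> list[tuple[float, float]]:
    """Contiguous runs of non-chaotic grid points, as closed mu intervals.

    Runs spanning fewer than ``min_width`` grid points are below the scan's
    resolution and are dropped.
    """
    nonchaotic = [lab.label in ("fixed_point", "periodic") for lab in labels]
    windows: list[tuple[float, float]] = []
    start = None
    for k, good in enumerate(nonchaotic):
        if good and start is None:
            start = k
        elif not good and start is not None:
            if k - start >= min_width:
                windows.append((float(mu_grid[start]), float(mu_grid[k - 1])))
            start = None
    if start is not None and len(nonchaotic) - start >= min_width:
        windows.append((float(mu_grid[start]), float(mu_grid[-1])))
    return windows
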