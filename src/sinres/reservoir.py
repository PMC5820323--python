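"""The sinusoidal random recurrent network.

State update (N nodes, discrete time):

    x[n+1] = mu * f( W @ x[n] + W_off * b + W_fb * alpha * u[n] ),

with f = sin by default (tanh available), mu the feedback amplification and
the single bifurcation parameter, b a common offset distributed through the
random vector W_off, and u the scalar input scaled by alpha.  W is a dense
random matrix with uniform [0, 1] entries at connectivity 0.99, scaled to
unit spectral radius so that mu is the effective loop gain: the resting
state then destabilizes near mu = 1 and the network shows a cascade of
regular (non-chaotic) windows at larger mu, separated by chaotic gaps.

The all-positive W is dominated by its Perron mode, whose eigenvector is
nearly uniform across nodes: the whole network is slaved to a scalar
mean field, which is what synchronizes the nodes and produces the shared
regular windows seen in the single-node bifurcation diagram.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .mackey_glass import MGSeries
from .dynamics import RegimeLabel, classify_regime, group_windows

__all__ = [
    "ReservoirConfig",
    "ReservoirWeights",
    "StateTrajectory",
    "BifurcationDiagram",
    "build_weights",
    "step",
    "run",
    "bifurcation_scan",
]

_ACTIVATIONS = {"sine": np.sin, "tanh": np.tanh}


@dataclass(frozen=True)
class ReservoirConfig:
    """Network hyper-parameters.

    ``connectivity`` is the fraction of nonzero entries of W; ``alpha``
    scales the scalar input; ``offset_b`` is the common offset fed through
    the random vector W_off.
    """

    n_nodes: int = 500
    mu: float = 0.9
    offset_b: float = 0.2
    alpha: float = 0.8
    connectivity: float = 0.99
    activation: str = "sine"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_nodes < 1:
            raise ValueError("n_nodes must be >= 1")
        if not 0 < self.connectivity <= 1:
            raise ValueError("connectivity must lie in (0, 1]")
        if self.alpha < 0:
            raise ValueError("alpha must be >= 0")
        if self.mu < 0:
            raise ValueError("mu must be >= 0")
        if self.activation not in _ACTIVATIONS:
            raise ValueError(f"activation must be one of {sorted(_ACTIVATIONS)}")

    def with_mu(self, mu: float) -> "ReservoirConfig":
        return ReservoirConfig(
            n_nodes=self.n_nodes,
            mu=mu,
            offset_b=self.offset_b,
            alpha=self.alpha,
            connectivity=self.connectivity,
            activation=self.activation,
            seed=self.seed,
        )

    def with_alpha(self, alpha: float) -> "ReservoirConfig":
        return ReservoirConfig(
            n_nodes=self.n_nodes,
            mu=self.mu,
            offset_b=self.offset_b,
            alpha=alpha,
            connectivity=self.connectivity,
            activation=self.activation,
            seed=self.seed,
        )


@dataclass
class ReservoirWeights:
    """The random connectivity triple {W, W_off, W_fb} and its seed.

    W is stored after division by the raw spectral radius (kept in
    ``spectral_radius_raw``); its entries therefore lie in [0, 1/rho_raw].
    W_off is uniform [0, 1]; W_fb is uniform [-1, 1] — signed input weights
    spread the scalar input across the non-Perron modes instead of
    collapsing it onto the mean field (they do not enter the autonomous
    dynamics at all).
    """

    W: np.ndarray
    W_off: np.ndarray
    W_fb: np.ndarray
    seed: int
    spectral_radius_raw: float = float("nan")

    @property
    def n_nodes(self) -> int:
        return self.W.shape[0]


@dataclass
class StateTrajectory:
    """Time-ordered node states (time x N), tagged driven or autonomous."""

    states: np.ndarray
    mu: float
    driven: bool
    input_used: np.ndarray | None = field(default=None, repr=False)

    def __len__(self) -> int:
        return len(self.states)


@dataclass
class BifurcationDiagram:
    """Post-transient single-node samples per mu, with regime labels."""

    mu_grid: np.ndarray
    sampled_states: np.ndarray  # (len(mu_grid), n_samples)
    node_index: int
    labels: list[RegimeLabel]
    windows: list[tuple[float, float]]


def build_weights(config: ReservoirConfig) -> ReservoirWeights:
    """Draw the random weight triple, reproducibly from the config seed.

    W: uniform [0, 1] entries, exactly ``floor((1-connectivity) * N^2)``
    uniformly chosen entries zeroed, then scaled to unit spectral radius.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_nodes
    W = rng.uniform(0.0, 1.0, size=(n, n))
    n_zero = int(np.floor((1.0 - config.connectivity) * n * n))
    if n_zero:
        flat_idx = rng.choice(n * n, size=n_zero, replace=False)
        W.flat[flat_idx] = 0.0
    rho = float(np.max(np.abs(np.linalg.eigvals(W)))) if n > 0 else 1.0
    if rho > 0:
        W /= rho
    w_off = rng.uniform(0.0, 1.0, size=n)
    w_fb = rng.uniform(-1.0, 1.0, size=n)
    return ReservoirWeights(
        W=W, W_off=w_off, W_fb=w_fb, seed=config.seed, spectral_radius_raw=rho
    )


def step(
    x: np.ndarray, u: float, w: ReservoirWeights, c: ReservoirConfig
) -> np.ndarray:
    """One network update consuming scalar input u (0 in autonomous mode)."""
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)) or not np.isfinite(u):
        raise ValueError("non-finite state or input")
    act = _ACTIVATIONS[c.activation]
    return c.mu * act(w.W @ x + w.W_off * c.offset_b + w.W_fb * (c.alpha * u))


def run(
    w: ReservoirWeights,
    c: ReservoirConfig,
    input_series: MGSeries | np.ndarray | None = None,
    n_steps: int = 1000,
    x0: np.ndarray | None = None,
) -> StateTrajectory:
    """Iterate the network for ``n_steps`` and record every state.

    Input alignment: the update that produces state row ``t`` consumes input
    sample ``t - 1`` (the very first update consumes 0).  The readout target
    for row ``t`` is then input sample ``t`` — one-step-ahead prediction.
    """
    n = w.n_nodes
    x = np.zeros(n) if x0 is None else np.asarray(x0, dtype=float).copy()
    if input_series is not None:
        u_vals = (
            input_series.values
            if isinstance(input_series, MGSeries)
            else np.asarray(input_series, dtype=float)
        )
        if len(u_vals) < n_steps:
            raise ValueError(
                f"input length {len(u_vals)} shorter than n_steps {n_steps}"
            )
    else:
        u_vals = None
    driven = u_vals is not None and c.alpha > 0
    act = _ACTIVATIONS[c.activation]
    W, off, fb = w.W, w.W_off * c.offset_b, w.W_fb
    states = np.empty((n_steps, n))
    for t in range(n_steps):
        u = u_vals[t - 1] if (u_vals is not None and t > 0) else 0.0
        x = c.mu * act(W @ x + off + fb * (c.alpha * u))
        if not np.all(np.isfinite(x)):
            raise FloatingPointError(f"state diverged at step {t}")
        states[t] = x
    return StateTrajectory(
        states=states,
        mu=c.mu,
        driven=driven,
        input_used=u_vals[:n_steps].copy() if driven else None,
    )


def bifurcation_scan(
    w: ReservoirWeights,
    c: ReservoirConfig,
    mu_grid,
    node_index: int = 34,
    transient: int = 1000,
    n_samples: int = 200,
) -> BifurcationDiagram:
    """Autonomous single-node bifurcation diagram over a mu grid.

    For each mu the network runs ``transient`` steps from rest, then
    ``n_samples + 1`` further states of one node are recorded and classified
    (fixed point / periodic / chaotic).  Contiguous non-chaotic runs become
    the regular windows.
    """
    if c.alpha != 0:
        raise ValueError("bifurcation scan requires an autonomous config (alpha=0)")
    mu_grid = np.asarray(mu_grid, dtype=float)
    if mu_grid.size == 0:
        raise ValueError("empty mu grid")
    if not np.all(np.diff(mu_grid) > 0):
        raise ValueError("mu_grid must be strictly increasing")
    if not 0 <= node_index < w.n_nodes:
        raise IndexError(f"node_index {node_index} out of range")
    sampled = np.empty((len(mu_grid), n_samples))
    labels: list[RegimeLabel] = []
    for k, mu in enumerate(mu_grid):
        cfg = c.with_mu(float(mu))
        warm = run(w, cfg, None, n_steps=transient) if transient else None
        x0 = warm.states[-1] if warm is not None else None
        tail = run(w, cfg, None, n_steps=n_samples + 1, x0=x0)
        node_vals = tail.states[:, node_index]
        sampled[k] = node_vals[:n_samples]
        labels.append(classify_regime(node_vals, lyap=None, mu=float(mu)))
    windows = group_windows(mu_grid, labels)
    return BifurcationDiagram(
        mu_grid=mu_grid,
        sampled_states=sampled,
        node_index=node_index,
        labels=labels,
        windows=windows,
    )
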