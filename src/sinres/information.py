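"""Mutual information between node responses and the input signal.

The mutual information between the i-th node series and the injected teacher,

    MI_i = sum P(x_i, y) log2( P(x_i, y) / (P(x_i) P(y)) ),

is estimated with a plug-in equal-width 2-D histogram over the observed
ranges.  Summing over all nodes gives the aggregate C = sum_i MI_i, which
quantifies how much of the input's information content the network as a
whole preserves at zero lag.  (The network literature usually reserves
"memory capacity" for a lagged linear-reconstruction measure; here the name
denotes this same-time MI sum.)
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING

import numpy as np

from .mackey_glass import MGSeries

if TYPE_CHECKING:  # pragma: no cover
    from .reservoir import StateTrajectory

__all__ = ["MIEstimate", "mutual_information", "memory_capacity"]


@dataclass
class MIEstimate:
    """Per-node mutual information (bits) and its sum."""

    per_node_mi: np.ndarray
    capacity: float
    bins: int
    n_samples: int


def mutual_information(a, b, bins: int = 32) -> float:
    """Plug-in histogram mutual information of two sequences, in bits.

    Symmetric in its arguments; a constant sequence carries no information
    and yields exactly 0.
    """
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if len(a) != len(b):
        raise ValueError(f"length mismatch: {len(a)} vs {len(b)}")
    if bins < 2:
        raise ValueError("bins must be >= 2")
    if len(a) < 2:
        raise ValueError("need at least 2 samples")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        return 0.0  # a constant carries no information
    counts, _, _ = np.histogram2d(a, b, bins=bins)
    p = counts / counts.sum()
    px = p.sum(axis=1)
    py = p.sum(axis=0)
    outer = np.outer(px, py)
    nz = p > 0
    return float(np.sum(p[nz] * np.log2(p[nz] / outer[nz])))


def memory_capacity(
    traj: "StateTrajectory", input_series: MGSeries | np.ndarray, bins: int = 32
) -> MIEstimate:
    """MI between every node and the aligned input, and their sum C.

    Row ``t`` of the trajectory is paired with input sample ``t`` — the same
    alignment used for readout training targets.
    """
    values = (
        input_series.values
        if isinstance(input_series, MGSeries)
        else np.asarray(input_series, dtype=float)
    )
    states = traj.states
    if len(states) != len(values):
        raise ValueError(
            f"trajectory length {len(states)} does not match input length {len(values)}"
        )
    per_node = np.array(
        [mutual_information(states[:, i], values, bins) for i in range(states.shape[1])]
    )
    return MIEstimate(
        per_node_mi=per_node,
        capacity=float(per_node.sum()),
        bins=bins,
        n_samples=len(values),
    )
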