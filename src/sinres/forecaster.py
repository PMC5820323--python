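"""Scikit-learn style estimator wrapping the reservoir + readout pipeline.

``ReservoirForecaster`` follows the sklearn estimator contract
(``get_params`` / ``set_params`` / ``clone``-compatible ``__init__``,
validation in ``fit``, trailing-underscore fitted attributes) so it can sit
inside sklearn model-selection utilities.  Like other time-series
forecasters it bends the ``predict`` signature: ``fit`` takes the scalar
teacher series and ``predict`` takes a forecast horizon rather than a
feature matrix.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin

from .mackey_glass import MGSeries
from .readout import (
    PredictionResult,
    TrainingConfig,
    nmse,
    sigma_alpha0,
    train_readout,
)
from .reservoir import ReservoirConfig, build_weights, run

__all__ = ["ReservoirForecaster"]


class ReservoirForecaster(BaseEstimator, RegressorMixin):
    """Closed-loop chaotic time-series forecaster with a fixed random core.

    Parameters
    ----------
    n_nodes : int
        Network size N.
    mu : float
        Feedback amplification (the bifurcation parameter).
    offset_b : float
        Node offset operating point.
    alpha : float
        Input scaling during teacher forcing (and in the closed loop).
    connectivity : float
        Fraction of nonzero internal weights.
    activation : str
        "sine" (default) or "tanh".
    washout : int
        Leading training samples excluded from the regression.
    random_state : int
        Seed for the random weight triple.

    Attributes
    ----------
    weights_ : ReservoirWeights
        The random connectivity triple.
    readout_ : ReadoutWeights
        Trained output vector and training residual.
    states_ : ndarray of shape (n_train, n_nodes)
        Teacher-forced trajectory used for the regression.
    training_nmse_ : float
        NMSE of the trained readout on the training block.

    Examples
    --------
    >>> from sinres.mackey_glass import MGConfig, generate_mg, center
    >>> teacher = center(generate_mg(MGConfig(length=2100)))
    >>> f = ReservoirForecaster(n_nodes=100, mu=0.9, random_state=0)
    >>> y_hat = f.fit(teacher.values[:2000]).predict(35)
    """

    def __init__(
        self,
        n_nodes: int = 500,
        mu: float = 0.9,
        offset_b: float = 0.2,
        alpha: float = 0.8,
        connectivity: float = 0.99,
        activation: str = "sine",
        washout: int = 100,
        random_state: int = 0,
    ):
        self.n_nodes = n_nodes
        self.mu = mu
        self.offset_b = offset_b
        self.alpha = alpha
        self.connectivity = connectivity
        self.activation = activation
        self.washout = washout
        self.random_state = random_state

    def _configs(self, n_train: int, horizon: int) -> tuple[ReservoirConfig, TrainingConfig]:
        rc = ReservoirConfig(
            n_nodes=self.n_nodes,
            mu=self.mu,
            offset_b=self.offset_b,
            alpha=self.alpha,
            connectivity=self.connectivity,
            activation=self.activation,
            seed=self.random_state,
        )
        tc = TrainingConfig(
            n_train=n_train,
            alpha=self.alpha,
            washout=self.washout,
            horizon=horizon,
            sigma_discard=min(10, horizon - 1),
            sigma_window=horizon - min(10, horizon - 1),
        )
        return rc, tc

    def fit(self, y, X=None) -> "ReservoirForecaster":
        """Teacher-force the network on the scalar series y and train w_out."""
        y = np.asarray(y, dtype=float).ravel()
        if y.ndim != 1 or len(y) <= self.washout + 1:
            raise ValueError("y must be a 1-D series longer than the washout")
        if np.max(np.abs(y)) >= 1:
            raise ValueError(
                "teacher values must lie strictly inside (-1, 1); center/scale first"
            )
        rc, tc = self._configs(n_train=len(y), horizon=35)
        self.teacher_ = MGSeries(values=y, centered=bool(abs(y.mean()) < 1e-9 * max(y.std(), 1)))
        self.weights_ = build_weights(rc)
        traj = run(self.weights_, rc, y, n_steps=len(y))
        self.states_ = traj.states
        self._traj = traj
        self.readout_ = train_readout(traj, y, tc)
        self.training_nmse_ = self.readout_.training_nmse
        self._rc = rc
        return self

    def predict(self, n_steps: int = 35) -> np.ndarray:
        """Free-run the closed loop for n_steps from the post-training state."""
        self._check_fitted()
        result = self._free_run(n_steps)
        return result.free_run

    def score_free_run(self, truth) -> PredictionResult:
        """Free-run over len(truth) steps and report the NMSE against it."""
        self._check_fitted()
        truth = np.asarray(truth, dtype=float).ravel()
        result = self._free_run(len(truth))
        result.truth = truth
        result.nmse = nmse(result.free_run, truth)
        return result

    def sigma_alpha0(self, truth) -> float:
        """Autonomous output variance ratio over the horizon len(truth)."""
        self._check_fitted()
        truth = np.asarray(truth, dtype=float).ravel()
        horizon = len(truth)
        discard = min(10, horizon - 1)
        tc = TrainingConfig(
            n_train=len(self.states_),
            alpha=self.alpha,
            washout=self.washout,
            horizon=horizon,
            sigma_discard=discard,
            sigma_window=horizon - discard,
        )
        teacher = MGSeries(
            values=np.concatenate([self.teacher_.values, truth]), centered=False
        )
        return sigma_alpha0(
            self.weights_, self.readout_, self._rc, tc, teacher, traj=self._traj
        )

    def _free_run(self, n_steps: int) -> PredictionResult:
        from .reservoir import step

        x = self._traj.states[-1].copy()
        u = float(np.tanh(self.readout_.w_out @ x))
        free = np.empty(n_steps)
        for h in range(n_steps):
            x = step(x, u, self.weights_, self._rc)
            u = float(np.tanh(self.readout_.w_out @ x))
            free[h] = u
        return PredictionResult(
            free_run=free,
            truth=np.full(n_steps, np.nan),
            nmse=float("nan"),
            mu=self.mu,
            seed=self.random_state,
        )

    def _check_fitted(self) -> None:
        if not hasattr(self, "readout_"):
            raise RuntimeError("this ReservoirForecaster instance is not fitted yet")
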