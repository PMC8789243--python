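"""Per-neuron linear prediction of steady-state activity.

Each neuron forecasts its own settling endpoint from its first few activity
steps: ``x(T) ~= x~ = lambda(1) x(1) + ... + lambda(K) x(K) + b``, with the
coefficients fitted by ordinary least squares across a collection of
free-phase trajectories (one regression per neuron, K = ``predictor_window``,
default 5, steady state at step 20).  The forecast ``x~`` plays three roles:
it is the reference of the neuronal surprise ``|x - x~|``, the target of the
fast adaptation nudge, and the subtrahend of the synaptic update.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .exceptions import ConfigurationError, FitError, PhaseError
from .net import FREE, NetworkParams, Trajectory

__all__ = ["SteadyStatePredictor", "fit_predictors", "predict_steady_state"]


class SteadyStatePredictor(BaseEstimator):
    """Independent per-neuron OLS forecast of the settling endpoint.

    Parameters
    ----------
    window : int
        Number of initial settling steps used as regressors (K).
    ridge : float
        Optional L2 penalty on the lambda coefficients (not the intercept);
        0 keeps plain least squares with a minimum-norm solution on
        rank-deficient designs.

    Attributes
    ----------
    lambdas_ : ndarray of shape (n_units, window)
        Per-neuron step coefficients, hidden units first then output units.
    offset_ : ndarray of shape (n_units,)
        Per-neuron intercepts ``b``.
    n_fit_ : int
        Number of trajectories the model was fitted on.
    """

    def __init__(self, window: int = 5, ridge: float = 0.0):
        self.window = window
        self.ridge = ridge

    def fit(self, trajectories: Sequence[Trajectory]) -> "SteadyStatePredictor":
        """Fit one regression per neuron on free-phase trajectories."""
        trajs = list(trajectories)
        if any(t.phase != FREE for t in trajs):
            raise PhaseError("predictor fitting requires free-phase trajectories only")
        if len(trajs) < self.window + 2:
            raise FitError(
                f"need at least window + 2 = {self.window + 2} trajectories, got {len(trajs)}"
            )
        shapes = {(t.hidden.shape, t.output.shape) for t in trajs}
        if len(shapes) != 1:
            raise ConfigurationError("trajectories come from differently shaped networks")
        early = np.stack([t.early(self.window) for t in trajs])  # (n, K, n_units)
        steady = np.stack([t.steady for t in trajs])  # (n, n_units)
        self.n_hidden_ = trajs[0].hidden.shape[1]
        self.n_output_ = trajs[0].output.shape[1]
        self._fit_arrays(early, steady)
        return self

    def fit_batch(self, hidden: np.ndarray, output: np.ndarray) -> "SteadyStatePredictor":
        """Fit from stacked free-phase activity arrays.

        ``hidden``/``output`` have shape ``(B, T_settle, n_units_of_layer)``
        as produced by :func:`predadapt.net.settle_batch` for the free phase.
        Equivalent to :meth:`fit` on the corresponding trajectories.
        """
        B = hidden.shape[0]
        if B < self.window + 2:
            raise FitError(
                f"need at least window + 2 = {self.window + 2} trajectories, got {B}"
            )
        K = self.window
        early = np.concatenate([hidden[:, :K, :], output[:, :K, :]], axis=2)
        steady = np.concatenate([hidden[:, -1, :], output[:, -1, :]], axis=1)
        self.n_hidden_ = hidden.shape[2]
        self.n_output_ = output.shape[2]
        self._fit_arrays(early, steady)
        return self

    def _fit_arrays(self, early: np.ndarray, steady: np.ndarray) -> None:
        n, K, n_units = early.shape
        lambdas = np.empty((n_units, K))
        offset = np.empty(n_units)
        ones = np.ones((n, 1))
        for j in range(n_units):
            X = np.hstack([early[:, :, j], ones])
            y = steady[:, j]
            if self.ridge > 0.0:
                # penalise the K slope coefficients only
                P = np.diag([self.ridge] * K + [0.0])
                coef = np.linalg.solve(X.T @ X + P, X.T @ y)
            else:
                coef, *_ = np.linalg.lstsq(X, y, rcond=None)
            lambdas[j] = coef[:K]
            offset[j] = coef[K]
        if not (np.isfinite(lambdas).all() and np.isfinite(offset).all()):
            raise FitError("non-finite predictor coefficients")
        self.lambdas_ = lambdas
        self.offset_ = offset
        self.n_fit_ = n

    def predict(self, early_activity: np.ndarray) -> np.ndarray:
        """Forecast ``x~`` for one trajectory.

        ``early_activity`` has shape ``(window, n_units)`` — the first K
        steps of every predicted unit, hidden columns first.
        """
        early_activity = np.asarray(early_activity, dtype=float)
        return self.predict_batch(early_activity[None, :, :])[0]

    def predict_batch(self, early: np.ndarray) -> np.ndarray:
        """Vectorised forecast for ``(B, window, n_units)`` early activity."""
        if not hasattr(self, "lambdas_"):
            raise FitError("predictor is not fitted")
        early = np.asarray(early, dtype=float)
        if early.ndim != 3 or early.shape[1] != self.lambdas_.shape[1]:
            raise ConfigurationError(
                f"early activity must have shape (B, {self.lambdas_.shape[1]}, n_units), "
                f"got {early.shape}"
            )
        if early.shape[2] != self.lambdas_.shape[0]:
            raise ConfigurationError(
                f"early activity has {early.shape[2]} units, predictor has "
                f"{self.lambdas_.shape[0]}"
            )
        return np.einsum("jk,bkj->bj", self.lambdas_, early) + self.offset_

    def predict_trajectory(self, trajectory: Trajectory) -> np.ndarray:
        """Forecast from a trajectory's own first ``window`` steps."""
        return self.predict(trajectory.early(self.window))

    def to_frame(self) -> pd.DataFrame:
        """Coefficient table (unit_id, layer, lambda_1..K, b) for CSV export."""
        if not hasattr(self, "lambdas_"):
            raise FitError("predictor is not fitted")
        K = self.lambdas_.shape[1]
        layer = ["hidden"] * self.n_hidden_ + ["output"] * self.n_output_
        data = {"unit_id": np.arange(self.lambdas_.shape[0]), "layer": layer}
        for k in range(K):
            data[f"lambda_{k + 1}"] = self.lambdas_[:, k]
        data["b"] = self.offset_
        return pd.DataFrame(data)


def fit_predictors(
    free_trajectories: Iterable[Trajectory], params: NetworkParams, ridge: float = 0.0
) -> SteadyStatePredictor:
    """Fit a :class:`SteadyStatePredictor` with the window from ``params``."""
    return SteadyStatePredictor(window=params.predictor_window, ridge=ridge).fit(
        list(free_trajectories)
    )


def predict_steady_state(
    predictor: SteadyStatePredictor, early_activity: np.ndarray
) -> np.ndarray:
    """Functional alias for :meth:`SteadyStatePredictor.predict`."""
    return predictor.predict(early_activity)
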