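"""Recurrent network core: parameters, weights and settling dynamics.

The model is an energy-based recurrent network with three layers: input units
clamped to the stimulus pixels, a hidden layer, and an output layer with
feedback connections onto the hidden layer.  When a stimulus is presented the
activity propagates for a fixed number of synchronous update steps until it
reaches a steady state ("settling").  Three phases exist:

* **free** — only the stimulus drives the network; the step-``T_settle``
  activity is the free steady state ``x_F``.
* **clamped** — from step ``t_clamp`` onward the output units are fixed to a
  one-hot class target (the teaching signal); the endpoint supplies the
  "actual" activity ``x`` of the predictive learning rule.
* **clamped with adaptation** — as clamped, but from the clamp step onward
  each hidden unit is additionally nudged toward its own predicted steady
  state ``x~``::

      x[j, t] = a * x~[j] + (1 - a) * sigma(sum_i w[i, j] * x[i, t - 1])

  with adaptation strength ``a`` in [0, 1].  This emulates fast neuronal
  adaptation (tens of milliseconds): the unit blends its bottom-up drive with
  the forecast from its internal predictive model.

Units use the logistic activation, so unclamped activities live in (0, 1);
clamp targets of 0/1 are therefore the saturating extremes.  Updates are
synchronous and fully deterministic: identical weights, stimulus, parameters
and predictor always yield identical trajectories.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd
from scipy.special import expit

from .exceptions import ConfigurationError, NumericalError, PhaseError

__all__ = [
    "NetworkParams",
    "Weights",
    "Trajectory",
    "init_weights",
    "settle",
    "settle_batch",
    "classify",
]

#: pre-activations are clipped to +/- this value before the sigmoid so that
#: runaway weights produce saturated activity instead of overflow warnings.
PREACT_CLIP = 500.0

FREE = "free"
CLAMPED = "clamped"
CLAMPED_ADAPTED = "clamped_adapted"


@dataclass(frozen=True)
class NetworkParams:
    """Architecture and settling schedule of the recurrent network.

    Parameters
    ----------
    n_input, n_hidden, n_output
        Layer sizes; the digit protocol of the reference experiments uses
        420 inputs (a 21x20 pixel crop), 50 hidden and 10 output units.
    T_settle
        Number of synchronous settling steps; the step-``T_settle`` activity
        is treated as the steady state (no early exit).
    t_clamp
        1-based step from which the output units are clamped to the teaching
        signal (and from which adaptation, if enabled, acts).
    predictor_window
        Number of initial steps fed to the per-neuron steady-state predictor.
    adapt_strength
        Adaptation strength ``a`` in [0, 1]; 0 disables adaptation.
    weight_init_scale
        Half-width of the uniform weight initialisation interval.
    symmetric_feedback
        If set, the output->hidden feedback is kept equal to the transpose of
        the hidden->output weights (the classical energy-based choice).
    hidden_recurrence
        If set, adds a plastic hidden<->hidden matrix (off by default; the
        feedback loop through the output layer already makes the net
        recurrent).
    seed
        Seed for weight initialisation.
    """

    n_input: int
    n_hidden: int
    n_output: int
    T_settle: int = 20
    t_clamp: int = 8
    predictor_window: int = 5
    adapt_strength: float = 0.0
    activation: str = "logistic"
    weight_init_scale: float = 0.1
    symmetric_feedback: bool = False
    hidden_recurrence: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_input", "n_hidden", "n_output"):
            if int(getattr(self, name)) < 1:
                raise ConfigurationError(f"{name} must be >= 1, got {getattr(self, name)}")
        if not (1 <= self.predictor_window < self.t_clamp < self.T_settle):
            raise ConfigurationError(
                "need 1 <= predictor_window < t_clamp < T_settle, got "
                f"window={self.predictor_window}, t_clamp={self.t_clamp}, "
                f"T_settle={self.T_settle}"
            )
        if not 0.0 <= self.adapt_strength <= 1.0:
            raise ConfigurationError(f"adapt_strength must lie in [0, 1], got {self.adapt_strength}")
        if self.activation != "logistic":
            raise ConfigurationError(f"unsupported activation {self.activation!r}")
        if self.weight_init_scale < 0:
            raise ConfigurationError("weight_init_scale must be >= 0")

    @property
    def n_units(self) -> int:
        """Number of predicted units (hidden + output)."""
        return self.n_hidden + self.n_output

    def with_adaptation(self, a: float) -> "NetworkParams":
        """Return a copy with a different adaptation strength."""
        return replace(self, adapt_strength=a)


@dataclass
class Weights:
    """Plastic weight matrices of the network.

    ``W_ih`` maps input->hidden, ``W_ho`` hidden->output, ``W_oh`` the
    output->hidden feedback, and the optional ``W_hh`` a hidden<->hidden
    recurrence.  All matrices are stored pre-synaptic x post-synaptic.
    """

    W_ih: np.ndarray
    W_ho: np.ndarray
    W_oh: np.ndarray
    W_hh: Optional[np.ndarray] = None

    def validate(self, params: NetworkParams) -> None:
        expected = {
            "W_ih": (params.n_input, params.n_hidden),
            "W_ho": (params.n_hidden, params.n_output),
            "W_oh": (params.n_output, params.n_hidden),
        }
        for name, shape in expected.items():
            mat = getattr(self, name)
            if mat.shape != shape:
                raise ConfigurationError(f"{name} has shape {mat.shape}, expected {shape}")
            if not np.isfinite(mat).all():
                raise NumericalError(f"{name} contains non-finite entries")
        if params.hidden_recurrence:
            if self.W_hh is None or self.W_hh.shape != (params.n_hidden, params.n_hidden):
                raise ConfigurationError("hidden_recurrence set but W_hh missing or mis-shaped")

    def copy(self) -> "Weights":
        return Weights(
            W_ih=self.W_ih.copy(),
            W_ho=self.W_ho.copy(),
            W_oh=self.W_oh.copy(),
            W_hh=None if self.W_hh is None else self.W_hh.copy(),
        )

    def as_dict(self) -> dict:
        out = {"W_ih": self.W_ih, "W_ho": self.W_ho, "W_oh": self.W_oh}
        if self.W_hh is not None:
            out["W_hh"] = self.W_hh
        return out

    def max_abs(self) -> float:
        return max(float(np.abs(m).max()) for m in self.as_dict().values())


@dataclass
class Trajectory:
    """Per-step activity of one stimulus presentation.

    ``hidden`` and ``output`` hold the activity of steps ``1..T_settle`` in
    rows (row ``t - 1`` is step ``t``).  ``phase`` records which settling
    regime produced the trajectory.
    """

    hidden: np.ndarray
    output: np.ndarray
    stimulus: np.ndarray
    phase: str
    clamp_target: Optional[np.ndarray] = None
    stimulus_id: Optional[int] = None

    @property
    def n_steps(self) -> int:
        return self.hidden.shape[0]

    @property
    def steady_hidden(self) -> np.ndarray:
        return self.hidden[-1]

    @property
    def steady_output(self) -> np.ndarray:
        return self.output[-1]

    @property
    def steady(self) -> np.ndarray:
        """Steady-state activity of hidden then output units, concatenated."""
        return np.concatenate([self.hidden[-1], self.output[-1]])

    def early(self, window: int) -> np.ndarray:
        """Activity of steps ``1..window`` as a ``(window, n_units)`` array."""
        if not 1 <= window <= self.n_steps:
            raise ConfigurationError(f"window {window} outside 1..{self.n_steps}")
        return np.concatenate([self.hidden[:window], self.output[:window]], axis=1)

    def to_frame(self) -> pd.DataFrame:
        """Long-format table (step, unit_id, layer, activity) for CSV export."""
        rows = []
        for layer, act in (("hidden", self.hidden), ("output", self.output)):
            T, n = act.shape
            rows.append(
                pd.DataFrame(
                    {
                        "step": np.repeat(np.arange(1, T + 1), n),
                        "unit_id": np.tile(np.arange(n), T),
                        "layer": layer,
                        "activity": act.ravel(),
                    }
                )
            )
        return pd.concat(rows, ignore_index=True)


def init_weights(params: NetworkParams) -> Weights:
    """Draw initial weights i.i.d. uniform on [-scale, +scale].

    Reproducible for a fixed ``params.seed``.  With ``symmetric_feedback``
    the feedback matrix starts as the transpose of ``W_ho``; otherwise it is
    an independent draw.
    """
    rng = np.random.default_rng(params.seed)
    s = params.weight_init_scale
    W_ih = rng.uniform(-s, s, size=(params.n_input, params.n_hidden))
    W_ho = rng.uniform(-s, s, size=(params.n_hidden, params.n_output))
    if params.symmetric_feedback:
        W_oh = W_ho.T.copy()
    else:
        W_oh = rng.uniform(-s, s, size=(params.n_output, params.n_hidden))
    W_hh = None
    if params.hidden_recurrence:
        W_hh = rng.uniform(-s, s, size=(params.n_hidden, params.n_hidden))
    return Weights(W_ih=W_ih, W_ho=W_ho, W_oh=W_oh, W_hh=W_hh)


def _sigma(pre: np.ndarray) -> np.ndarray:
    return expit(np.clip(pre, -PREACT_CLIP, PREACT_CLIP))


def settle_batch(
    weights: Weights,
    stimuli: np.ndarray,
    clamp_targets: Optional[np.ndarray],
    params: NetworkParams,
    predictor=None,
) -> tuple[np.ndarray, np.ndarray]:
    """Settle a batch of stimuli sharing the same weights.

    Parameters
    ----------
    stimuli
        ``(B, n_input)`` pixel array in [0, 1]; input units are held at these
        values for the whole trajectory.
    clamp_targets
        ``(B, n_output)`` one-hot teaching signals, or None for the free
        phase.  From step ``t_clamp`` the output rows are overwritten with
        the targets exactly (bit-for-bit).
    predictor
        A fitted steady-state predictor; required when adaptation is active
        (``clamp_targets`` given and ``adapt_strength > 0``).  Each hidden
        unit's target ``x~`` is computed once per trajectory from its own
        steps ``1..predictor_window`` — which precede the clamp onset, so
        they coincide with the free-phase prefix.

    Returns
    -------
    (hidden, output)
        Arrays of shape ``(B, T_settle, n_hidden)`` and
        ``(B, T_settle, n_output)``.
    """
    stimuli = np.atleast_2d(np.asarray(stimuli, dtype=float))
    B = stimuli.shape[0]
    if stimuli.shape[1] != params.n_input:
        raise ConfigurationError(
            f"stimulus length {stimuli.shape[1]} != n_input {params.n_input}"
        )
    clamped = clamp_targets is not None
    if clamped:
        clamp_targets = np.atleast_2d(np.asarray(clamp_targets, dtype=float))
        if clamp_targets.shape != (B, params.n_output):
            raise ConfigurationError(
                f"clamp_targets shape {clamp_targets.shape} != ({B}, {params.n_output})"
            )
    a = params.adapt_strength
    adapting = clamped and a > 0.0
    if adapting and predictor is None:
        raise ConfigurationError("adapt_strength > 0 requires a fitted predictor")

    H = np.empty((B, params.T_settle, params.n_hidden))
    O = np.empty((B, params.T_settle, params.n_output))
    h = np.zeros((B, params.n_hidden))
    o = np.zeros((B, params.n_output))
    x_tilde_h: Optional[np.ndarray] = None

    for t in range(1, params.T_settle + 1):
        pre_h = stimuli @ weights.W_ih + o @ weights.W_oh
        if weights.W_hh is not None:
            pre_h = pre_h + h @ weights.W_hh
        new_h = _sigma(pre_h)
        new_o = _sigma(h @ weights.W_ho)
        if clamped and t >= params.t_clamp:
            new_o = clamp_targets.copy()
        if adapting and t >= params.t_clamp:
            if x_tilde_h is None:
                K = params.predictor_window
                early = np.concatenate([H[:, :K, :], O[:, :K, :]], axis=2)
                x_tilde_h = predictor.predict_batch(early)[:, : params.n_hidden]
                # the forecast targets a logistic unit's activity, which lives
                # in (0, 1); clip so the nudge cannot push units outside the
                # activation range
                np.clip(x_tilde_h, 0.0, 1.0, out=x_tilde_h)
            new_h = a * x_tilde_h + (1.0 - a) * new_h
        h, o = new_h, new_o
        H[:, t - 1, :] = h
        O[:, t - 1, :] = o

    if not (np.isfinite(H).all() and np.isfinite(O).all()):
        raise NumericalError("non-finite activity during settling")
    return H, O


def settle(
    weights: Weights,
    stimulus: np.ndarray,
    clamp_target: Optional[np.ndarray],
    params: NetworkParams,
    predictor=None,
    stimulus_id: Optional[int] = None,
) -> Trajectory:
    """Settle a single stimulus and return its full :class:`Trajectory`."""
    stimulus = np.asarray(stimulus, dtype=float).ravel()
    targets = None if clamp_target is None else np.asarray(clamp_target, dtype=float)[None, :]
    H, O = settle_batch(weights, stimulus[None, :], targets, params, predictor)
    if clamp_target is None:
        phase = FREE
    elif params.adapt_strength > 0.0:
        phase = CLAMPED_ADAPTED
    else:
        phase = CLAMPED
    return Trajectory(
        hidden=H[0],
        output=O[0],
        stimulus=stimulus,
        phase=phase,
        clamp_target=None if clamp_target is None else np.asarray(clamp_target, dtype=float),
        stimulus_id=stimulus_id,
    )


def classify(trajectory: Trajectory) -> int:
    """Class label read out from a free-phase trajectory.

    The label is the index of the maximal output activity at the final
    settling step; ties break to the lowest index.  Clamped trajectories are
    rejected — their outputs echo the teaching signal, not a decision.
    """
    if trajectory.phase != FREE:
        raise PhaseError(f"classify needs a free-phase trajectory, got {trajectory.phase!r}")
    return int(np.argmax(trajectory.steady_output))
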