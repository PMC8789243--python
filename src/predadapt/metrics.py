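"""Quantitative measures: neuronal surprise, sNCC, accuracy summaries.

Surprise is the per-neuron absolute difference between the (clamped)
steady-state activity ``x`` and the predicted free steady state ``x~``; the
epoch-level statistic averages it over all stimuli of the epoch and over all
neurons.  The single-neuron correlate of consciousness (sNCC) is the
magnitude of the fast adaptation, ``|x - x_A|``, where ``x_A`` is the
steady state of the same clamped settle with adaptation switched on.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .exceptions import ConfigurationError

__all__ = [
    "EpochMetrics",
    "neuron_surprise",
    "epoch_surprise",
    "sncc",
    "surprise_peak",
]


@dataclass
class EpochMetrics:
    """Summary of one training epoch.

    ``mean_surprise`` averages ``|x - x~|`` over the epoch's stimuli and over
    all hidden and output units; the per-layer means are kept as diagnostics.
    ``mean_sncc`` is 0 whenever adaptation is off.
    """

    epoch: int
    accuracy: float
    mean_surprise: float
    mean_sncc: float
    n_eval_stimuli: int
    mean_surprise_hidden: float = field(default=float("nan"))
    mean_surprise_output: float = field(default=float("nan"))

    def __post_init__(self) -> None:
        if not 0.0 <= self.accuracy <= 1.0:
            raise ConfigurationError(f"accuracy {self.accuracy} outside [0, 1]")
        if self.mean_surprise < 0 or self.mean_sncc < 0:
            raise ConfigurationError("surprise and sNCC are non-negative")


def _pair(x, y) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ConfigurationError(f"shape mismatch: {x.shape} vs {y.shape}")
    return x, y


def neuron_surprise(x: np.ndarray, x_tilde: np.ndarray) -> np.ndarray:
    """Per-neuron surprise ``|x - x~|`` (element-wise)."""
    x, x_tilde = _pair(x, x_tilde)
    return np.abs(x - x_tilde)


def epoch_surprise(surprises) -> float:
    """Grand mean of a (n_stimuli, n_neurons) surprise array.

    Averaging over stimuli first and neurons second (or the reverse) gives
    the same number for a full rectangular array, so the grand mean is used.
    """
    arr = np.asarray(surprises, dtype=float)
    if arr.size == 0:
        raise ConfigurationError("epoch_surprise needs at least one stimulus")
    return float(arr.mean())


def sncc(x: np.ndarray, x_adapted: np.ndarray) -> np.ndarray:
    """Single-neuron correlate of consciousness ``|x - x_A|``.

    Both arguments must be steady states of settles that share weights,
    stimulus and clamp target and differ only in adaptation strength.
    """
    x, x_adapted = _pair(x, x_adapted)
    return np.abs(x - x_adapted)


def surprise_peak(history) -> tuple[int, float, float]:
    """Locate the rise-then-fall shape of the epoch surprise curve.

    Accepts a ``TrainHistory`` or any sequence of per-epoch mean surprises
    and returns ``(peak_epoch, peak_value, final_value)``; ties break to the
    earliest epoch.  The skill-consciousness reading is: a peak after the
    first epoch with a lower final value mirrors the conscious-competence
    stages (low surprise while "unconsciously incompetent", a surge while the
    teaching signal is salient, decline once the task is mastered).
    """
    if hasattr(history, "metrics"):
        epochs = [m.epoch for m in history.metrics]
        values = [m.mean_surprise for m in history.metrics]
    else:
        values = [float(v) for v in history]
        epochs = list(range(len(values)))
    if len(values) < 2:
        raise ConfigurationError("surprise_peak needs at least two epochs")
    arr = np.asarray(values)
    i = int(np.argmax(arr))  # first maximum on ties
    return epochs[i], float(arr[i]), float(arr[-1])
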