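"""Environmental consciousness C_e and the N-dimensional forager toy.

A forager lives in an N-dimensional sensory space.  Sensory evidence alone
would send it to ``P_s``; its internal model predicts the optimum at ``P_p``;
the true optimum (most food) sits at ``P_m``.  The organism adapts by moving
part-way from the sensory point toward the prediction, ending at ``P_A``.
Environmental consciousness is then

    C_e = d(P_s, P_m) - d(P_A, P_m)

i.e. the surprise term (how far a pure reflex would land from the optimum)
minus the adaptation error (how far the adapted organism still is).  C_e is
0 for a pure reflex (``P_A = P_s``), equals the full surprise when
adaptation is perfect (``P_A = P_m``), and is negative when the internal
model moves the organism the wrong way.  The same expression reduces to the
neuronal quantities: with a perfect model, ``C_e ~= |x - x_A| = sNCC``, and
with perfect adaptation ``C_e ~= |x - x~|``, the neuronal surprise.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Callable

import numpy as np

from .exceptions import ConfigurationError

__all__ = ["ForagerScenario", "compute_ce", "adapt_position", "neuron_ce_bridge"]


def _euclidean(p: np.ndarray, q: np.ndarray) -> float:
    return float(np.linalg.norm(p - q))


METRICS: dict[str, Callable[[np.ndarray, np.ndarray], float]] = {"euclidean": _euclidean}


def _points(*pts) -> list[np.ndarray]:
    arrs = [np.asarray(p, dtype=float).ravel() for p in pts]
    dims = {a.shape[0] for a in arrs}
    if len(dims) != 1:
        raise ConfigurationError(f"points have mismatched dimensions: {sorted(dims)}")
    return arrs


def compute_ce(P_s, P_A, P_m, metric: str = "euclidean") -> float:
    """C_e = d(P_s, P_m) - d(P_A, P_m); negative for maladaptive moves."""
    if metric not in METRICS:
        raise ConfigurationError(f"unknown metric {metric!r}")
    P_s, P_A, P_m = _points(P_s, P_A, P_m)
    d = METRICS[metric]
    return d(P_s, P_m) - d(P_A, P_m)


def adapt_position(P_s, P_p, adapt_strength: float):
    """Adapted position as a convex combination of sensory and predicted points.

    Mirrors the neuronal adaptation update: strength 0 leaves the organism at
    the sensory-driven point, strength 1 moves it fully to the prediction.
    """
    if not 0.0 <= adapt_strength <= 1.0:
        raise ConfigurationError(f"adapt_strength must lie in [0, 1], got {adapt_strength}")
    P_s, P_p = _points(P_s, P_p)
    return adapt_strength * P_p + (1.0 - adapt_strength) * P_s


def neuron_ce_bridge(x, x_A, x_tilde) -> tuple[np.ndarray, np.ndarray]:
    """The two limiting neuronal forms of C_e.

    Returns ``(|x - x_A|, |x - x~|)``: C_e as adaptation magnitude (sNCC,
    valid when the internal model is perfect) and C_e as surprise (valid
    when adaptation is perfect).  When the adapted state reaches the
    prediction exactly the two coincide.
    """
    x, x_A, x_tilde = (np.asarray(v, dtype=float) for v in (x, x_A, x_tilde))
    if not (x.shape == x_A.shape == x_tilde.shape):
        raise ConfigurationError("x, x_A and x_tilde must share one shape")
    return np.abs(x - x_A), np.abs(x - x_tilde)


@dataclass
class ForagerScenario:
    """One single-step foraging situation in an N-dimensional sensory space."""

    dim: int
    P_m: np.ndarray
    P_s: np.ndarray
    P_p: np.ndarray
    adapt_strength: float = 0.5
    metric: str = "euclidean"

    def __post_init__(self) -> None:
        self.P_m, self.P_s, self.P_p = _points(self.P_m, self.P_s, self.P_p)
        if self.P_m.shape[0] != self.dim:
            raise ConfigurationError(
                f"points have dimension {self.P_m.shape[0]}, scenario says {self.dim}"
            )
        if not 0.0 <= self.adapt_strength <= 1.0:
            raise ConfigurationError("adapt_strength must lie in [0, 1]")
        if self.metric not in METRICS:
            raise ConfigurationError(f"unknown metric {self.metric!r}")

    def adapted_position(self) -> np.ndarray:
        return adapt_position(self.P_s, self.P_p, self.adapt_strength)

    def surprise_term(self) -> float:
        return METRICS[self.metric](self.P_s, self.P_m)

    def error_term(self) -> float:
        return METRICS[self.metric](self.adapted_position(), self.P_m)

    def ce(self) -> float:
        return compute_ce(self.P_s, self.adapted_position(), self.P_m, self.metric)

    # -- JSON round trip ---------------------------------------------------
    @classmethod
    def from_json(cls, path) -> "ForagerScenario":
        raw = json.loads(Path(path).read_text())
        try:
            return cls(
                dim=int(raw["dim"]),
                P_m=raw["P_m"],
                P_s=raw["P_s"],
                P_p=raw["P_p"],
                adapt_strength=float(raw.get("adapt_strength", 0.5)),
                metric=raw.get("metric", "euclidean"),
            )
        except KeyError as exc:  # pragma: no cover - message only
            raise ConfigurationError(f"scenario file missing field {exc}") from exc

    def to_json(self, path) -> None:
        payload = {
            "dim": self.dim,
            "P_m": self.P_m.tolist(),
            "P_s": self.P_s.tolist(),
            "P_p": self.P_p.tolist(),
            "adapt_strength": self.adapt_strength,
            "metric": self.metric,
        }
        Path(path).write_text(json.dumps(payload, indent=2))
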