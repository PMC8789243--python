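"""Predictive synaptic learning and the epoch training loop.

The synaptic rule adjusts each weight in proportion to the presynaptic
steady activity and the postsynaptic *surprise* — the gap between the
clamped steady state and the neuron's own forecast of its free steady
state::

    dw[i, j] = alpha * x_pre[i] * (x_post[j] - x~_post[j])

With the forecast forced to zero the rule degenerates to Hebb's rule
``dw = alpha * x_pre * x_post`` ("cells that fire together, wire together").

One training epoch runs, for each stimulus in seeded random order, a clamped
settle (with adaptation when enabled), forecasts every neuron's steady state
from the trajectory's own early steps, and applies the rule online to every
plastic matrix.  An experiment is: fit the steady-state predictors on a
block of free-phase settles, then repeat epochs of (optional predictor
refit -> clamped training pass -> free-phase evaluation), logging accuracy,
mean surprise and mean sNCC per epoch.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__
from .data import Dataset
from .exceptions import ConfigurationError, NumericalError
from .metrics import EpochMetrics
from .net import NetworkParams, Weights, init_weights, settle_batch
from .predictor import SteadyStatePredictor

logger = logging.getLogger(__name__)

__all__ = [
    "TrainConfig",
    "TrainHistory",
    "weight_update",
    "train_epoch",
    "evaluate",
    "run_experiment",
]


@dataclass(frozen=True)
class TrainConfig:
    """Hyper-parameters of the training procedure.

    ``stimuli_per_epoch`` and ``predictor_fit_stimuli`` default to the
    reference protocol (400 clamped presentations per epoch after an initial
    1,600-stimulus free-phase block for the predictor fit).  The learning
    rate has no reference value; 0.01 makes the toy protocols converge
    within a couple hundred epochs.
    """

    learning_rate: float = 0.01
    n_epochs: int = 10
    stimuli_per_epoch: int = 400
    predictor_fit_stimuli: int = 1600
    eval_stimuli: int = 400
    refit_every_n_epochs: int = 1
    ridge: float = 0.0
    zero_prediction: bool = False  # force x~ = 0: pure Hebbian reduction
    batch_updates: bool = False  # accumulate dw over the epoch, apply once
    max_weight: Optional[float] = None  # optional divergence guard
    seed: int = 0
    dataset_ref: str = ""

    def __post_init__(self) -> None:
        if self.learning_rate < 0:
            raise ConfigurationError("learning_rate must be >= 0")
        for name in ("n_epochs",):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        for name in ("stimuli_per_epoch", "predictor_fit_stimuli", "eval_stimuli"):
            if getattr(self, name) < 1:
                raise ConfigurationError(f"{name} must be >= 1")
        if self.refit_every_n_epochs < 1:
            raise ConfigurationError("refit_every_n_epochs must be >= 1")


@dataclass
class TrainHistory:
    """Per-epoch metrics, final weights and a reproducibility manifest."""

    metrics: list[EpochMetrics]
    weights: Weights
    predictor: SteadyStatePredictor
    config: TrainConfig
    params: NetworkParams
    manifest: dict = field(default_factory=dict)

    def metrics_frame(self) -> pd.DataFrame:
        return pd.DataFrame([asdict(m) for m in self.metrics])

    def save(self, out_dir) -> None:
        """Write metrics.csv, manifest.json and a named-array weights file."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.metrics_frame().to_csv(out / "metrics.csv", index=False)
        (out / "manifest.json").write_text(json.dumps(self.manifest, indent=2, sort_keys=True))
        np.savez(out / "weights.npz", **self.weights.as_dict())


def weight_update(x_pre, x_post, x_tilde_post, learning_rate: float) -> np.ndarray:
    """Predictive synaptic update ``alpha * x_pre (x_post - x~_post)``.

    Scalars give a scalar dw; vectors give the outer-product update for a
    full pre x post weight matrix.
    """
    x_pre = np.asarray(x_pre, dtype=float)
    x_post = np.asarray(x_post, dtype=float)
    x_tilde_post = np.asarray(x_tilde_post, dtype=float)
    if not (
        np.isfinite(x_pre).all() and np.isfinite(x_post).all() and np.isfinite(x_tilde_post).all()
    ):
        raise NumericalError("non-finite activity in weight update")
    diff = x_post - x_tilde_post
    if x_pre.ndim == 0:
        return learning_rate * x_pre * diff
    return learning_rate * np.outer(x_pre, diff)


def _one_hot(labels: np.ndarray, n_classes: int) -> np.ndarray:
    return np.eye(n_classes)[np.asarray(labels, dtype=int)]


def _sample(rng: np.random.Generator, n_avail: int, n_want: int, what: str) -> np.ndarray:
    if n_avail >= n_want:
        return rng.choice(n_avail, size=n_want, replace=False)
    warnings.warn(
        f"dataset has {n_avail} stimuli but {n_want} requested for {what}; "
        "sampling with replacement",
        stacklevel=2,
    )
    return rng.choice(n_avail, size=n_want, replace=True)


def _check_weights(weights: Weights, config: TrainConfig) -> None:
    for name, mat in weights.as_dict().items():
        if not np.isfinite(mat).all():
            raise NumericalError(f"{name} diverged to non-finite values")
        if config.max_weight is not None:
            np.clip(mat, -config.max_weight, config.max_weight, out=mat)


def fit_predictor_on(
    weights: Weights,
    dataset: Dataset,
    n_stimuli: int,
    params: NetworkParams,
    rng: np.random.Generator,
    ridge: float = 0.0,
) -> SteadyStatePredictor:
    """Fit steady-state predictors on fresh free-phase settles."""
    idx = _sample(rng, len(dataset), n_stimuli, "predictor fit")
    H, O = settle_batch(weights, dataset.stimuli[idx], None, params)
    return SteadyStatePredictor(window=params.predictor_window, ridge=ridge).fit_batch(H, O)


def evaluate(
    weights: Weights,
    predictor: SteadyStatePredictor,
    dataset: Dataset,
    params: NetworkParams,
    n_stimuli: int,
    rng: np.random.Generator,
    compute_surprise: bool = False,
) -> dict:
    """Free-phase accuracy plus (optionally) surprise and sNCC on a sample.

    Accuracy is the fraction of free settles whose final-step output argmax
    matches the label.  sNCC pairs a clamped settle with adaptation against
    the identical settle without it and averages ``|x - x_A|`` over units
    and stimuli (0 when adaptation is off).
    """
    idx = _sample(rng, len(dataset), min(n_stimuli, len(dataset)), "evaluation")
    stimuli = dataset.stimuli[idx]
    labels = dataset.labels[idx]
    _, O_free = settle_batch(weights, stimuli, None, params)
    pred_labels = np.argmax(O_free[:, -1, :], axis=1)
    out = {"accuracy": float(np.mean(pred_labels == labels)), "n_eval": len(idx)}

    targets = _one_hot(labels, params.n_output)
    if params.adapt_strength > 0.0:
        base = params.with_adaptation(0.0)
        H0, O0 = settle_batch(weights, stimuli, targets, base)
        Ha, Oa = settle_batch(weights, stimuli, targets, params, predictor)
        x0 = np.concatenate([H0[:, -1, :], O0[:, -1, :]], axis=1)
        xa = np.concatenate([Ha[:, -1, :], Oa[:, -1, :]], axis=1)
        out["mean_sncc"] = float(np.abs(x0 - xa).mean())
        H_cl, O_cl = Ha, Oa
    else:
        out["mean_sncc"] = 0.0
        H_cl = O_cl = None

    if compute_surprise:
        if H_cl is None:
            H_cl, O_cl = settle_batch(weights, stimuli, targets, params, predictor)
        K = predictor.window
        early = np.concatenate([H_cl[:, :K, :], O_cl[:, :K, :]], axis=2)
        x_tilde = predictor.predict_batch(early)
        x = np.concatenate([H_cl[:, -1, :], O_cl[:, -1, :]], axis=1)
        surp = np.abs(x - x_tilde)
        nh = params.n_hidden
        out["mean_surprise"] = float(surp.mean())
        out["mean_surprise_hidden"] = float(surp[:, :nh].mean())
        out["mean_surprise_output"] = float(surp[:, nh:].mean())
    return out


def train_epoch(
    weights: Weights,
    predictor: SteadyStatePredictor,
    dataset: Dataset,
    config: TrainConfig,
    params: NetworkParams,
    rng: Optional[np.random.Generator] = None,
    epoch: int = 1,
    eval_dataset: Optional[Dataset] = None,
) -> tuple[Weights, EpochMetrics]:
    """One clamped training pass followed by a free-phase evaluation.

    The input ``weights`` are left untouched; the updated copy is returned.
    Surprise is accumulated from the training pass itself (clamped steady
    state vs the trajectory's own forecast), averaged over the epoch's
    stimuli and all hidden + output units.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    w = weights.copy()
    idx = _sample(rng, len(dataset), config.stimuli_per_epoch, "training")
    nh = params.n_hidden
    K = params.predictor_window
    lr = config.learning_rate
    surprises = np.empty((len(idx), params.n_units))
    acc_ih = acc_ho = acc_oh = None
    if config.batch_updates:
        acc_ih = np.zeros_like(w.W_ih)
        acc_ho = np.zeros_like(w.W_ho)
        acc_oh = np.zeros_like(w.W_oh)

    for s, i in enumerate(idx):
        stim = dataset.stimuli[i]
        target = _one_hot(dataset.labels[i : i + 1], params.n_output)
        H, O = settle_batch(w, stim[None, :], target, params, predictor)
        early = np.concatenate([H[:, :K, :], O[:, :K, :]], axis=2)
        if config.zero_prediction:
            x_tilde = np.zeros(params.n_units)
        else:
            x_tilde = predictor.predict_batch(early)[0]
        x_h = H[0, -1, :]
        x_o = O[0, -1, :]  # equals the clamp target bit-for-bit
        d_h = x_h - x_tilde[:nh]
        d_o = x_o - x_tilde[nh:]
        surprises[s, :nh] = np.abs(d_h)
        surprises[s, nh:] = np.abs(d_o)

        dw_ih = lr * np.outer(stim, d_h)
        dw_ho = lr * np.outer(x_h, d_o)
        dw_oh = None if params.symmetric_feedback else lr * np.outer(x_o, d_h)
        if config.batch_updates:
            acc_ih += dw_ih
            acc_ho += dw_ho
            if dw_oh is not None:
                acc_oh += dw_oh
        else:
            w.W_ih += dw_ih
            w.W_ho += dw_ho
            if dw_oh is None:
                w.W_oh = w.W_ho.T.copy()
            else:
                w.W_oh += dw_oh

    if config.batch_updates:
        w.W_ih += acc_ih
        w.W_ho += acc_ho
        if params.symmetric_feedback:
            w.W_oh = w.W_ho.T.copy()
        else:
            w.W_oh += acc_oh
    _check_weights(w, config)

    stats = evaluate(
        w,
        predictor,
        eval_dataset if eval_dataset is not None else dataset,
        params,
        config.eval_stimuli,
        rng,
    )
    metrics = EpochMetrics(
        epoch=epoch,
        accuracy=stats["accuracy"],
        mean_surprise=float(surprises.mean()),
        mean_sncc=stats["mean_sncc"],
        n_eval_stimuli=stats["n_eval"],
        mean_surprise_hidden=float(surprises[:, :nh].mean()),
        mean_surprise_output=float(surprises[:, nh:].mean()),
    )
    return w, metrics


def run_experiment(
    config: TrainConfig,
    params: NetworkParams,
    dataset: Dataset,
    eval_dataset: Optional[Dataset] = None,
) -> TrainHistory:
    """Full experiment: initial predictor fit, epochs, metrics, manifest.

    Weight initialisation is seeded by ``params.seed``; all stimulus
    sampling by ``config.seed``.  Runs are bitwise reproducible.
    """
    if dataset.n_classes != params.n_output:
        raise ConfigurationError(
            f"dataset has {dataset.n_classes} classes but network {params.n_output} outputs"
        )
    if dataset.n_pixels != params.n_input:
        raise ConfigurationError(
            f"dataset has {dataset.n_pixels} pixels but network {params.n_input} inputs"
        )
    rng = np.random.default_rng(config.seed)
    weights = init_weights(params)
    predictor = fit_predictor_on(
        weights, dataset, config.predictor_fit_stimuli, params, rng, config.ridge
    )
    eval_ds = eval_dataset if eval_dataset is not None else dataset

    stats0 = evaluate(
        weights, predictor, eval_ds, params, config.eval_stimuli, rng, compute_surprise=True
    )
    metrics = [
        EpochMetrics(
            epoch=0,
            accuracy=stats0["accuracy"],
            mean_surprise=stats0["mean_surprise"],
            mean_sncc=stats0["mean_sncc"],
            n_eval_stimuli=stats0["n_eval"],
            mean_surprise_hidden=stats0["mean_surprise_hidden"],
            mean_surprise_output=stats0["mean_surprise_output"],
        )
    ]
    logger.info("epoch 0: accuracy=%.3f surprise=%.4f", stats0["accuracy"], stats0["mean_surprise"])

    for epoch in range(1, config.n_epochs + 1):
        # epoch 1 keeps the initial large-block fit (weights are unchanged);
        # later epochs refit on fresh free runs so the forecast tracks the
        # current weights.
        if epoch > 1 and (epoch - 1) % config.refit_every_n_epochs == 0:
            predictor = fit_predictor_on(
                weights, dataset, config.stimuli_per_epoch, params, rng, config.ridge
            )
        weights, em = train_epoch(
            weights, predictor, dataset, config, params, rng, epoch, eval_ds
        )
        metrics.append(em)
        logger.info(
            "epoch %d: accuracy=%.3f surprise=%.4f sncc=%.4f",
            epoch,
            em.accuracy,
            em.mean_surprise,
            em.mean_sncc,
        )

    manifest = {
        "package": "predadapt",
        "version": __version__,
        "numpy_version": np.__version__,
        "config": asdict(config),
        "params": asdict(params),
        "n_stimuli": len(dataset),
    }
    return TrainHistory(
        metrics=metrics,
        weights=weights,
        predictor=predictor,
        config=config,
        params=params,
        manifest=manifest,
    )
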