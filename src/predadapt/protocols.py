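"""Canonical experiment protocols.

Two ready-made configurations of the digit experiment:

* the **reference protocol** — the 420-50-10 network on 28x28 digit images
  center-cropped to 21x20, with 1,600 free-phase stimuli for the initial
  predictor fit and 400 clamped stimuli per epoch;
* a **reduced protocol** — a 100-20-5 network on 10x10 synthetic digits with
  proportionally smaller per-epoch sample sizes, used by the test suite and
  the acceptance script so a full multi-seed study runs in seconds.

The reduced protocol fixes its study conditions once: pixel-noise SD 0.4
(hard enough that accuracy stays off the ceiling, comparable to hand-written
digits), learning rate 0.05 (the epoch budget then covers the full
rise-and-fall of the surprise curve), a small ridge penalty on the
steady-state predictors (their OLS designs grow near-collinear once
trajectories saturate late in training), and a held-out evaluation set drawn
from the same generator with an offset seed.
"""

from __future__ import annotations

from typing import Optional

from .data import Dataset, crop_center, generate_synthetic_digits
from .learning import TrainConfig, TrainHistory, run_experiment
from .net import NetworkParams

__all__ = ["reduced_digit_protocol", "reference_digit_protocol", "reduced_dataset"]

#: seed offset separating the held-out evaluation draw from the training draw
EVAL_SEED_OFFSET = 100_003


def reduced_dataset(
    seed: int,
    n_per_class: int = 40,
    n_classes: int = 5,
    image_shape: tuple[int, int] = (10, 10),
    noise_sd: float = 0.4,
) -> Dataset:
    """Synthetic digit set for the reduced protocol (default 200 stimuli)."""
    return generate_synthetic_digits(
        n_per_class=n_per_class,
        n_classes=n_classes,
        image_shape=image_shape,
        noise_sd=noise_sd,
        seed=seed,
    )


def reduced_digit_protocol(
    seed: int,
    adapt_strength: float = 0.0,
    n_epochs: int = 60,
    learning_rate: float = 0.05,
    n_hidden: int = 20,
    ridge: float = 1e-3,
    dataset: Optional[Dataset] = None,
    eval_dataset: Optional[Dataset] = None,
) -> TrainHistory:
    """Run the 100-20-5 reduced digit experiment for one seed.

    Accuracy is measured on a held-out set of fresh generator draws
    (1,000 stimuli) so late-training differences are not drowned in
    evaluation noise.
    """
    ds = dataset if dataset is not None else reduced_dataset(seed)
    ev = (
        eval_dataset
        if eval_dataset is not None
        else reduced_dataset(seed + EVAL_SEED_OFFSET, n_per_class=200)
    )
    params = NetworkParams(
        n_input=ds.n_pixels,
        n_hidden=n_hidden,
        n_output=ds.n_classes,
        adapt_strength=adapt_strength,
        seed=seed,
    )
    config = TrainConfig(
        learning_rate=learning_rate,
        n_epochs=n_epochs,
        stimuli_per_epoch=80,
        predictor_fit_stimuli=200,
        eval_stimuli=1000,
        ridge=ridge,
        seed=seed,
        dataset_ref=f"synthetic-digits-{ds.image_shape[0]}x{ds.image_shape[1]}",
    )
    return run_experiment(config, params, ds, eval_dataset=ev)


def reference_digit_protocol(
    seed: int,
    adapt_strength: float = 0.0,
    n_epochs: int = 50,
    learning_rate: float = 0.05,
    n_per_class: int = 200,
    noise_sd: float = 0.4,
) -> TrainHistory:
    """Run the 420-50-10 protocol on synthetic 28x28 digits cropped to 21x20."""
    ds = crop_center(
        generate_synthetic_digits(
            n_per_class=n_per_class, n_classes=10, image_shape=(28, 28),
            noise_sd=noise_sd, seed=seed,
        ),
        (21, 20),
    )
    ev = crop_center(
        generate_synthetic_digits(
            n_per_class=100, n_classes=10, image_shape=(28, 28),
            noise_sd=noise_sd, seed=seed + EVAL_SEED_OFFSET,
        ),
        (21, 20),
    )
    params = NetworkParams(
        n_input=420, n_hidden=50, n_output=10, adapt_strength=adapt_strength, seed=seed
    )
    config = TrainConfig(
        learning_rate=learning_rate,
        n_epochs=n_epochs,
        ridge=1e-3,
        seed=seed,
        dataset_ref="synthetic-digits-28x28-cropped-21x20",
    )
    return run_experiment(config, params, ds, eval_dataset=ev)
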