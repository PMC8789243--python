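"""scikit-learn estimator facade over the training loop.

`PredictiveNetClassifier` wraps the full experiment (weight initialisation,
predictor fits, clamped training epochs) behind the familiar fit/predict
surface so the network composes with sklearn model selection.  Inputs must
be pixel-like features in [0, 1] — the input units are clamped directly to
the feature values.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted, check_X_y, check_array

from .data import Dataset
from .learning import TrainConfig, run_experiment
from .net import NetworkParams, settle_batch

__all__ = ["PredictiveNetClassifier"]


class PredictiveNetClassifier(ClassifierMixin, BaseEstimator):
    """Recurrent network classifier trained with the predictive rule.

    Parameters mirror :class:`~predadapt.net.NetworkParams` and
    :class:`~predadapt.learning.TrainConfig`; ``random_state`` seeds both
    the weight initialisation and the stimulus sampling.

    Attributes
    ----------
    classes_ : ndarray
        Sorted unique class labels seen in ``fit``.
    weights_ : Weights
        Final plastic weight matrices.
    predictor_ : SteadyStatePredictor
        Per-neuron steady-state forecaster fitted on the last refit.
    history_ : TrainHistory
        Full per-epoch metrics (accuracy, mean surprise, mean sNCC).
    """

    def __init__(
        self,
        n_hidden: int = 50,
        n_epochs: int = 20,
        learning_rate: float = 0.01,
        adapt_strength: float = 0.0,
        T_settle: int = 20,
        t_clamp: int = 8,
        predictor_window: int = 5,
        stimuli_per_epoch: int = 400,
        predictor_fit_stimuli: int = 1600,
        eval_stimuli: int = 200,
        weight_init_scale: float = 0.1,
        symmetric_feedback: bool = False,
        hidden_recurrence: bool = False,
        random_state: int = 0,
    ):
        self.n_hidden = n_hidden
        self.n_epochs = n_epochs
        self.learning_rate = learning_rate
        self.adapt_strength = adapt_strength
        self.T_settle = T_settle
        self.t_clamp = t_clamp
        self.predictor_window = predictor_window
        self.stimuli_per_epoch = stimuli_per_epoch
        self.predictor_fit_stimuli = predictor_fit_stimuli
        self.eval_stimuli = eval_stimuli
        self.weight_init_scale = weight_init_scale
        self.symmetric_feedback = symmetric_feedback
        self.hidden_recurrence = hidden_recurrence
        self.random_state = random_state

    def _check_pixels(self, X: np.ndarray) -> None:
        if X.size and (X.min() < 0 or X.max() > 1):
            raise ValueError("features must be pixel-like values in [0, 1]")

    def fit(self, X, y) -> "PredictiveNetClassifier":
        X, y = check_X_y(X, y, dtype=float)
        self._check_pixels(X)
        self.classes_, y_idx = np.unique(y, return_inverse=True)
        if len(self.classes_) < 2:
            raise ValueError("need at least two classes")
        self.n_features_in_ = X.shape[1]

        # image_shape is a formality here: features are already flat vectors
        params = NetworkParams(
            n_input=X.shape[1],
            n_hidden=self.n_hidden,
            n_output=len(self.classes_),
            T_settle=self.T_settle,
            t_clamp=self.t_clamp,
            predictor_window=self.predictor_window,
            adapt_strength=self.adapt_strength,
            weight_init_scale=self.weight_init_scale,
            symmetric_feedback=self.symmetric_feedback,
            hidden_recurrence=self.hidden_recurrence,
            seed=self.random_state,
        )
        config = TrainConfig(
            learning_rate=self.learning_rate,
            n_epochs=self.n_epochs,
            stimuli_per_epoch=min(self.stimuli_per_epoch, X.shape[0]),
            predictor_fit_stimuli=min(self.predictor_fit_stimuli, X.shape[0]),
            eval_stimuli=min(self.eval_stimuli, X.shape[0]),
            seed=self.random_state,
        )
        dataset = Dataset(
            stimuli=X,
            labels=y_idx,
            image_shape=(1, X.shape[1]),
            provenance="synthetic",
            n_classes=len(self.classes_),
        )
        self.history_ = run_experiment(config, params, dataset)
        self.weights_ = self.history_.weights
        self.predictor_ = self.history_.predictor
        self.params_ = params
        return self

    def decision_function(self, X) -> np.ndarray:
        """Final-step free-phase output activity per class."""
        check_is_fitted(self, "weights_")
        X = check_array(X, dtype=float)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"X has {X.shape[1]} features, classifier was fitted with {self.n_features_in_}"
            )
        self._check_pixels(X)
        _, O = settle_batch(self.weights_, X, None, self.params_)
        return O[:, -1, :]

    def predict(self, X) -> np.ndarray:
        scores = self.decision_function(X)
        return self.classes_[np.argmax(scores, axis=1)]
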