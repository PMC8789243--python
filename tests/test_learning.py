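"""Predictive weight update and the epoch training loop."""

import numpy as np
import pytest

from predadapt import (
    Dataset,
    NetworkParams,
    TrainConfig,
    init_weights,
    run_experiment,
    settle,
    train_epoch,
    weight_update,
)
from predadapt.exceptions import NumericalError
from predadapt.learning import fit_predictor_on


def _toy_dataset(rng, n, n_pixels, n_classes):
    return Dataset(
        stimuli=rng.uniform(0, 1, (n, n_pixels)),
        labels=rng.integers(0, n_classes, n),
        image_shape=(1, n_pixels),
        n_classes=n_classes,
    )


class TestWeightUpdate:
    def test_direct_arithmetic(self):
        assert weight_update(0.5, 0.8, 0.6, 0.1) == pytest.approx(0.01, abs=1e-15)

    def test_zero_forecast_reduces_to_hebb(self, rng):
        pre = rng.uniform(0, 1, 4)
        post = rng.uniform(0, 1, 3)
        dw = weight_update(pre, post, np.zeros(3), 0.2)
        assert np.allclose(dw, 0.2 * np.outer(pre, post), atol=0)

    def test_zero_surprise_means_no_learning(self, rng):
        post = rng.uniform(0, 1, 3)
        dw = weight_update(rng.uniform(0, 1, 4), post, post, 0.5)
        assert np.all(dw == 0)

    def test_linear_in_learning_rate(self, rng):
        pre, post, tilde = rng.uniform(0, 1, (3, 5))
        dw1 = weight_update(pre, post, tilde, 0.01)
        dw2 = weight_update(pre, post, tilde, 0.02)
        assert np.allclose(dw2, 2 * dw1, rtol=1e-12)

    def test_non_finite_rejected(self):
        with pytest.raises(NumericalError):
            weight_update(np.array([np.inf]), np.array([1.0]), np.array([0.0]), 0.1)


class TestTrainEpoch:
    def test_zero_learning_rate_is_noop(self, rng):
        params = NetworkParams(n_input=4, n_hidden=3, n_output=2, seed=1)
        ds = _toy_dataset(rng, 10, 4, 2)
        w = init_weights(params)
        config = TrainConfig(
            learning_rate=0.0, stimuli_per_epoch=10, predictor_fit_stimuli=10, eval_stimuli=10
        )
        pred = fit_predictor_on(w, ds, 10, params, np.random.default_rng(0))
        w2, _ = train_epoch(w, pred, ds, config, params)
        for name, mat in w.as_dict().items():
            assert np.array_equal(mat, w2.as_dict()[name])

    def test_zero_prediction_equals_manual_hebbian_loop(self, rng):
        # trace-level oracle: replicate the epoch by hand with x~ = 0
        params = NetworkParams(n_input=4, n_hidden=3, n_output=2, seed=3)
        ds = _toy_dataset(rng, 8, 4, 2)
        w0 = init_weights(params)
        config = TrainConfig(
            learning_rate=0.05,
            stimuli_per_epoch=8,
            predictor_fit_stimuli=8,
            eval_stimuli=8,
            zero_prediction=True,
            seed=11,
        )
        pred = fit_predictor_on(w0, ds, 8, params, np.random.default_rng(0))
        got, _ = train_epoch(w0, pred, ds, config, params)

        manual = w0.copy()
        order = np.random.default_rng(config.seed).choice(8, size=8, replace=False)
        for i in order:
            stim = ds.stimuli[i]
            target = np.eye(2)[ds.labels[i]]
            traj = settle(manual, stim, target, params)
            x_h, x_o = traj.steady_hidden, traj.steady_output
            manual.W_ih += weight_update(stim, x_h, np.zeros(3), 0.05)
            manual.W_ho += weight_update(x_h, x_o, np.zeros(2), 0.05)
            manual.W_oh += weight_update(x_o, x_h, np.zeros(3), 0.05)
        for name, mat in manual.as_dict().items():
            assert np.allclose(mat, got.as_dict()[name], atol=1e-14)

    def test_rigged_perfect_forecast_freezes_weights(self, rng):
        # when x~ equals the clamped steady state exactly, surprise is zero
        # and the epoch changes nothing
        from predadapt.predictor import SteadyStatePredictor

        params = NetworkParams(n_input=4, n_hidden=3, n_output=2, seed=5)
        stim = rng.uniform(0, 1, 4)
        ds = Dataset(stimuli=stim[None, :], labels=[1], image_shape=(1, 4), n_classes=2)
        w = init_weights(params)
        traj = settle(w, stim, np.eye(2)[1], params)
        pred = SteadyStatePredictor(window=params.predictor_window)
        pred.lambdas_ = np.zeros((5, params.predictor_window))
        pred.offset_ = traj.steady.copy()
        pred.n_hidden_, pred.n_output_, pred.n_fit_ = 3, 2, 0
        config = TrainConfig(
            learning_rate=0.3, stimuli_per_epoch=1, predictor_fit_stimuli=1, eval_stimuli=1
        )
        w2, em = train_epoch(w, pred, ds, config, params)
        assert em.mean_surprise == 0.0
        for name, mat in w.as_dict().items():
            assert np.array_equal(mat, w2.as_dict()[name])

    def test_small_dataset_samples_with_replacement_and_warns(self, rng):
        params = NetworkParams(n_input=4, n_hidden=3, n_output=2, seed=2)
        ds = _toy_dataset(rng, 3, 4, 2)
        w = init_weights(params)
        pred = fit_predictor_on(w, ds, 8, params, np.random.default_rng(0))
        config = TrainConfig(stimuli_per_epoch=10, predictor_fit_stimuli=8, eval_stimuli=3)
        with pytest.warns(UserWarning, match="replacement"):
            train_epoch(w, pred, ds, config, params)

    def test_max_weight_guard_clips(self, rng):
        params = NetworkParams(n_input=4, n_hidden=3, n_output=2, seed=2)
        ds = _toy_dataset(rng, 10, 4, 2)
        w = init_weights(params)
        pred = fit_predictor_on(w, ds, 10, params, np.random.default_rng(0))
        config = TrainConfig(
            learning_rate=50.0,
            stimuli_per_epoch=10,
            predictor_fit_stimuli=10,
            eval_stimuli=5,
            max_weight=0.5,
        )
        w2, _ = train_epoch(w, pred, ds, config, params)
        assert w2.max_abs() <= 0.5


class TestRunExperiment:
    def test_zero_epochs_leaves_initial_record_only(self, rng):
        params = NetworkParams(n_input=6, n_hidden=3, n_output=2, seed=4)
        ds = _toy_dataset(rng, 20, 6, 2)
        config = TrainConfig(
            n_epochs=0, stimuli_per_epoch=10, predictor_fit_stimuli=15, eval_stimuli=10
        )
        hist = run_experiment(config, params, ds)
        assert len(hist.metrics) == 1
        assert hist.metrics[0].epoch == 0

    def test_same_seed_reproduces_metrics_exactly(self, rng):
        params = NetworkParams(n_input=6, n_hidden=3, n_output=2, seed=4)
        ds = _toy_dataset(rng, 30, 6, 2)
        config = TrainConfig(
            n_epochs=3, stimuli_per_epoch=15, predictor_fit_stimuli=20, eval_stimuli=15, seed=9
        )
        h1 = run_experiment(config, params, ds)
        h2 = run_experiment(config, params, ds)
        assert h1.metrics_frame().equals(h2.metrics_frame())
        for name, mat in h1.weights.as_dict().items():
            assert np.array_equal(mat, h2.weights.as_dict()[name])

    def test_surprise_decreases_on_repeated_single_stimulus(self, rng):
        # one stimulus presented over and over: the forecast tracks the
        # clamped endpoint and the surprise shrinks epoch over epoch
        params = NetworkParams(n_input=3, n_hidden=3, n_output=2, seed=6)
        stim = rng.uniform(0, 1, 3)
        ds = Dataset(
            stimuli=np.tile(stim, (8, 1)), labels=[1] * 8, image_shape=(1, 3), n_classes=2
        )
        config = TrainConfig(
            learning_rate=0.3,
            n_epochs=10,
            stimuli_per_epoch=8,
            predictor_fit_stimuli=8,
            eval_stimuli=8,
        )
        hist = run_experiment(config, params, ds)
        surprises = [m.mean_surprise for m in hist.metrics[1:]]
        assert all(s2 < s1 for s1, s2 in zip(surprises, surprises[1:]))
        assert surprises[-1] < 0.1 * max(surprises)

    def test_history_save_roundtrip(self, rng, tmp_path):
        params = NetworkParams(n_input=6, n_hidden=3, n_output=2, seed=4)
        ds = _toy_dataset(rng, 20, 6, 2)
        config = TrainConfig(
            n_epochs=1, stimuli_per_epoch=10, predictor_fit_stimuli=15, eval_stimuli=10
        )
        hist = run_experiment(config, params, ds)
        hist.save(tmp_path)
        assert (tmp_path / "metrics.csv").exists()
        assert (tmp_path / "manifest.json").exists()
        loaded = np.load(tmp_path / "weights.npz")
        assert np.array_equal(loaded["W_ih"], hist.weights.W_ih)
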