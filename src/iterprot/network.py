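"""Feedforward network with greedy stacked-autoencoder pretraining.

Every predictor in the pipeline is the same architecture: three sigmoid
hidden layers of 150 units and a sigmoid output head (3 units for
secondary structure, 1 for relative ASA, 8 for the angle sin/cos
channels).  Hidden weights are initialized greedily, one sparse
autoencoder per layer (linear activations, L1 activity penalty), then the
whole stack is refined by plain stochastic back-propagation on a squared
error loss under a stepped learning-rate ladder (1, 0.5, 0.2, 0.05 with a
fixed number of epochs at each rate).

Everything is plain NumPy and fully deterministic given the config seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np


@dataclass(frozen=True)
class NetworkConfig:
    """Hyper-parameters for one predictor network.

    The defaults are the reference schedule: 10 autoencoder epochs at rate
    0.05, then back-propagation at rates (1, 0.5, 0.2, 0.05) for 30 epochs
    each.  ``scaled`` derives a cheaper schedule with the same rate ladder
    for desk-scale experiments.
    """

    hidden_layers: tuple[int, ...] = (150, 150, 150)
    ae_learning_rate: float = 0.05
    ae_epochs: int = 10
    bp_learning_rates: tuple[float, ...] = (1.0, 0.5, 0.2, 0.05)
    bp_epochs_per_rate: int = 30
    seed: int = 0
    batch_size: int = 128
    sparsity_weight: float = 1e-4
    momentum: float = 0.0
    weight_decay: float = 0.0
    loss: str = "squared"  # or "cross_entropy"

    def __post_init__(self) -> None:
        if any(w <= 0 for w in self.hidden_layers):
            raise ValueError("hidden layer widths must be positive")
        if self.ae_learning_rate <= 0 or any(
                r < 0 for r in self.bp_learning_rates):
            raise ValueError("learning rates must be positive")
        if self.loss not in ("squared", "cross_entropy"):
            raise ValueError(f"unknown loss {self.loss!r}")

    def scaled(self, ae_epochs: int, bp_epochs_per_rate: int,
               **overrides) -> "NetworkConfig":
        """A copy with a shorter epoch budget (rate ladder unchanged)."""
        return replace(self, ae_epochs=ae_epochs,
                       bp_epochs_per_rate=bp_epochs_per_rate, **overrides)


@dataclass
class TrainedNetwork:
    """Weights + config of one trained predictor.

    ``weights`` is a list of (W, b) per layer, hidden layers first, output
    head last.  Hidden and output activations are sigmoid.
    """

    weights: list[tuple[np.ndarray, np.ndarray]]
    config: NetworkConfig
    input_dim: int
    output_dim: int
    loss_history: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        dims = [self.input_dim, *self.config.hidden_layers, self.output_dim]
        for k, (W, b) in enumerate(self.weights):
            if W.shape != (dims[k], dims[k + 1]) or b.shape != (dims[k + 1],):
                raise ValueError(
                    f"layer {k}: weight shape {W.shape} does not chain "
                    f"{dims[k]} -> {dims[k + 1]}"
                )


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def _glorot(rng: np.random.Generator, n_in: int, n_out: int,
            gain: float = 1.0) -> np.ndarray:
    # gain 4 for sigmoid layers, 1 for linear (autoencoder) layers
    limit = gain * np.sqrt(6.0 / (n_in + n_out))
    return (rng.random((n_in, n_out)) - 0.5) * 2.0 * limit


def _minibatches(n: int, batch_size: int, rng: np.random.Generator):
    order = rng.permutation(n)
    for start in range(0, n, batch_size):
        yield order[start:start + batch_size]


def pretrain_stack(X: np.ndarray, config: NetworkConfig,
                   rng: np.random.Generator | None = None,
                   return_history: bool = False):
    """Greedy layer-wise initialization of the hidden stack.

    One linear sparse autoencoder is trained per hidden layer on the
    activations of the layers below it (10 epochs at rate 0.05 by default,
    L1 activity penalty).  Only the encoder half is kept.  Activations are
    propagated to the next layer through the sigmoid the assembled network
    will apply, so each autoencoder sees inputs on the scale its layer will
    receive.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    X = np.asarray(X, dtype=float)
    H = X
    encoders: list[tuple[np.ndarray, np.ndarray]] = []
    history: list[list[float]] = []  # per layer, per epoch reconstruction MSE
    for layer_idx, width in enumerate(config.hidden_layers):
        d = H.shape[1]
        W1 = _glorot(rng, d, width)       # linear layers: gain 1
        b1 = np.zeros(width)
        W2 = _glorot(rng, width, d)
        b2 = np.zeros(d)
        lr = config.ae_learning_rate
        layer_history: list[float] = []
        for _ in range(config.ae_epochs):
            epoch_mse: list[float] = []
            for batch in _minibatches(H.shape[0], config.batch_size, rng):
                x = H[batch]
                # reconstruction loss is the MSE over batch *and* feature
                # entries, which keeps the gradient scale independent of
                # the input width (a linear AE is otherwise unstable at
                # rate 0.05 for wide inputs)
                m = x.shape[0] * d
                h = x @ W1 + b1              # linear encoder
                xhat = h @ W2 + b2           # linear decoder
                err = xhat - x
                if not np.isfinite(err).all():
                    raise FloatingPointError(
                        f"autoencoder for layer {layer_idx} diverged "
                        f"(non-finite activations)"
                    )
                # d(recon)/dh plus L1 activity penalty on the code
                dh = (err @ W2.T
                      + config.sparsity_weight * np.sign(h)) / m
                W2 -= lr * (h.T @ err) / m
                b2 -= lr * err.sum(axis=0) / m
                W1 -= lr * (x.T @ dh)
                b1 -= lr * dh.sum(axis=0)
                epoch_mse.append(float(np.mean(err ** 2)))
            layer_history.append(float(np.mean(epoch_mse)))
        history.append(layer_history)
        encoders.append((W1, b1))
        H = _sigmoid(H @ W1 + b1)
    if return_history:
        return encoders, history
    return encoders


def ae_reconstruction_mse(X: np.ndarray, W1: np.ndarray, b1: np.ndarray,
                          W2: np.ndarray, b2: np.ndarray) -> float:
    """Reconstruction MSE of a linear autoencoder (test oracle helper)."""
    xhat = (X @ W1 + b1) @ W2 + b2
    return float(np.mean((xhat - X) ** 2))


def _forward(weights, X):
    """All layer activations (input first, output last); sigmoid throughout."""
    acts = [X]
    for W, b in weights:
        acts.append(_sigmoid(acts[-1] @ W + b))
    return acts


def finetune(pretrained: Sequence[tuple[np.ndarray, np.ndarray]],
             X: np.ndarray, Y: np.ndarray, config: NetworkConfig,
             mask: np.ndarray | None = None,
             rng: np.random.Generator | None = None) -> TrainedNetwork:
    """Supervised refinement of the pretrained stack by back-propagation.

    ``pretrained`` holds the hidden-layer encoders from
    :func:`pretrain_stack`; a fresh output head is appended.  ``Y`` must be
    in the sigmoid's range.  ``mask`` (same shape as ``Y``) excludes target
    entries — masked entries contribute neither loss nor gradient.  The
    learning-rate ladder runs ``bp_epochs_per_rate`` epochs at each rate.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if X.shape[0] != Y.shape[0]:
        raise ValueError("X and Y row counts differ")
    n_out = Y.shape[1]
    weights = [(W.copy(), b.copy()) for W, b in pretrained]
    weights.append((_glorot(rng, config.hidden_layers[-1], n_out, gain=4.0),
                    np.zeros(n_out)))
    if mask is None:
        mask = np.ones_like(Y, dtype=bool)

    velocities = [(np.zeros_like(W), np.zeros_like(b)) for W, b in weights]
    loss_history: list[float] = []
    for lr in config.bp_learning_rates:
        for _ in range(config.bp_epochs_per_rate):
            epoch_loss = 0.0
            n_terms = 0
            for batch in _minibatches(X.shape[0], config.batch_size, rng):
                x, y, m = X[batch], Y[batch], mask[batch]
                acts = _forward(weights, x)
                out = acts[-1]
                err = (out - y) * m
                k = max(int(m.sum()), 1)
                if config.loss == "squared":
                    epoch_loss += float(0.5 * (err ** 2).sum())
                    delta = err * out * (1.0 - out) / x.shape[0]
                else:  # cross-entropy with sigmoid: delta simplifies
                    with np.errstate(divide="ignore", invalid="ignore"):
                        ll = -(y * np.log(out) + (1 - y) * np.log(1 - out))
                    epoch_loss += float(np.where(m, ll, 0.0).sum())
                    delta = err / x.shape[0]
                n_terms += k
                for li in range(len(weights) - 1, -1, -1):
                    W, b = weights[li]
                    a_prev = acts[li]
                    gW = a_prev.T @ delta + config.weight_decay * W
                    gb = delta.sum(axis=0)
                    if li > 0:
                        a = acts[li]
                        delta = (delta @ W.T) * a * (1.0 - a)
                    vW, vb = velocities[li]
                    vW = config.momentum * vW - lr * gW
                    vb = config.momentum * vb - lr * gb
                    velocities[li] = (vW, vb)
                    weights[li] = (W + vW, b + vb)
            if not np.isfinite(epoch_loss):
                raise FloatingPointError(
                    "training diverged (loss is not finite); "
                    "try a lower initial learning rate"
                )
            loss_history.append(epoch_loss / max(n_terms, 1))
    return TrainedNetwork(weights=weights, config=config,
                          input_dim=X.shape[1], output_dim=n_out,
                          loss_history=loss_history)


def train_network(X: np.ndarray, Y: np.ndarray, config: NetworkConfig,
                  mask: np.ndarray | None = None) -> TrainedNetwork:
    """Pretrain + finetune in one call (single RNG stream from the seed)."""
    rng = np.random.default_rng(config.seed)
    encoders = pretrain_stack(X, config, rng)
    return finetune(encoders, X, Y, config, mask=mask, rng=rng)


def predict(network: TrainedNetwork, X: np.ndarray) -> np.ndarray:
    """Sigmoid outputs in (0, 1); deterministic given the weights."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != network.input_dim:
        raise ValueError(
            f"input dimension mismatch: expected {network.input_dim}, "
            f"got {X.shape[1] if X.ndim == 2 else X.shape}"
        )
    return _forward(network.weights, X)[-1]
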