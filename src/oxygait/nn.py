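"""Minimal NumPy neural networks: an LSTM regressor and an autoencoder.

Both are small, fully deterministic given a seed, and train with Adam on
manually derived gradients (the LSTM gradients are verified against finite
differences in the test suite).  The LSTM maps a sequence of feature vectors
to one scalar via the last hidden state; dropout (the "forgetting rate") is
applied to that last hidden state during training, and an L2 penalty acts on
all weight matrices.  The autoencoder is a single-hidden-layer
encoder/decoder pair trained to minimize mean-squared reconstruction error on
standardized inputs.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np

from .core import ConfigurationError, InputError


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -60, 60)))


class Adam:
    """Adam optimizer over a dict of named parameter arrays."""

    def __init__(self, params: dict, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict, grads: dict) -> None:
        self.t += 1
        b1t = 1 - self.beta1**self.t
        b2t = 1 - self.beta2**self.t
        for k, g in grads.items():
            self.m[k] = self.beta1 * self.m[k] + (1 - self.beta1) * g
            self.v[k] = self.beta2 * self.v[k] + (1 - self.beta2) * g * g
            params[k] -= self.lr * (self.m[k] / b1t) / (np.sqrt(self.v[k] / b2t) + self.eps)


class LSTMRegressor:
    """Single-layer LSTM with a linear scalar readout from the last hidden state."""

    def __init__(self, input_dim: int, hidden_units: int = 64, l2: float = 1e-4,
                 dropout: float = 0.2, seed: int = 0):
        if not 0 <= dropout < 1:
            raise ConfigurationError("dropout must be in [0, 1)")
        self.input_dim = input_dim
        self.hidden_units = hidden_units
        self.l2 = l2
        self.dropout = dropout
        rng = np.random.default_rng(seed)
        d, h = input_dim, hidden_units
        sx = np.sqrt(6.0 / (d + 4 * h))
        sh = np.sqrt(6.0 / (h + 4 * h))
        so = np.sqrt(6.0 / (h + 1))
        b = np.zeros(4 * h)
        b[h : 2 * h] = 1.0  # forget-gate bias
        self.params = {
            "Wx": rng.uniform(-sx, sx, (d, 4 * h)),
            "Wh": rng.uniform(-sh, sh, (h, 4 * h)),
            "b": b,
            "Wo": rng.uniform(-so, so, h),
            "bo": np.zeros(1),
        }

    # -- forward ------------------------------------------------------------

    def _run(self, X: np.ndarray):
        """Forward pass over X of shape (B, T, D); returns caches for BPTT."""
        if X.ndim != 3 or X.shape[2] != self.input_dim:
            raise InputError(
                f"expected input of shape (batch, seq, {self.input_dim}), got {X.shape}"
            )
        B, T, _ = X.shape
        h_dim = self.hidden_units
        p = self.params
        h = np.zeros((B, h_dim))
        c = np.zeros((B, h_dim))
        cache = []
        for t in range(T):
            a = X[:, t] @ p["Wx"] + h @ p["Wh"] + p["b"]
            i = _sigmoid(a[:, :h_dim])
            f = _sigmoid(a[:, h_dim : 2 * h_dim])
            g = np.tanh(a[:, 2 * h_dim : 3 * h_dim])
            o = _sigmoid(a[:, 3 * h_dim :])
            c_new = f * c + i * g
            tc = np.tanh(c_new)
            h_new = o * tc
            cache.append((h, c, i, f, g, o, c_new, tc))
            h, c = h_new, c_new
        return h, cache

    def predict(self, X: np.ndarray) -> np.ndarray:
        h, _ = self._run(np.asarray(X, dtype=float))
        return h @ self.params["Wo"] + self.params["bo"][0]

    # -- loss + gradients ---------------------------------------------------

    def loss_and_grads(self, X: np.ndarray, y: np.ndarray,
                       rng: np.random.Generator | None = None):
        """MSE + L2 loss and its gradients; dropout mask drawn from rng if given."""
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        B, T, _ = X.shape
        h_dim = self.hidden_units
        p = self.params
        h_last, cache = self._run(X)

        if rng is not None and self.dropout > 0:
            mask = (rng.random((B, h_dim)) >= self.dropout) / (1 - self.dropout)
        else:
            mask = np.ones((B, h_dim))
        h_drop = h_last * mask
        pred = h_drop @ p["Wo"] + p["bo"][0]
        err = pred - y
        loss = float(np.mean(err**2))
        loss += self.l2 * sum(float(np.sum(p[k] ** 2)) for k in ("Wx", "Wh", "Wo"))

        grads = {k: np.zeros_like(v) for k, v in p.items()}
        dpred = 2.0 * err / B
        grads["Wo"] = h_drop.T @ dpred
        grads["bo"] = np.array([dpred.sum()])
        dh = np.outer(dpred, p["Wo"]) * mask
        dc = np.zeros((B, h_dim))
        for t in range(T - 1, -1, -1):
            h_prev, c_prev, i, f, g, o, c_new, tc = cache[t]
            do = dh * tc
            dc = dc + dh * o * (1 - tc**2)
            di = dc * g
            df = dc * c_prev
            dg = dc * i
            dc_prev = dc * f
            da = np.hstack([
                di * i * (1 - i),
                df * f * (1 - f),
                dg * (1 - g**2),
                do * o * (1 - o),
            ])
            grads["Wx"] += X[:, t].T @ da
            grads["Wh"] += h_prev.T @ da
            grads["b"] += da.sum(axis=0)
            dh = da @ p["Wh"].T
            dc = dc_prev
        for k in ("Wx", "Wh", "Wo"):
            grads[k] += 2.0 * self.l2 * p[k]
        return loss, grads

    # -- parameter management -----------------------------------------------

    def get_params(self) -> dict:
        return {k: v.copy() for k, v in self.params.items()}

    def set_params(self, params: dict) -> None:
        self.params = {k: v.copy() for k, v in params.items()}

    def clone(self) -> "LSTMRegressor":
        other = copy.copy(self)
        other.params = self.get_params()
        return other


@dataclass
class TrainingHistory:
    train_loss: list = field(default_factory=list)
    val_rmse: list = field(default_factory=list)
    best_iteration: int = -1
    stop_reason: str = ""

    @property
    def n_iterations(self) -> int:
        return len(self.val_rmse)


def train_lstm(
    model: LSTMRegressor,
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_val: np.ndarray,
    y_val: np.ndarray,
    max_iterations: int = 200,
    patience: int = 8,
    learning_rate: float = 1e-3,
    batch_size: int = 64,
    seed: int = 0,
) -> TrainingHistory:
    """Minibatch Adam training with RMSE-based early stopping.

    One iteration is one pass over the training set.  Training stops when the
    validation RMSE has not strictly decreased for `patience` consecutive
    iterations; the parameters of the best (minimum validation RMSE) iteration
    are restored before returning.
    """
    rng = np.random.default_rng(seed)
    opt = Adam(model.params, lr=learning_rate)
    hist = TrainingHistory()
    best_rmse = np.inf
    best_params = model.get_params()
    stall = 0
    n = X_train.shape[0]
    for it in range(max_iterations):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for s0 in range(0, n, batch_size):
            idx = order[s0 : s0 + batch_size]
            loss, grads = model.loss_and_grads(X_train[idx], y_train[idx], rng=rng)
            opt.step(model.params, grads)
            epoch_loss += loss * len(idx)
        hist.train_loss.append(epoch_loss / n)
        rmse = float(np.sqrt(np.mean((model.predict(X_val) - y_val) ** 2)))
        hist.val_rmse.append(rmse)
        if rmse < best_rmse - 1e-12:
            best_rmse = rmse
            best_params = model.get_params()
            hist.best_iteration = it
            stall = 0
        else:
            stall += 1
            if stall >= patience:
                hist.stop_reason = "patience"
                break
    else:
        hist.stop_reason = "max_iterations"
    model.set_params(best_params)
    return hist


class Autoencoder:
    """Undercomplete encoder/decoder trained on standardized inputs.

    encoder: x -> act(x W1 + b1) in latent_dim; decoder: z -> z W2 + b2.
    activation is "linear" (default) or "tanh".  Inputs are centered/scaled by
    training statistics stored on the model; reconstruction loss is measured in
    standardized units.
    """

    def __init__(self, input_dim: int, latent_dim: int, seed: int = 0,
                 activation: str = "linear"):
        if latent_dim >= input_dim:
            raise ConfigurationError(
                f"latent_dim ({latent_dim}) must be smaller than input_dim ({input_dim})"
            )
        if activation not in ("linear", "tanh"):
            raise ConfigurationError(f"unknown activation {activation!r}")
        self.input_dim = input_dim
        self.latent_dim = latent_dim
        self.activation = activation
        rng = np.random.default_rng(seed)
        s1 = np.sqrt(6.0 / (input_dim + latent_dim))
        self.params = {
            "W1": rng.uniform(-s1, s1, (input_dim, latent_dim)),
            "b1": np.zeros(latent_dim),
            "W2": rng.uniform(-s1, s1, (latent_dim, input_dim)),
            "b2": np.zeros(input_dim),
        }
        self.mu = np.zeros(input_dim)
        self.sd = np.ones(input_dim)
        self.loss_curve: list[float] = []
        self.best_iteration = -1

    def _standardize(self, X: np.ndarray) -> np.ndarray:
        return (X - self.mu) / self.sd

    def _act(self, Z: np.ndarray) -> np.ndarray:
        return np.tanh(Z) if self.activation == "tanh" else Z

    def _forward(self, Xs: np.ndarray):
        Z = Xs @ self.params["W1"] + self.params["b1"]
        A = self._act(Z)
        Xhat = A @ self.params["W2"] + self.params["b2"]
        return Z, A, Xhat

    def fit(self, X: np.ndarray, max_epochs: int = 200, patience: int = 8,
            learning_rate: float = 1e-2) -> "Autoencoder":
        X = np.asarray(X, dtype=float)
        if X.shape[0] < self.latent_dim:
            raise InputError("need at least latent_dim training rows")
        self.mu = X.mean(axis=0)
        sd = X.std(axis=0)
        self.sd = np.where(sd > 0, sd, 1.0)
        Xs = self._standardize(X)
        opt = Adam(self.params, lr=learning_rate)
        best = np.inf
        best_params = {k: v.copy() for k, v in self.params.items()}
        stall = 0
        n, d = Xs.shape
        for epoch in range(max_epochs):
            Z, A, Xhat = self._forward(Xs)
            E = Xhat - Xs
            loss = float(np.mean(E**2))
            self.loss_curve.append(loss)
            if loss < best - 1e-12:
                best = loss
                best_params = {k: v.copy() for k, v in self.params.items()}
                self.best_iteration = epoch
                stall = 0
            else:
                stall += 1
                if stall >= patience:
                    break
            dXhat = 2.0 * E / (n * d)
            grads = {
                "W2": A.T @ dXhat,
                "b2": dXhat.sum(axis=0),
            }
            dA = dXhat @ self.params["W2"].T
            dZ = dA * (1 - A**2) if self.activation == "tanh" else dA
            grads["W1"] = Xs.T @ dZ
            grads["b1"] = dZ.sum(axis=0)
            opt.step(self.params, grads)
        self.params = best_params
        return self

    def encode(self, X: np.ndarray) -> np.ndarray:
        Xs = self._standardize(np.asarray(X, dtype=float))
        _, A, _ = self._forward(Xs)
        return A

    def reconstruction_error(self, X: np.ndarray) -> float:
        Xs = self._standardize(np.asarray(X, dtype=float))
        _, _, Xhat = self._forward(Xs)
        return float(np.mean((Xhat - Xs) ** 2))
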