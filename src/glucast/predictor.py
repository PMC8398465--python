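"""Single-layer LSTM regressor for 60-minute-ahead glucose prediction.

The model is a recurrent layer of 56 memory cells over 24-step sequences of
3–5 conditioned channels, followed by a single-unit affine output.  With the
default 56 units and 4 channels the recurrent layer holds 4·(u·(u+c)+u) =
13664 trainable weights and the output layer u+1 = 57.

The network is implemented directly in numpy — forward pass, full
backpropagation through time, and Adam — with the conventional gate ordering
(input, forget, cell, output), Glorot-uniform input kernels, orthogonal
recurrent kernels and a unit forget-gate bias.  Training minimizes the RMSE
objective; all randomness (initialization and batch shuffling) flows from a
single integer seed, so identical seeds give identical training histories.

Channels are standardized by train-split mean/std before training and the
scaling is inverted on predictions, so reported RMSE is always in raw mmol/L.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .windows import WindowSet

__all__ = [
    "ModelSpec",
    "LSTMModel",
    "FitResult",
    "build_model",
    "train",
    "evaluate",
    "rmse",
    "mmol_to_mgdl",
    "MMOL_TO_MGDL",
]

#: Conversion factor for glucose: 1 mmol/L = 18.016 mg/dL.
MMOL_TO_MGDL = 18.016


@dataclass(frozen=True)
class ModelSpec:
    """Architecture and training hyper-parameters."""

    n_channels: int = 4
    lstm_units: int = 56
    batch_size: int = 16
    epochs: int = 150
    learning_rate: float = 1e-3
    standardize: bool = True

    def __post_init__(self) -> None:
        if self.n_channels not in (3, 4, 5):
            raise ValueError(
                f"n_channels must be 3, 4 or 5, got {self.n_channels} "
                "(3 covers the no-activity ablation)"
            )
        if self.lstm_units < 1 or self.epochs < 1 or self.batch_size < 1:
            raise ValueError("lstm_units, epochs and batch_size must be >= 1")


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -60, 60)))


class LSTMModel:
    """LSTM(u) → Dense(1) with numpy forward/backward passes."""

    def __init__(self, spec: ModelSpec, seed: int = 0):
        self.spec = spec
        u, c = spec.lstm_units, spec.n_channels
        rng = np.random.default_rng(seed)
        limit = np.sqrt(6.0 / (c + 4 * u))
        self.Wx = rng.uniform(-limit, limit, size=(c, 4 * u))
        # orthogonal recurrent kernel, one per gate
        blocks = []
        for _ in range(4):
            a = rng.standard_normal((u, u))
            q, r = np.linalg.qr(a)
            blocks.append(q * np.sign(np.diag(r)))
        self.Wh = np.concatenate(blocks, axis=1)
        self.b = np.zeros(4 * u)
        self.b[u : 2 * u] = 1.0  # unit forget bias
        limit_d = np.sqrt(6.0 / (u + 1))
        self.Wd = rng.uniform(-limit_d, limit_d, size=(u, 1))
        self.bd = np.zeros(1)
        # per-channel / target standardization (identity until fitted)
        self.x_mean = np.zeros(c)
        self.x_std = np.ones(c)
        self.y_mean = 0.0
        self.y_std = 1.0

    # -- parameter bookkeeping -------------------------------------------
    @property
    def recurrent_param_count(self) -> int:
        u, c = self.spec.lstm_units, self.spec.n_channels
        return 4 * (u * (u + c) + u)

    @property
    def dense_param_count(self) -> int:
        return self.spec.lstm_units + 1

    @property
    def param_counts(self) -> dict[str, int]:
        return {
            "recurrent": self.recurrent_param_count,
            "dense": self.dense_param_count,
            "total": self.recurrent_param_count + self.dense_param_count,
        }

    def _params(self) -> list[np.ndarray]:
        return [self.Wx, self.Wh, self.b, self.Wd, self.bd]

    # -- forward / backward ----------------------------------------------
    def _forward(self, x: np.ndarray, cache: bool = False):
        """x: (B, T, C) already standardized. Returns predictions (B,)."""
        B, T, _ = x.shape
        u = self.spec.lstm_units
        h = np.zeros((B, u))
        c = np.zeros((B, u))
        states = []
        for t in range(T):
            z = x[:, t, :] @ self.Wx + h @ self.Wh + self.b
            i = _sigmoid(z[:, :u])
            f = _sigmoid(z[:, u : 2 * u])
            g = np.tanh(z[:, 2 * u : 3 * u])
            o = _sigmoid(z[:, 3 * u :])
            c_prev = c
            c = f * c_prev + i * g
            tanh_c = np.tanh(c)
            h = o * tanh_c
            if cache:
                states.append((i, f, g, o, c_prev, tanh_c))
        pred = (h @ self.Wd + self.bd)[:, 0]
        if cache:
            return pred, h, states
        return pred

    def _backward(self, x, states, h_last, dpred):
        """Gradients of the loss w.r.t. all parameters; dpred: (B,)."""
        B, T, _ = x.shape
        u = self.spec.lstm_units
        dWx = np.zeros_like(self.Wx)
        dWh = np.zeros_like(self.Wh)
        db = np.zeros_like(self.b)
        dWd = h_last.T @ dpred[:, None]
        dbd = np.array([dpred.sum()])

        dh = dpred[:, None] @ self.Wd.T  # (B, u)
        dc = np.zeros((B, u))
        # reconstruct h_{t-1} from states on the fly
        h_prevs = [np.zeros((B, u))]
        for t in range(T - 1):
            i, f, g, o, c_prev, tanh_c = states[t]
            h_prevs.append(o * tanh_c)
        for t in range(T - 1, -1, -1):
            i, f, g, o, c_prev, tanh_c = states[t]
            do = dh * tanh_c
            dc = dc + dh * o * (1.0 - tanh_c**2)
            di = dc * g
            dg = dc * i
            df = dc * c_prev
            dz = np.concatenate(
                [
                    di * i * (1.0 - i),
                    df * f * (1.0 - f),
                    dg * (1.0 - g**2),
                    do * o * (1.0 - o),
                ],
                axis=1,
            )
            dWx += x[:, t, :].T @ dz
            dWh += h_prevs[t].T @ dz
            db += dz.sum(axis=0)
            dh = dz @ self.Wh.T
            dc = dc * f
        return [dWx, dWh, db, dWd, dbd]

    # -- persistence ------------------------------------------------------
    def save_weights(self, path) -> None:
        """Checkpoint all trainable weights and scaling constants (npz)."""
        np.savez(
            path, Wx=self.Wx, Wh=self.Wh, b=self.b, Wd=self.Wd, bd=self.bd,
            x_mean=self.x_mean, x_std=self.x_std,
            y_mean=self.y_mean, y_std=self.y_std,
        )

    def load_weights(self, path) -> None:
        with np.load(path) as data:
            for name in ("Wx", "Wh", "b", "Wd", "bd", "x_mean", "x_std"):
                current = getattr(self, name)
                if data[name].shape != current.shape:
                    raise ValueError(
                        f"checkpoint {name} shape {data[name].shape} does not match "
                        f"model shape {current.shape}"
                    )
                setattr(self, name, data[name])
            self.y_mean = float(data["y_mean"])
            self.y_std = float(data["y_std"])

    # -- prediction -------------------------------------------------------
    def predict(self, x: np.ndarray) -> np.ndarray:
        """Predictions in raw mmol/L for raw-unit inputs x of shape (B, T, C)."""
        xs = (x - self.x_mean) / self.x_std
        pred = self._forward(xs)
        return pred * self.y_std + self.y_mean


@dataclass
class FitResult:
    """Trained model handle with per-epoch history and final test RMSE."""

    model: LSTMModel
    history: pd.DataFrame  # columns: epoch, train_loss, val_loss
    test_rmse: float

    def save_history(self, path) -> None:
        self.history.to_csv(path, index=False)


def build_model(spec: ModelSpec, seed: int = 0) -> LSTMModel:
    """Instantiate the recurrent regressor and report its parameter counts."""
    return LSTMModel(spec, seed=seed)


def rmse(predictions: np.ndarray, targets: np.ndarray) -> float:
    predictions = np.asarray(predictions, dtype=float)
    targets = np.asarray(targets, dtype=float)
    if predictions.size == 0:
        raise ValueError("cannot compute RMSE of an empty set")
    return float(np.sqrt(np.mean((predictions - targets) ** 2)))


class _Adam:
    def __init__(self, params, lr, beta1=0.9, beta2=0.999, eps=1e-7):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, params, grads):
        self.t += 1
        lr_t = self.lr * np.sqrt(1 - self.b2**self.t) / (1 - self.b1**self.t)
        for p, g, m, v in zip(params, grads, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g**2
            p -= lr_t * m / (np.sqrt(v) + self.eps)


def train(model: LSTMModel, windowset: WindowSet, spec: ModelSpec, seed: int) -> FitResult:
    """Fit the model on the train split for exactly ``spec.epochs`` epochs.

    Batches of ``spec.batch_size`` windows, one weight update per batch,
    validation RMSE recorded every epoch, final-epoch weights retained (no
    early stopping).  Raises on channel mismatch or a non-finite loss.
    """
    if len(windowset.channel_names) != spec.n_channels:
        raise ValueError(
            f"window set has {len(windowset.channel_names)} channels but the model "
            f"expects {spec.n_channels}"
        )
    X_tr, y_tr = windowset.tensors("train")
    X_va, y_va = windowset.tensors("validation")
    X_te, y_te = windowset.tensors("test")
    if min(len(y_tr), len(y_va), len(y_te)) == 0:
        raise ValueError("train, validation and test splits must all be non-empty")

    if spec.standardize:
        model.x_mean = X_tr.reshape(-1, X_tr.shape[-1]).mean(axis=0)
        model.x_std = X_tr.reshape(-1, X_tr.shape[-1]).std(axis=0)
        model.x_std[model.x_std < 1e-8] = 1.0
        model.y_mean = float(y_tr.mean())
        model.y_std = float(y_tr.std()) or 1.0

    Xs = (X_tr - model.x_mean) / model.x_std
    ys = (y_tr - model.y_mean) / model.y_std
    Xvs = (X_va - model.x_mean) / model.x_std
    yvs = (y_va - model.y_mean) / model.y_std

    rng = np.random.default_rng(seed)
    opt = _Adam(model._params(), spec.learning_rate)
    n = len(ys)
    history = []
    for epoch in range(spec.epochs):
        order = rng.permutation(n)
        sq_sum = 0.0
        for lo in range(0, n, spec.batch_size):
            idx = order[lo : lo + spec.batch_size]
            xb, yb = Xs[idx], ys[idx]
            pred, h_last, states = model._forward(xb, cache=True)
            err = pred - yb
            batch_rmse = np.sqrt(np.mean(err**2))
            if not np.isfinite(batch_rmse):
                raise FloatingPointError(
                    f"non-finite training loss at epoch {epoch}; "
                    "check input scaling or learning rate"
                )
            sq_sum += float(np.sum(err**2))
            if batch_rmse > 0:
                dpred = err / (len(yb) * batch_rmse)  # d RMSE / d pred
                grads = model._backward(xb, states, h_last, dpred)
                opt.step(model._params(), grads)
        train_loss = float(np.sqrt(sq_sum / n))
        val_loss = rmse(model._forward(Xvs), yvs)
        history.append({"epoch": epoch + 1, "train_loss": train_loss, "val_loss": val_loss})

    test_rmse = rmse(model.predict(X_te), y_te)
    return FitResult(model, pd.DataFrame(history), test_rmse)


def evaluate(model: LSTMModel, X_test: np.ndarray, y_test: np.ndarray) -> float:
    """Test-set RMSE in mmol/L: √(mean (ŷ − y)²) over the test windows."""
    if len(y_test) == 0:
        raise ValueError("empty test set")
    return rmse(model.predict(X_test), np.asarray(y_test, dtype=float))


def mmol_to_mgdl(x: float) -> float:
    """Convert glucose from mmol/L to mg/dL (×18.016), reported to 1 decimal."""
    if x < 0:
        raise ValueError("glucose concentration cannot be negative")
    return round(x * MMOL_TO_MGDL, 1)
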