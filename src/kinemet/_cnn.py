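"""A compact 1-D convolutional regressor in NumPy.

Architecture, for an 18-wide velocity vector treated as an 18x1 signal:
two convolutional layers (length-3 kernels, same padding, ReLU), each
followed by length-2 max pooling, then a dense head of two 16-unit hidden
layers and a scalar linear output.  Trained by mini-batch Adam on the mean
squared error.  All randomness (weight init, shuffling) comes from one
seeded generator, so training is bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["CNNRegressor"]


def _relu(z: np.ndarray) -> np.ndarray:
    return np.maximum(z, 0.0)


def _conv_forward(x: np.ndarray, w: np.ndarray, b: np.ndarray):
    """Same-padded length-3 convolution.

    x: (n, L, c_in); w: (3, c_in, c_out); returns z (n, L, c_out) and the
    padded window tensor for backprop.
    """
    n, L, c_in = x.shape
    xp = np.pad(x, ((0, 0), (1, 1), (0, 0)))
    # cols[n, l, c, k] = xp[n, l + k, c]
    cols = np.lib.stride_tricks.sliding_window_view(xp, 3, axis=1)
    z = np.einsum("nlck,kco->nlo", cols, w) + b
    return z, cols


def _conv_backward(cols: np.ndarray, w: np.ndarray, dz: np.ndarray, L: int):
    dw = np.einsum("nlck,nlo->kco", cols, dz)
    db = dz.sum(axis=(0, 1))
    dcols = np.einsum("kco,nlo->nlck", w, dz)
    n, _, c_in, _ = dcols.shape
    dxp = np.zeros((n, L + 2, c_in))
    for k in range(3):
        dxp[:, k : k + L, :] += dcols[:, :, :, k]
    return dw, db, dxp[:, 1:-1, :]


def _pool_forward(a: np.ndarray):
    """Length-2, stride-2 max pooling; a trailing odd element is dropped."""
    n, L, c = a.shape
    L2 = L // 2
    pairs = a[:, : 2 * L2, :].reshape(n, L2, 2, c)
    arg = pairs.argmax(axis=2)
    return pairs.max(axis=2), (arg, L)


def _pool_backward(dp: np.ndarray, cache) -> np.ndarray:
    arg, L = cache
    n, L2, c = dp.shape
    da_pairs = np.zeros((n, L2, 2, c))
    np.put_along_axis(da_pairs, arg[:, :, None, :], dp[:, :, None, :], axis=2)
    da = np.zeros((n, L, c))
    da[:, : 2 * L2, :] = da_pairs.reshape(n, 2 * L2, c)
    return da


@dataclass
class CNNRegressor:
    """1-D conv-net regressor for fixed-width tabular rows.

    Parameters
    ----------
    input_width : expected number of input features per row (default 18).
    filters : channel counts of the two convolutional layers.
    dense_units : width of the two dense hidden layers.
    epochs, batch_size, learning_rate : Adam training schedule.
    validation_fraction, patience : early stopping on a held-out slice of
        the training data (set ``patience=None`` to disable).
    seed : generator seed for init and shuffling.
    """

    input_width: int = 18
    filters: tuple[int, int] = (16, 32)
    dense_units: int = 16
    epochs: int = 200
    batch_size: int = 64
    learning_rate: float = 1e-3
    validation_fraction: float = 0.1
    patience: int | None = 20
    seed: int = 0

    params_: dict = field(default=None, repr=False)
    n_iter_: int = 0

    # ------------------------------------------------------------------
    def _init_params(self, rng: np.random.Generator) -> dict:
        c1, c2 = self.filters
        L2 = self.input_width // 2  # after first pool
        L3 = L2 // 2  # after second pool
        flat = L3 * c2
        d = self.dense_units

        def he(shape, fan_in):
            return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)

        return {
            "w1": he((3, 1, c1), 3),
            "b1": np.zeros(c1),
            "w2": he((3, c1, c2), 3 * c1),
            "b2": np.zeros(c2),
            "w3": he((flat, d), flat),
            "b3": np.zeros(d),
            "w4": he((d, d), d),
            "b4": np.zeros(d),
            "w5": he((d, 1), d),
            "b5": np.zeros(1),
        }

    def _forward(self, x: np.ndarray, params: dict, cache: bool = False):
        p = params
        z1, cols1 = _conv_forward(x, p["w1"], p["b1"])
        a1 = _relu(z1)
        p1, pc1 = _pool_forward(a1)
        z2, cols2 = _conv_forward(p1, p["w2"], p["b2"])
        a2 = _relu(z2)
        p2, pc2 = _pool_forward(a2)
        flat = p2.reshape(x.shape[0], -1)
        z3 = flat @ p["w3"] + p["b3"]
        a3 = _relu(z3)
        z4 = a3 @ p["w4"] + p["b4"]
        a4 = _relu(z4)
        out = (a4 @ p["w5"] + p["b5"]).ravel()
        if not cache:
            return out
        return out, (x, cols1, z1, a1, pc1, p1, cols2, z2, a2, pc2, p2, flat, z3, a3, z4, a4)

    def _backward(self, params: dict, caches, dout: np.ndarray) -> dict:
        p = params
        (x, cols1, z1, a1, pc1, p1, cols2, z2, a2, pc2, p2, flat, z3, a3, z4, a4) = caches
        g: dict[str, np.ndarray] = {}
        dout = dout[:, None]
        g["w5"] = a4.T @ dout
        g["b5"] = dout.sum(axis=0)
        da4 = dout @ p["w5"].T
        dz4 = da4 * (z4 > 0)
        g["w4"] = a3.T @ dz4
        g["b4"] = dz4.sum(axis=0)
        da3 = dz4 @ p["w4"].T
        dz3 = da3 * (z3 > 0)
        g["w3"] = flat.T @ dz3
        g["b3"] = dz3.sum(axis=0)
        dflat = dz3 @ p["w3"].T
        dp2 = dflat.reshape(p2.shape)
        da2 = _pool_backward(dp2, pc2)
        dz2 = da2 * (z2 > 0)
        g["w2"], g["b2"], dp1 = _conv_backward(cols2, p["w2"], dz2, p1.shape[1])
        da1 = _pool_backward(dp1, pc1)
        dz1 = da1 * (z1 > 0)
        g["w1"], g["b1"], _ = _conv_backward(cols1, p["w1"], dz1, x.shape[1])
        return g

    # ------------------------------------------------------------------
    def fit(self, X: np.ndarray, y: np.ndarray) -> "CNNRegressor":
        X = np.atleast_2d(np.asarray(X, dtype=float))
        y = np.asarray(y, dtype=float).ravel()
        if X.shape[1] != self.input_width:
            raise ValueError(
                f"this network expects {self.input_width} input features, got {X.shape[1]}"
            )
        if X.shape[0] != y.shape[0]:
            raise ValueError("X and y must have equal length")
        if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
            raise ValueError("non-finite training data")

        rng = np.random.default_rng(self.seed)
        params = self._init_params(rng)
        m = {k: np.zeros_like(v) for k, v in params.items()}
        v = {k: np.zeros_like(vv) for k, vv in params.items()}
        beta1, beta2, eps = 0.9, 0.999, 1e-8

        n = X.shape[0]
        n_val = int(round(self.validation_fraction * n)) if self.patience is not None else 0
        perm = rng.permutation(n)
        val_idx, train_idx = perm[:n_val], perm[n_val:]
        Xtr, ytr = X[train_idx], y[train_idx]
        Xval, yval = X[val_idx], y[val_idx]

        x3 = Xtr[:, :, None]
        best_val, best_params, stall = np.inf, None, 0
        step = 0
        for epoch in range(self.epochs):
            order = rng.permutation(len(Xtr))
            for start in range(0, len(Xtr), self.batch_size):
                idx = order[start : start + self.batch_size]
                xb, yb = x3[idx], ytr[idx]
                out, caches = self._forward(xb, params, cache=True)
                dout = 2.0 * (out - yb) / len(yb)
                grads = self._backward(params, caches, dout)
                step += 1
                for k in params:
                    m[k] = beta1 * m[k] + (1 - beta1) * grads[k]
                    v[k] = beta2 * v[k] + (1 - beta2) * grads[k] ** 2
                    mhat = m[k] / (1 - beta1**step)
                    vhat = v[k] / (1 - beta2**step)
                    params[k] -= self.learning_rate * mhat / (np.sqrt(vhat) + eps)
            self.n_iter_ = epoch + 1
            if n_val > 0:
                val_pred = self._forward(Xval[:, :, None], params)
                val_mse = float(np.mean((val_pred - yval) ** 2))
                if val_mse < best_val - 1e-10:
                    best_val, stall = val_mse, 0
                    best_params = {k: vv.copy() for k, vv in params.items()}
                else:
                    stall += 1
                    if stall >= self.patience:
                        break
        self.params_ = best_params if best_params is not None else params
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        if self.params_ is None:
            raise RuntimeError("CNNRegressor is not fitted")
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.input_width:
            raise ValueError(
                f"this network expects {self.input_width} input features, got {X.shape[1]}"
            )
        return self._forward(X[:, :, None], self.params_)
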