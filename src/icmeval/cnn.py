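"""Minimal 1-D convolutional network in numpy.

A compact, self-contained implementation of the layer set the episode
classifier needs — Conv1D, ReLU, BatchNorm, Dropout, MaxPool, global average
pooling, dense layers, a sigmoid head — trained with Adam on the binary
focal cross-entropy loss.  Sized for desk-scale problems (a few thousand
90-second snippets on one CPU); all heavy lifting is batched BLAS matmul
via an im2col layout.

Array convention: activations are float32 of shape ``(N, C, L)``.
"""

from __future__ import annotations

import numpy as np

F32 = np.float32


# ---------------------------------------------------------------------------
# Layers
# ---------------------------------------------------------------------------

class Layer:
    params: dict
    grads: dict

    def __init__(self):
        self.params, self.grads = {}, {}

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class Conv1D(Layer):
    """Same-padded 1-D convolution via im2col + batched matmul."""

    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator):
        super().__init__()
        self.c_in, self.c_out, self.k = c_in, c_out, k
        std = np.sqrt(2.0 / (c_in * k))  # He init
        self.params = {
            "W": (rng.standard_normal((c_out, c_in * k)) * std).astype(F32),
            "b": np.zeros(c_out, dtype=F32),
        }
        self.grads = {n: np.zeros_like(p) for n, p in self.params.items()}

    def _im2col(self, x: np.ndarray) -> np.ndarray:
        n, c, L = x.shape
        pl = (self.k - 1) // 2
        pr = self.k - 1 - pl
        xp = np.pad(x, ((0, 0), (0, 0), (pl, pr)))
        win = np.lib.stride_tricks.sliding_window_view(xp, self.k, axis=2)  # (N,C,L,k)
        return win.transpose(0, 1, 3, 2).reshape(n, c * self.k, L)

    def forward(self, x, train):
        self._cols = self._im2col(x)
        self._in_shape = x.shape
        y = self.params["W"] @ self._cols  # (N, c_out, L)
        return y + self.params["b"][None, :, None]

    def backward(self, dy):
        W = self.params["W"]
        self.grads["W"] = np.einsum("nol,nkl->ok", dy, self._cols).astype(F32)
        self.grads["b"] = dy.sum(axis=(0, 2)).astype(F32)
        dcols = (W.T @ dy).reshape(
            dy.shape[0], self.c_in, self.k, dy.shape[2]
        )
        n, c, L = self._in_shape
        pl = (self.k - 1) // 2
        dxp = np.zeros((n, c, L + self.k - 1), dtype=F32)
        for j in range(self.k):
            dxp[:, :, j:j + L] += dcols[:, :, j, :]
        self._cols = None
        return dxp[:, :, pl:pl + L]


class ReLU(Layer):
    def forward(self, x, train):
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, dy):
        out = dy * self._mask
        self._mask = None
        return out


class BatchNorm1D(Layer):
    """Per-channel batch normalization over the (N, L) axes."""

    def __init__(self, c: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.momentum, self.eps = momentum, eps
        self.params = {"gamma": np.ones(c, dtype=F32), "beta": np.zeros(c, dtype=F32)}
        self.grads = {n: np.zeros_like(p) for n, p in self.params.items()}
        self.running_mean = np.zeros(c, dtype=F32)
        self.running_var = np.ones(c, dtype=F32)

    def forward(self, x, train):
        if train:
            mean = x.mean(axis=(0, 2))
            var = x.var(axis=(0, 2))
            self.running_mean = ((1 - self.momentum) * self.running_mean
                                 + self.momentum * mean).astype(F32)
            self.running_var = ((1 - self.momentum) * self.running_var
                                + self.momentum * var).astype(F32)
        else:
            mean, var = self.running_mean, self.running_var
        self._std = np.sqrt(var + self.eps)[None, :, None]
        self._xhat = (x - mean[None, :, None]) / self._std
        return self.params["gamma"][None, :, None] * self._xhat + \
            self.params["beta"][None, :, None]

    def backward(self, dy):
        self.grads["gamma"] = (dy * self._xhat).sum(axis=(0, 2)).astype(F32)
        self.grads["beta"] = dy.sum(axis=(0, 2)).astype(F32)
        g = self.params["gamma"][None, :, None]
        dxhat = dy * g
        dx = (dxhat - dxhat.mean(axis=(0, 2), keepdims=True)
              - self._xhat * (dxhat * self._xhat).mean(axis=(0, 2), keepdims=True)
              ) / self._std
        self._xhat = None
        return dx.astype(F32)


class Dropout(Layer):
    def __init__(self, p: float, rng: np.random.Generator):
        super().__init__()
        self.p, self.rng = float(p), rng

    def forward(self, x, train):
        if not train or self.p <= 0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return (x * self._mask).astype(F32)

    def backward(self, dy):
        if self._mask is None:
            return dy
        out = (dy * self._mask).astype(F32)
        self._mask = None
        return out


class MaxPool1D(Layer):
    """Width-2 max pooling; an odd trailing sample is dropped."""

    def forward(self, x, train):
        n, c, L = x.shape
        self._odd = L % 2
        if self._odd:
            x = x[:, :, :L - 1]
        self._in_len = L
        xr = x.reshape(n, c, -1, 2)
        self._idx = xr.argmax(axis=3)
        return np.take_along_axis(xr, self._idx[..., None], axis=3)[..., 0]

    def backward(self, dy):
        n, c, Lp = dy.shape
        dxr = np.zeros((n, c, Lp, 2), dtype=F32)
        np.put_along_axis(dxr, self._idx[..., None], dy[..., None], axis=3)
        dx = dxr.reshape(n, c, 2 * Lp)
        if self._odd:
            dx = np.pad(dx, ((0, 0), (0, 0), (0, 1)))
        return dx


class GlobalAvgPool(Layer):
    def forward(self, x, train):
        self._L = x.shape[2]
        return x.mean(axis=2)

    def backward(self, dy):
        return np.repeat(dy[:, :, None] / self._L, self._L, axis=2).astype(F32)


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        super().__init__()
        std = np.sqrt(2.0 / n_in)
        self.params = {
            "W": (rng.standard_normal((n_in, n_out)) * std).astype(F32),
            "b": np.zeros(n_out, dtype=F32),
        }
        self.grads = {n: np.zeros_like(p) for n, p in self.params.items()}

    def forward(self, x, train):
        self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, dy):
        self.grads["W"] = (self._x.T @ dy).astype(F32)
        self.grads["b"] = dy.sum(axis=0).astype(F32)
        out = dy @ self.params["W"].T
        self._x = None
        return out


class ReLUFlat(ReLU):
    pass


# ---------------------------------------------------------------------------
# Focal loss
# ---------------------------------------------------------------------------

def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=np.float64)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def focal_loss(p: np.ndarray, y: np.ndarray, gamma: float, alpha: float) -> np.ndarray:
    """Binary focal cross-entropy per sample.

    FL(p, y) = −α·y·(1−p)^γ·log p − (1−α)·(1−y)·p^γ·log(1−p).
    With γ=0, α=0.5 this is exactly half the binary cross-entropy.
    """
    p = np.clip(p, 1e-7, 1.0 - 1e-7)
    return (-alpha * y * (1.0 - p) ** gamma * np.log(p)
            - (1.0 - alpha) * (1.0 - y) * p ** gamma * np.log(1.0 - p))


def focal_loss_grad_logit(p: np.ndarray, y: np.ndarray, gamma: float,
                          alpha: float) -> np.ndarray:
    """d(mean focal loss)/d(logit), per sample (caller divides by N)."""
    p = np.clip(p, 1e-7, 1.0 - 1e-7)
    if gamma == 0.0:
        dLdp = -alpha * y / p + (1.0 - alpha) * (1.0 - y) / (1.0 - p)
    else:
        dLdp_pos = alpha * (gamma * (1.0 - p) ** (gamma - 1.0) * np.log(p)
                            - (1.0 - p) ** gamma / p)
        dLdp_neg = -(1.0 - alpha) * (gamma * p ** (gamma - 1.0) * np.log(1.0 - p)
                                     - p ** gamma / (1.0 - p))
        dLdp = y * dLdp_pos + (1.0 - y) * dLdp_neg
    return dLdp * p * (1.0 - p)  # chain through sigmoid


# ---------------------------------------------------------------------------
# Network + Adam
# ---------------------------------------------------------------------------

class SequentialNet:
    """A feed-forward stack of the layers above with a single logit output."""

    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """Return logits of shape (N,)."""
        h = x.astype(F32)
        for layer in self.layers:
            h = layer.forward(h, train)
        return h[:, 0].astype(np.float64)

    def backward(self, dlogit: np.ndarray) -> None:
        g = dlogit[:, None].astype(F32)
        for layer in reversed(self.layers):
            g = layer.backward(g)

    def predict_proba(self, x: np.ndarray, batch_size: int = 256) -> np.ndarray:
        out = []
        for i in range(0, len(x), batch_size):
            out.append(sigmoid(self.forward(x[i:i + batch_size], train=False)))
        return np.concatenate(out) if out else np.empty(0)

    # --- parameter flattening for save/load and the optimizer ---
    def named_params(self):
        for li, layer in enumerate(self.layers):
            for name, p in layer.params.items():
                yield f"layer{li}.{name}", layer, name, p
        for li, layer in enumerate(self.layers):
            if isinstance(layer, BatchNorm1D):
                yield f"layer{li}.running_mean", layer, "running_mean", layer.running_mean
                yield f"layer{li}.running_var", layer, "running_var", layer.running_var

    def state_dict(self) -> dict[str, np.ndarray]:
        return {key: np.array(p) for key, _, _, p in self.named_params()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for key, layer, name, _ in self.named_params():
            val = state[key].astype(F32)
            if name in layer.params:
                layer.params[name] = val
                layer.grads[name] = np.zeros_like(val)
            else:
                setattr(layer, name, val)


class Adam:
    def __init__(self, net: SequentialNet, lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.net, self.lr = net, lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m: dict[str, np.ndarray] = {}
        self.v: dict[str, np.ndarray] = {}

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for li, layer in enumerate(self.net.layers):
            for name, p in layer.params.items():
                key = f"{li}.{name}"
                g = layer.grads[name]
                m = self.m.setdefault(key, np.zeros_like(p))
                v = self.v.setdefault(key, np.zeros_like(p))
                m[:] = b1 * m + (1 - b1) * g
                v[:] = b2 * v + (1 - b2) * g * g
                mhat = m / (1 - b1 ** self.t)
                vhat = v / (1 - b2 ** self.t)
                p -= (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(F32)
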