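"""Minimal 1D convolutional classifier with manual backpropagation.

A small two-layer convolutional network (valid convolutions, ReLU,
global average pooling, sigmoid head) trained with Adam on binary
cross-entropy.  Sized for CPU training on a few thousand short windows
in seconds.  Weights serialize to/from plain JSON-able dicts.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


class Conv1DNet:
    """conv(k1, c1) -> ReLU -> conv(k2, c2) -> ReLU -> linear -> sigmoid.

    The head is a dense layer over all (channel, position) activations:
    position sensitivity is required because the classifier must answer
    whether the peak is at the *centre* of the window, not merely inside
    it (global pooling would be translation-invariant and blur calls
    across the transient's whole width).
    """

    def __init__(
        self,
        window: int,
        kernel_sizes: tuple[int, int] = (7, 5),
        channels: tuple[int, int] = (16, 32),
        rng: np.random.Generator | None = None,
    ):
        k1, k2 = kernel_sizes
        c1, c2 = channels
        if window < k1 + k2 - 1:
            raise ValueError("window too short for the chosen kernel sizes")
        rng = rng or np.random.default_rng(0)
        self.window = window
        self.w1 = rng.normal(0.0, np.sqrt(2.0 / k1), size=(c1, 1, k1))
        self.b1 = np.zeros(c1)
        self.w2 = rng.normal(0.0, np.sqrt(2.0 / (k2 * c1)), size=(c2, c1, k2))
        self.b2 = np.zeros(c2)
        l2 = window - k1 - k2 + 2  # spatial extent after two valid convs
        self.w3 = rng.normal(0.0, np.sqrt(1.0 / (c2 * l2)), size=c2 * l2)
        self.b3 = 0.0

    # -- forward ----------------------------------------------------------
    def _forward(self, x: np.ndarray):
        """x: (batch, window) standardized inputs."""
        x = x[:, None, :]  # (B, 1, L)
        x1 = sliding_window_view(x, self.w1.shape[2], axis=2)  # (B,1,L1,k1)
        z1 = np.einsum("bctk,ock->bot", x1, self.w1) + self.b1[None, :, None]
        a1 = np.maximum(z1, 0.0)
        x2 = sliding_window_view(a1, self.w2.shape[2], axis=2)  # (B,c1,L2,k2)
        z2 = np.einsum("bctk,ock->bot", x2, self.w2) + self.b2[None, :, None]
        a2 = np.maximum(z2, 0.0)
        g = a2.reshape(a2.shape[0], -1)  # (B, c2 * L2)
        logit = g @ self.w3 + self.b3
        return (x1, z1, a1, x2, z2, a2, g), logit

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        _, logit = self._forward(np.asarray(x, dtype=float))
        return _sigmoid(logit)

    # -- training ---------------------------------------------------------
    def fit(
        self,
        x: np.ndarray,
        y: np.ndarray,
        epochs: int = 40,
        lr: float = 3e-3,
        batch_size: int = 128,
        rng: np.random.Generator | None = None,
    ) -> list[float]:
        """Adam on binary cross-entropy; returns per-epoch mean loss."""
        rng = rng or np.random.default_rng(0)
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        params = ["w1", "b1", "w2", "b2", "w3", "b3"]
        m = {p: np.zeros_like(np.asarray(getattr(self, p), dtype=float)) for p in params}
        v = {p: np.zeros_like(np.asarray(getattr(self, p), dtype=float)) for p in params}
        beta1, beta2, eps = 0.9, 0.999, 1e-8
        step = 0
        history = []
        n = x.shape[0]
        for _ in range(epochs):
            order = rng.permutation(n)
            losses = []
            for start in range(0, n, batch_size):
                idx = order[start : start + batch_size]
                grads, loss = self._grads(x[idx], y[idx])
                losses.append(loss)
                step += 1
                for p in params:
                    m[p] = beta1 * m[p] + (1 - beta1) * grads[p]
                    v[p] = beta2 * v[p] + (1 - beta2) * grads[p] ** 2
                    mhat = m[p] / (1 - beta1**step)
                    vhat = v[p] / (1 - beta2**step)
                    setattr(
                        self,
                        p,
                        getattr(self, p) - lr * mhat / (np.sqrt(vhat) + eps),
                    )
            history.append(float(np.mean(losses)))
        return history

    def _grads(self, x: np.ndarray, y: np.ndarray):
        cache, logit = self._forward(x)
        x1, z1, a1, x2, z2, a2, g = cache
        p = _sigmoid(logit)
        b = x.shape[0]
        loss = float(
            -np.mean(
                y * np.log(np.clip(p, 1e-12, None))
                + (1 - y) * np.log(np.clip(1 - p, 1e-12, None))
            )
        )
        dlogit = (p - y) / b  # (B,)
        grads: dict[str, np.ndarray | float] = {}
        grads["w3"] = g.T @ dlogit
        grads["b3"] = float(dlogit.sum())
        da2 = np.outer(dlogit, self.w3).reshape(a2.shape)
        l2 = a2.shape[2]
        dz2 = da2 * (z2 > 0)
        grads["w2"] = np.einsum("bot,bctk->ock", dz2, x2)
        grads["b2"] = dz2.sum(axis=(0, 2))
        da1 = np.zeros_like(a1)
        k2 = self.w2.shape[2]
        for k in range(k2):
            da1[:, :, k : k + l2] += np.einsum("bot,oc->bct", dz2, self.w2[:, :, k])
        dz1 = da1 * (z1 > 0)
        grads["w1"] = np.einsum("bot,bctk->ock", dz1, x1)
        grads["b1"] = dz1.sum(axis=(0, 2))
        return grads, loss

    # -- (de)serialization -------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "window": self.window,
            "w1": self.w1.tolist(),
            "b1": self.b1.tolist(),
            "w2": self.w2.tolist(),
            "b2": self.b2.tolist(),
            "w3": self.w3.tolist(),
            "b3": self.b3,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Conv1DNet":
        w1 = np.array(d["w1"])
        w2 = np.array(d["w2"])
        net = cls(
            window=int(d["window"]),
            kernel_sizes=(w1.shape[2], w2.shape[2]),
            channels=(w1.shape[0], w2.shape[0]),
        )
        net.w1, net.b1 = w1, np.array(d["b1"])
        net.w2, net.b2 = w2, np.array(d["b2"])
        net.w3, net.b3 = np.array(d["w3"]), float(d["b3"])
        return net
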