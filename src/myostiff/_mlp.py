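"""Minimal feed-forward network engine: ReLU hidden layers, Adam, MAE loss.

Weights are float32; He-normal initialization from a seeded generator.  The
loss is the mean absolute error of Eq.-style normalization: the per-batch
objective sums |error| over output dimensions and averages over the batch,
so its subgradient is sign(pred - target)/batch.
"""

from __future__ import annotations

import numpy as np

__all__ = ["MLP"]


class MLP:
    def __init__(self, layer_sizes, seed: int = 0):
        """layer_sizes: e.g. (114, 512, 512, 2)."""
        self.layer_sizes = tuple(int(s) for s in layer_sizes)
        rng = np.random.default_rng(seed)
        self.W, self.b = [], []
        for fan_in, fan_out in zip(self.layer_sizes[:-1], self.layer_sizes[1:]):
            w = rng.standard_normal((fan_in, fan_out)) * np.sqrt(2.0 / fan_in)
            self.W.append(w.astype(np.float32))
            self.b.append(np.zeros(fan_out, dtype=np.float32))
        self._adam = None

    # ------------------------------------------------------------------
    def forward(self, X: np.ndarray) -> np.ndarray:
        a = X.astype(np.float32, copy=False)
        last = len(self.W) - 1
        for i, (w, b) in enumerate(zip(self.W, self.b)):
            a = a @ w + b
            if i < last:
                np.maximum(a, 0.0, out=a)
        return a

    def mae(self, X: np.ndarray, Y: np.ndarray) -> float:
        """Sum of |error| over outputs, mean over rows."""
        return float(np.abs(self.forward(X) - Y).sum(axis=1).mean())

    # ------------------------------------------------------------------
    def _init_adam(self):
        self._adam = {
            "t": 0,
            "mW": [np.zeros_like(w) for w in self.W],
            "vW": [np.zeros_like(w) for w in self.W],
            "mb": [np.zeros_like(b) for b in self.b],
            "vb": [np.zeros_like(b) for b in self.b],
        }

    def train_epoch(self, X: np.ndarray, Y: np.ndarray, rng: np.random.Generator,
                    lr: float = 1e-4, batch_size: int = 32,
                    beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8) -> float:
        """One epoch of shuffled mini-batch Adam on the MAE loss.

        Returns the mean per-batch training loss of the epoch.
        """
        if self._adam is None:
            self._init_adam()
        st = self._adam
        n = len(X)
        order = rng.permutation(n)
        losses = []
        for s in range(0, n, batch_size):
            idx = order[s:s + batch_size]
            x, y = X[idx], Y[idx]
            # forward, caching pre-activations
            acts = [x]
            zs = []
            a = x
            last = len(self.W) - 1
            for i, (w, b) in enumerate(zip(self.W, self.b)):
                z = a @ w + b
                zs.append(z)
                a = np.maximum(z, 0.0) if i < last else z
                acts.append(a)
            err = acts[-1] - y
            losses.append(float(np.abs(err).sum(axis=1).mean()))
            g = np.sign(err).astype(np.float32) / len(idx)
            # backward
            gW = [None] * len(self.W)
            gb = [None] * len(self.b)
            for i in range(len(self.W) - 1, -1, -1):
                gW[i] = acts[i].T @ g
                gb[i] = g.sum(axis=0)
                if i > 0:
                    g = g @ self.W[i].T
                    g[zs[i - 1] <= 0] = 0.0
            # Adam update
            st["t"] += 1
            t = st["t"]
            c1 = 1.0 - beta1 ** t
            c2 = 1.0 - beta2 ** t
            for i in range(len(self.W)):
                for key, param, grad in (("W", self.W[i], gW[i]), ("b", self.b[i], gb[i])):
                    m = st["m" + key][i]
                    v = st["v" + key][i]
                    m *= beta1
                    m += (1 - beta1) * grad
                    v *= beta2
                    v += (1 - beta2) * grad * grad
                    param -= lr * (m / c1) / (np.sqrt(v / c2) + eps)
        return float(np.mean(losses))

    # ------------------------------------------------------------------
    def get_weights(self):
        return [w.copy() for w in self.W], [b.copy() for b in self.b]

    def set_weights(self, weights):
        W, b = weights
        self.W = [w.copy() for w in W]
        self.b = [x.copy() for x in b]
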