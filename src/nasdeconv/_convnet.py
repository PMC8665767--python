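"""A minimal 1-D convolutional binary classifier in numpy.

Architecture: conv1d (2 input channels, 16 filters, kernel 5) -> ReLU ->
max-pool (2) -> dropout -> dense -> sigmoid, trained with Adam on binary
cross-entropy with early stopping on validation loss.  Written directly
in numpy with manual backpropagation; the network is tiny (a few
thousand parameters) and trains in seconds on CPU.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class ConvNet1D:
    def __init__(
        self,
        n_channels: int = 2,
        length: int = 21,
        filters: int = 16,
        kernel: int = 5,
        pool: int = 2,
        dropout: float = 0.3,
        lr: float = 1e-3,
        seed: int = 0,
    ):
        self.C, self.L, self.F, self.K = n_channels, length, filters, kernel
        self.pool = pool
        self.dropout = dropout
        self.lr = lr
        self.seed = seed
        self.Lc = length - kernel + 1
        self.Lp = self.Lc // pool
        self.trained = False
        self._init_params(np.random.default_rng(seed))

    def _init_params(self, rng):
        scale = np.sqrt(2.0 / (self.C * self.K))
        self.W1 = rng.normal(0, scale, size=(self.F, self.C, self.K))
        self.b1 = np.zeros(self.F)
        self.W2 = rng.normal(0, np.sqrt(2.0 / (self.F * self.Lp)), size=self.F * self.Lp)
        self.b2 = 0.0

    # -- forward -------------------------------------------------------

    def _forward(self, x, rng=None):
        """x: (N, C, L).  Returns probabilities and a cache for backprop."""
        xw = sliding_window_view(x, self.K, axis=2)          # (N, C, Lc, K)
        z1 = np.einsum("fck,nclk->nfl", self.W1, xw) + self.b1[None, :, None]
        a1 = np.maximum(z1, 0.0)
        n, F, Lc = a1.shape
        a1p = a1[:, :, : self.Lp * self.pool].reshape(n, F, self.Lp, self.pool)
        amax = a1p.argmax(axis=3)
        p1 = np.take_along_axis(a1p, amax[..., None], axis=3)[..., 0]
        if rng is not None and self.dropout > 0:
            mask = (rng.random(p1.shape) >= self.dropout) / (1.0 - self.dropout)
        else:
            mask = np.ones_like(p1)
        h = (p1 * mask).reshape(n, -1)
        logit = h @ self.W2 + self.b2
        prob = 1.0 / (1.0 + np.exp(-logit))
        return prob, (x, xw, z1, a1p, amax, mask, h)

    def predict_proba(self, features: np.ndarray) -> np.ndarray:
        """features: (N, C*L) flat vectors."""
        x = np.asarray(features, dtype=np.float64).reshape(-1, self.C, self.L)
        prob, _ = self._forward(x, rng=None)
        return prob

    # -- training ------------------------------------------------------

    def fit(
        self,
        features: np.ndarray,
        labels: np.ndarray,
        epochs: int = 200,
        batch_size: int = 64,
        val_fraction: float = 0.2,
        patience: int = 10,
    ) -> dict:
        rng = np.random.default_rng(self.seed)
        self._init_params(rng)
        x = np.asarray(features, dtype=np.float64).reshape(-1, self.C, self.L)
        y = np.asarray(labels, dtype=np.float64)
        n = len(x)
        order = rng.permutation(n)
        n_val = max(1, int(round(val_fraction * n)))
        val_idx, tr_idx = order[:n_val], order[n_val:]
        xv, yv = x[val_idx], y[val_idx]
        xt, yt = x[tr_idx], y[tr_idx]

        m = [np.zeros_like(p) for p in (self.W1, self.b1, self.W2)] + [0.0]
        v = [np.zeros_like(p) for p in (self.W1, self.b1, self.W2)] + [0.0]
        beta1, beta2, eps = 0.9, 0.999, 1e-8
        step = 0
        best_loss, best_params, stall = np.inf, None, 0
        history = []
        for epoch in range(epochs):
            perm = rng.permutation(len(xt))
            for i0 in range(0, len(xt), batch_size):
                idx = perm[i0 : i0 + batch_size]
                grads = self._grads(xt[idx], yt[idx], rng)
                step += 1
                params = [self.W1, self.b1, self.W2, self.b2]
                new = []
                for k, (p, g) in enumerate(zip(params, grads)):
                    m[k] = beta1 * m[k] + (1 - beta1) * g
                    v[k] = beta2 * v[k] + (1 - beta2) * np.square(g)
                    mh = m[k] / (1 - beta1**step)
                    vh = v[k] / (1 - beta2**step)
                    new.append(p - self.lr * mh / (np.sqrt(vh) + eps))
                self.W1, self.b1, self.W2, self.b2 = new
            pv, _ = self._forward(xv, rng=None)
            val_loss = _bce(yv, pv)
            history.append(val_loss)
            if val_loss < best_loss - 1e-6:
                best_loss, stall = val_loss, 0
                best_params = (self.W1.copy(), self.b1.copy(), self.W2.copy(), self.b2)
            else:
                stall += 1
                if stall >= patience:
                    break
        if best_params is not None:
            self.W1, self.b1, self.W2, self.b2 = best_params
        self.trained = True
        return {"val_loss": best_loss, "epochs": len(history), "history": history}

    def _grads(self, x, y, rng):
        prob, (x_, xw, z1, a1p, amax, mask, h) = self._forward(x, rng=rng)
        n = len(x)
        dlogit = (prob - y) / n
        dW2 = h.T @ dlogit
        db2 = dlogit.sum()
        dh = np.outer(dlogit, self.W2).reshape(a1p.shape[0], self.F, self.Lp)
        dp1 = dh * mask
        da1p = np.zeros_like(a1p)
        np.put_along_axis(da1p, amax[..., None], dp1[..., None], axis=3)
        da1 = np.zeros_like(z1)
        da1[:, :, : self.Lp * self.pool] = da1p.reshape(n, self.F, self.Lp * self.pool)
        dz1 = da1 * (z1 > 0)
        dW1 = np.einsum("nfl,nclk->fck", dz1, xw)
        db1 = dz1.sum(axis=(0, 2))
        return [dW1, db1, dW2, db2]

    # -- persistence ---------------------------------------------------

    def save(self, path: str) -> None:
        np.savez(
            path,
            W1=self.W1, b1=self.b1, W2=self.W2, b2=self.b2,
            meta=np.array([self.C, self.L, self.F, self.K, self.pool]),
            dropout=self.dropout, trained=int(self.trained),
        )

    @classmethod
    def load(cls, path: str) -> "ConvNet1D":
        d = np.load(path if str(path).endswith(".npz") else str(path) + ".npz")
        C, L, F, K, pool = (int(x) for x in d["meta"])
        net = cls(C, L, F, K, pool, dropout=float(d["dropout"]))
        net.W1, net.b1, net.W2, net.b2 = d["W1"], d["b1"], d["W2"], float(d["b2"])
        net.trained = bool(d["trained"])
        return net


def _bce(y, p, eps=1e-12):
    p = np.clip(p, eps, 1 - eps)
    return float(-(y * np.log(p) + (1 - y) * np.log(1 - p)).mean())
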