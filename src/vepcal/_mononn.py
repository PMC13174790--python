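"""Monotone posterior network.

A 1-input MLP with two hidden layers of width 16 whose weights are
re-parameterized through softplus, making every weight non-negative and the
score-to-posterior map monotone non-decreasing by construction. Trained with
full-batch Adam on the binomial negative log-likelihood, early stopping on a
20% validation split.
"""

from __future__ import annotations

import numpy as np

_HIDDEN = 16


def _softplus(v):
    return np.logaddexp(0.0, v)


def _sigmoid(z):
    return 1.0 / (1.0 + np.exp(-np.clip(z, -35, 35)))


class MonotoneNet:
    def __init__(self, seed=0):
        rng = np.random.default_rng(seed)
        # softplus(-1) ~ 0.31: weights start small but nonzero
        self.params = {
            "V1": rng.normal(-1.0, 0.5, size=(1, _HIDDEN)),
            "b1": np.zeros(_HIDDEN),
            "V2": rng.normal(-1.0, 0.5, size=(_HIDDEN, _HIDDEN)),
            "b2": np.zeros(_HIDDEN),
            "V3": rng.normal(-1.0, 0.5, size=(_HIDDEN, 1)),
            "b3": np.zeros(1),
        }
        self._seed = seed

    def _forward(self, x, params):
        W1, W2, W3 = (_softplus(params[k]) for k in ("V1", "V2", "V3"))
        h1 = np.tanh(x @ W1 + params["b1"])
        h2 = np.tanh(h1 @ W2 + params["b2"])
        z = (h2 @ W3 + params["b3"]).ravel()
        return _sigmoid(z), (x, h1, h2, W1, W2, W3)

    def predict(self, scores):
        x = np.asarray(scores, dtype=float).reshape(-1, 1)
        p, _ = self._forward(x, self.params)
        return p

    @staticmethod
    def _loss(p, y):
        eps = 1e-12
        return -float(np.mean(y * np.log(p + eps) + (1 - y) * np.log(1 - p + eps)))

    def fit(self, scores, labels, lr=0.05, max_epochs=400, patience=30):
        x_all = np.asarray(scores, dtype=float).reshape(-1, 1)
        y_all = np.asarray(labels, dtype=float)
        rng = np.random.default_rng(self._seed + 1)
        idx = rng.permutation(len(y_all))
        n_val = max(1, int(0.2 * len(y_all)))
        vi, ti = idx[:n_val], idx[n_val:]
        if len(ti) < 2:
            ti = idx
        x, y = x_all[ti], y_all[ti]
        xv, yv = x_all[vi], y_all[vi]

        p = self.params
        m = {k: np.zeros_like(v) for k, v in p.items()}
        v = {k: np.zeros_like(val) for k, val in p.items()}
        b1_, b2_ = 0.9, 0.999
        best_loss, best_params, wait = np.inf, None, 0

        for t in range(1, max_epochs + 1):
            prob, (xc, h1, h2, W1, W2, W3) = self._forward(x, p)
            n = len(y)
            dz = (prob - y).reshape(-1, 1) / n
            g = {}
            g["b3"] = dz.sum(axis=0)
            gW3 = h2.T @ dz
            dh2 = dz @ W3.T
            dz2 = dh2 * (1 - h2 * h2)
            g["b2"] = dz2.sum(axis=0)
            gW2 = h1.T @ dz2
            dh1 = dz2 @ W2.T
            dz1 = dh1 * (1 - h1 * h1)
            g["b1"] = dz1.sum(axis=0)
            gW1 = xc.T @ dz1
            # chain rule through the softplus re-parameterization
            g["V1"] = gW1 * _sigmoid(p["V1"])
            g["V2"] = gW2 * _sigmoid(p["V2"])
            g["V3"] = gW3 * _sigmoid(p["V3"])

            for k in p:
                m[k] = b1_ * m[k] + (1 - b1_) * g[k]
                v[k] = b2_ * v[k] + (1 - b2_) * g[k] ** 2
                mhat = m[k] / (1 - b1_ ** t)
                vhat = v[k] / (1 - b2_ ** t)
                p[k] = p[k] - lr * mhat / (np.sqrt(vhat) + 1e-8)

            val_prob, _ = self._forward(xv, p)
            val_loss = self._loss(val_prob, yv)
            if val_loss < best_loss - 1e-6:
                best_loss, wait = val_loss, 0
                best_params = {k: val.copy() for k, val in p.items()}
            else:
                wait += 1
                if wait >= patience:
                    break
        if best_params is not None:
            self.params = best_params
        return self
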