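"""Compact sequence classifier: embedding -> global max pooling -> dense.

Documents are token-index sequences; each token looks up a learned
embedding, a global max over the sequence pools per embedding dimension,
and two dense layers (ReLU hidden, sigmoid output) produce the case
probability.  Training is plain mini-batch Adam on binary cross-entropy,
implemented in numpy — the model is tiny and CPU-bound by design.

Gradient flow through the max pool routes each pooled dimension's gradient
to the embedding row of the token that attained the max (standard max-pool
backprop).  Padding uses a reserved index whose embedding row is pinned at a
large negative value so padded positions never win the max.
"""

from __future__ import annotations

import numpy as np

PAD_INDEX = 0
OOV_INDEX = 1

_PAD_FILL = -1e9


class EmbeddingMaxPoolClassifier:
    """Binary classifier over padded token-index sequences.

    Parameters
    ----------
    vocab_size : total number of indices (including pad and OOV).
    embed_dim : embedding width (pooled feature width).
    hidden_dim : units in the dense hidden layer.
    epochs, batch_size, lr : Adam training schedule.
    seed : initialisation and shuffling seed (deterministic training).
    """

    def __init__(self, vocab_size: int, embed_dim: int = 64, hidden_dim: int = 64,
                 epochs: int = 12, batch_size: int = 32, lr: float = 1e-2,
                 seed: int = 0):
        self.vocab_size = vocab_size
        self.embed_dim = embed_dim
        self.hidden_dim = hidden_dim
        self.epochs = epochs
        self.batch_size = batch_size
        self.lr = lr
        self.seed = seed

    def _init_params(self, rng: np.random.Generator) -> None:
        d, h = self.embed_dim, self.hidden_dim
        self.E = rng.normal(0.0, 0.05, size=(self.vocab_size, d))
        self.E[PAD_INDEX] = _PAD_FILL
        self.W1 = rng.normal(0.0, np.sqrt(2.0 / d), size=(d, h))
        self.b1 = np.zeros(h)
        self.W2 = rng.normal(0.0, np.sqrt(2.0 / h), size=(h,))
        self.b2 = 0.0

    def _forward(self, X: np.ndarray):
        emb = self.E[X]                       # (n, L, d)
        arg = emb.argmax(axis=1)              # (n, d) winning positions
        pooled = np.take_along_axis(emb, arg[:, None, :], axis=1)[:, 0, :]
        # all-pad rows pool to the pad fill; clamp so dense math stays finite
        pooled = np.maximum(pooled, -10.0)
        z1 = pooled @ self.W1 + self.b1
        h1 = np.maximum(z1, 0.0)
        logit = h1 @ self.W2 + self.b2
        p = 1.0 / (1.0 + np.exp(-np.clip(logit, -30, 30)))
        return emb, arg, pooled, z1, h1, p

    def fit(self, X: np.ndarray, y: np.ndarray) -> "EmbeddingMaxPoolClassifier":
        X = np.asarray(X, dtype=np.int64)
        y = np.asarray(y, dtype=float)
        rng = np.random.default_rng(self.seed)
        self._init_params(rng)

        params = ["E", "W1", "b1", "W2", "b2"]
        m = {p: np.zeros_like(np.asarray(getattr(self, p), dtype=float)) for p in params}
        v = {p: np.zeros_like(np.asarray(getattr(self, p), dtype=float)) for p in params}
        beta1, beta2, eps = 0.9, 0.999, 1e-8
        step = 0

        n = len(X)
        for _ in range(self.epochs):
            order = rng.permutation(n)
            for lo in range(0, n, self.batch_size):
                idx = order[lo:lo + self.batch_size]
                xb, yb = X[idx], y[idx]
                _, arg, pooled, z1, h1, p = self._forward(xb)

                # binary cross-entropy gradients
                dlogit = (p - yb) / len(xb)               # (m,)
                gW2 = h1.T @ dlogit
                gb2 = dlogit.sum()
                dh1 = dlogit[:, None] * self.W2[None, :]
                dz1 = dh1 * (z1 > 0)
                gW1 = pooled.T @ dz1
                gb1 = dz1.sum(axis=0)
                dpooled = dz1 @ self.W1.T                  # (m, d)
                gE = np.zeros_like(self.E)
                win_tokens = np.take_along_axis(xb, arg, axis=1)  # (m, d)
                cols = np.tile(np.arange(self.embed_dim), len(xb))
                np.add.at(gE, (win_tokens.ravel(), cols), dpooled.ravel())

                grads = {"E": gE, "W1": gW1, "b1": gb1, "W2": gW2, "b2": gb2}
                step += 1
                for name in params:
                    g = grads[name]
                    m[name] = beta1 * m[name] + (1 - beta1) * g
                    v[name] = beta2 * v[name] + (1 - beta2) * np.square(g)
                    mhat = m[name] / (1 - beta1 ** step)
                    vhat = v[name] / (1 - beta2 ** step)
                    upd = self.lr * mhat / (np.sqrt(vhat) + eps)
                    if name == "b2":
                        self.b2 -= float(upd)
                    else:
                        setattr(self, name, getattr(self, name) - upd)
                self.E[PAD_INDEX] = _PAD_FILL  # keep padding out of the max
        return self

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=np.int64)
        p = self._forward(X)[-1]
        return np.column_stack([1.0 - p, p])

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        return self.predict_proba(X)[:, 1]
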