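"""Multi-layer perceptron classifier on the package's NumPy engine.

ReLU hidden layers with widths halving after the first, dropout after
each hidden layer, a single sigmoid output unit, binary cross-entropy
loss, Adam (learning rate 0.001), minibatches of 32, and a fixed epoch
count — the epoch budget is a grid hyper-parameter, not early-stopped.
"""

from __future__ import annotations

import numpy as np

from . import _nn

__all__ = ["mlp_layer_schedule", "MLPClassifierNet"]


def mlp_layer_schedule(first_layer_units: int, n_hidden_layers: int) -> list[int]:
    """Hidden-layer widths: first_layer_units, then floor-halving.

    Raises if any width would fall below one unit.
    """
    if first_layer_units < 1:
        raise ValueError("first_layer_units must be >= 1")
    if n_hidden_layers < 1:
        raise ValueError("n_hidden_layers must be >= 1")
    widths = [first_layer_units // 2**k for k in range(n_hidden_layers)]
    if any(w < 1 for w in widths):
        raise ValueError(f"layer schedule {widths} reaches a width below 1")
    return widths


class MLPClassifierNet:
    """sklearn-like binary classifier: fit / predict / predict_proba."""

    def __init__(
        self,
        n_features: int,
        first_layer_units: int,
        n_hidden_layers: int,
        dropout: float,
        epochs: int,
        seed: int = 0,
        batch_size: int = 32,
        lr: float = 1e-3,
    ):
        self.n_features = n_features
        self.widths = mlp_layer_schedule(first_layer_units, n_hidden_layers)
        self.dropout = dropout
        self.epochs = epochs
        self.seed = seed
        self.batch_size = batch_size
        self.lr = lr

    def _build(self):
        init_rng = np.random.default_rng([self.seed, 11])
        drop_rng = np.random.default_rng([self.seed, 13])
        layers: list[_nn.Layer] = []
        prev = self.n_features
        for w in self.widths:
            layers.append(_nn.Dense(prev, w, init_rng))
            layers.append(_nn.ReLU())
            layers.append(_nn.Dropout(self.dropout, drop_rng))
            prev = w
        layers.append(_nn.Dense(prev, 1, init_rng))  # logit head
        self._net = _nn.Sequential(layers)

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).reshape(-1, 1)
        self._build()
        opt = _nn.Adam(self._net.params(), lr=self.lr, eps=1e-7)
        shuffle_rng = np.random.default_rng([self.seed, 17])
        n = X.shape[0]
        for _ in range(self.epochs):
            order = shuffle_rng.permutation(n)
            for start in range(0, n, self.batch_size):
                idx = order[start : start + self.batch_size]
                logits = self._net.forward(X[idx], training=True)
                probs = _sigmoid(logits)
                # BCE gradient wrt logits
                grad = (probs - y[idx]) / idx.size
                self._net.backward(grad)
                opt.step(self._net.grads())
        return self

    def predict_proba(self, X):
        X = np.asarray(X, dtype=float)
        p = _sigmoid(self._net.forward(X, training=False)).ravel()
        return np.column_stack([1.0 - p, p])

    def predict(self, X):
        return (self.predict_proba(X)[:, 1] > 0.5).astype(int)


def _sigmoid(x):
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out
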