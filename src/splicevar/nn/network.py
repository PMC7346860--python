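"""Sequential network container, loss, and the SGD-Nesterov training loop."""

from __future__ import annotations

import numpy as np

from .layers import Dropout, Layer


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def softmax_cross_entropy(logits: np.ndarray, onehot: np.ndarray
                          ) -> tuple[float, np.ndarray]:
    """Mean categorical cross-entropy and its gradient w.r.t. the logits."""
    p = softmax(logits)
    eps = 1e-12
    loss = -np.mean(np.sum(onehot * np.log(p + eps), axis=1))
    grad = (p - onehot) / logits.shape[0]
    return float(loss), grad


class Network:
    """An ordered stack of layers ending in a 2-way softmax head.

    The final layer must produce the class logits; :meth:`predict_proba`
    applies the softmax. Training uses SGD with Nesterov momentum and a
    caller-supplied per-epoch learning-rate schedule.
    """

    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def init(self, seed: int) -> None:
        rng = np.random.default_rng(seed)
        for layer in self.layers:
            layer.init(rng)
            if isinstance(layer, Dropout):
                # independent, reproducible mask stream per dropout layer
                layer.rng = np.random.default_rng(rng.integers(2 ** 31))

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, training=training)
        return x

    def backward(self, dy: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy

    def params(self) -> list[np.ndarray]:
        return [p for layer in self.layers for p in layer.params()]

    def grads(self) -> list[np.ndarray]:
        return [g for layer in self.layers for g in layer.grads()]

    def predict_proba(self, x: np.ndarray, batch_size: int = 256) -> np.ndarray:
        out = [softmax(self.forward(x[i:i + batch_size], training=False))
               for i in range(0, len(x), batch_size)]
        return np.concatenate(out, axis=0)

    def fit(self, x: np.ndarray, onehot: np.ndarray, *, epochs: int,
            batch_size: int, lr_for_epoch, momentum: float = 0.9,
            seed: int = 0) -> list[dict]:
        """Train in place; returns per-epoch history (loss, learning rate).

        ``lr_for_epoch`` maps the 0-based epoch index to a learning rate.
        Raises on a non-finite loss.
        """
        rng = np.random.default_rng(seed)
        params = self.params()
        velocity = [np.zeros_like(p) for p in params]
        history = []
        n = len(x)
        for epoch in range(epochs):
            lr = float(lr_for_epoch(epoch))
            order = rng.permutation(n)
            losses = []
            for start in range(0, n, batch_size):
                idx = order[start:start + batch_size]
                logits = self.forward(x[idx], training=True)
                loss, dlogits = softmax_cross_entropy(logits, onehot[idx])
                if not np.isfinite(loss):
                    raise RuntimeError(
                        f"non-finite loss {loss} at epoch {epoch}, "
                        f"batch starting {start} (lr={lr}); training aborted"
                    )
                losses.append(loss)
                self.backward(dlogits)
                grads = self.grads()
                for p, v, g in zip(params, velocity, grads):
                    v *= momentum
                    v -= lr * g
                    p += momentum * v - lr * g
            history.append({"epoch": epoch, "lr": lr,
                            "loss": float(np.mean(losses))})
        return history
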