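"""Independent reference implementations used only as test oracles."""

from __future__ import annotations

import numpy as np


class PlainMLP:
    """A from-scratch softmax/ReLU multilayer perceptron without biases.

    Written independently of the package: dense matmul forward, textbook
    backprop, SGD with optional weight decay.  The RNG protocol (one uniform
    draw per layer at init, one permutation per epoch) matches the package's
    so trajectories are comparable bit-for-bit.
    """

    def __init__(self, layer_sizes, rng):
        self.W = []
        for fan_in, fan_out in zip(layer_sizes[:-1], layer_sizes[1:]):
            bound = 1.0 / np.sqrt(fan_in)
            self.W.append(rng.uniform(-bound, bound, size=(fan_out, fan_in)))

    def forward(self, X):
        acts = [X]
        for i, W in enumerate(self.W):
            z = acts[-1] @ W.T
            if i < len(self.W) - 1:
                acts.append(np.maximum(z, 0.0))
            else:
                zs = z - z.max(axis=-1, keepdims=True)
                e = np.exp(zs)
                acts.append(e / e.sum(axis=-1, keepdims=True))
        return acts

    def gradients(self, X, y, lam=0.0):
        acts = self.forward(X)
        B = X.shape[0]
        delta = acts[-1].copy()
        delta[np.arange(B), y] -= 1.0
        grads = [None] * len(self.W)
        for i in range(len(self.W) - 1, -1, -1):
            grads[i] = (delta.T @ acts[i]) / B
            if lam > 0.0:
                grads[i] = grads[i] + lam * self.W[i]
            if i > 0:
                delta = (delta @ self.W[i]) * (acts[i] > 0.0)
        return grads

    def train(self, X, y, eta, epochs, batch_size, rng, lam=0.0):
        n = X.shape[0]
        for _ in range(epochs):
            order = rng.permutation(n)
            for s in range(0, n, batch_size):
                idx = order[s : s + batch_size]
                for W, g in zip(self.W, self.gradients(X[idx], y[idx], lam)):
                    W -= eta * g

    def predict(self, X):
        return self.forward(X)[-1].argmax(axis=1)
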