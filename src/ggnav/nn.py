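"""Minimal feed-forward neural-network primitives on NumPy.

Everything here is deliberately small: the networks this package trains are
a linear softmax head over frozen convolutional features and a three-layer
Q-value MLP, so a hand-rolled forward/backward pass with SGD + momentum is
both sufficient and easy to audit.  All parameters live in plain float64
arrays; no autograd, no GPU.
"""

from __future__ import annotations

import numpy as np

__all__ = ["MLP", "SGDMomentum", "softmax", "relu"]


def relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0)


def softmax(z: np.ndarray, axis: int = -1) -> np.ndarray:
    """Numerically stable softmax along ``axis``."""
    z = np.asarray(z, dtype=np.float64)
    z = z - z.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


class MLP:
    """Fully connected network with ReLU hidden layers and a linear output.

    Parameters
    ----------
    dims
        Layer widths, e.g. ``[4320, 50, 30, 7]`` for the Q-network.
    rng
        Source for He-style weight initialisation.  A zero-init network
        (``init="zeros"``) is occasionally useful in tests.
    """

    def __init__(self, dims, rng: np.random.Generator | None = None,
                 init: str = "he"):
        self.dims = list(dims)
        self.weights: list[np.ndarray] = []
        self.biases: list[np.ndarray] = []
        for fan_in, fan_out in zip(dims[:-1], dims[1:]):
            if init == "zeros":
                w = np.zeros((fan_in, fan_out))
            else:
                if rng is None:
                    raise ValueError("rng required for random initialisation")
                w = rng.standard_normal((fan_in, fan_out)) * np.sqrt(2.0 / fan_in)
            self.weights.append(w)
            self.biases.append(np.zeros(fan_out))

    @property
    def n_layers(self) -> int:
        return len(self.weights)

    def forward(self, x: np.ndarray, return_activations: bool = False):
        """Forward pass on a batch ``(n, dims[0])`` (or a single vector)."""
        squeeze = x.ndim == 1
        a = np.atleast_2d(np.asarray(x, dtype=np.float64))
        if a.shape[1] != self.dims[0]:
            raise ValueError(
                f"input dim {a.shape[1]} != expected {self.dims[0]}")
        activations = [a]
        for i, (w, b) in enumerate(zip(self.weights, self.biases)):
            a = a @ w + b
            if i < self.n_layers - 1:
                a = relu(a)
            activations.append(a)
        out = a[0] if squeeze else a
        if return_activations:
            return out, activations
        return out

    def backward(self, activations, grad_out: np.ndarray):
        """Gradients of a scalar loss w.r.t. parameters.

        ``grad_out`` is dLoss/dOutput for the batch used in ``forward``.
        Returns ``(grads_w, grads_b)`` matching ``weights``/``biases``.
        """
        grads_w = [None] * self.n_layers
        grads_b = [None] * self.n_layers
        delta = np.asarray(grad_out, dtype=np.float64)
        for layer in range(self.n_layers - 1, -1, -1):
            grads_w[layer] = activations[layer].T @ delta
            grads_b[layer] = delta.sum(axis=0)
            if layer > 0:
                delta = delta @ self.weights[layer].T
                delta = np.where(activations[layer] > 0, delta, 0.0)
        return grads_w, grads_b

    def copy_parameters_from(self, other: "MLP") -> None:
        """Hard copy of all parameters (used for target-network syncs)."""
        if other.dims != self.dims:
            raise ValueError("architecture mismatch")
        self.weights = [w.copy() for w in other.weights]
        self.biases = [b.copy() for b in other.biases]

    def parameters_equal(self, other: "MLP") -> bool:
        return all(np.array_equal(a, b) for a, b in
                   zip(self.weights + self.biases,
                       other.weights + other.biases))

    def state_dict(self) -> dict:
        return {
            "dims": list(self.dims),
            **{f"w{i}": w for i, w in enumerate(self.weights)},
            **{f"b{i}": b for i, b in enumerate(self.biases)},
        }

    @classmethod
    def from_state_dict(cls, state: dict) -> "MLP":
        net = cls(state["dims"], init="zeros")
        net.weights = [np.asarray(state[f"w{i}"], dtype=np.float64)
                       for i in range(net.n_layers)]
        net.biases = [np.asarray(state[f"b{i}"], dtype=np.float64)
                      for i in range(net.n_layers)]
        return net


class SGDMomentum:
    """Classical momentum SGD: v <- m*v - lr*g ; p <- p + v."""

    def __init__(self, net: MLP, lr: float, momentum: float = 0.9):
        self.net = net
        self.lr = float(lr)
        self.momentum = float(momentum)
        self._vel_w = [np.zeros_like(w) for w in net.weights]
        self._vel_b = [np.zeros_like(b) for b in net.biases]

    def step(self, grads_w, grads_b) -> None:
        for i in range(self.net.n_layers):
            self._vel_w[i] = self.momentum * self._vel_w[i] - self.lr * grads_w[i]
            self._vel_b[i] = self.momentum * self._vel_b[i] - self.lr * grads_b[i]
            self.net.weights[i] += self._vel_w[i]
            self.net.biases[i] += self._vel_b[i]
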