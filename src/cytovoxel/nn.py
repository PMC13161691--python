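"""Small feed-forward network with manual backprop, used by the aligner.

Layers: dense, batch normalization (batch statistics during training, frozen
running statistics at inference) and ReLU. Optimized with Adam. Everything is
seeded and runs on plain numpy arrays, so identical configs give bit-identical
models on the same platform.
"""

from __future__ import annotations

import numpy as np

__all__ = ["MLP", "Adam"]


class _Dense:
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        # He initialization, appropriate for the ReLU nonlinearities.
        self.W = rng.normal(0.0, np.sqrt(2.0 / n_in), size=(n_in, n_out))
        self.b = np.zeros(n_out)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._x: np.ndarray | None = None

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        if training:
            self._x = x
        return x @ self.W + self.b

    def backward(self, grad: np.ndarray) -> np.ndarray:
        self.dW[...] = self._x.T @ grad
        self.db[...] = grad.sum(axis=0)
        return grad @ self.W.T

    def params(self):
        return [(self.W, self.dW), (self.b, self.db)]

    def state(self) -> dict:
        return {"W": self.W, "b": self.b}


class _BatchNorm:
    def __init__(self, n: int, momentum: float = 0.9, eps: float = 1e-5):
        self.gamma = np.ones(n)
        self.beta = np.zeros(n)
        self.running_mean = np.zeros(n)
        self.running_var = np.ones(n)
        self.momentum = momentum
        self.eps = eps
        self.dgamma = np.zeros(n)
        self.dbeta = np.zeros(n)
        self._cache = None

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        if training:
            mu = x.mean(axis=0)
            var = x.var(axis=0)
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mu
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
        else:
            mu, var = self.running_mean, self.running_var
        inv_sd = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu) * inv_sd
        if training:
            self._cache = (xhat, inv_sd)
        return self.gamma * xhat + self.beta

    def backward(self, grad: np.ndarray) -> np.ndarray:
        xhat, inv_sd = self._cache
        n = grad.shape[0]
        self.dgamma[...] = (grad * xhat).sum(axis=0)
        self.dbeta[...] = grad.sum(axis=0)
        # standard batch-norm backward through the batch statistics
        return (self.gamma * inv_sd / n) * (
            n * grad - self.dbeta - xhat * self.dgamma
        )

    def params(self):
        return [(self.gamma, self.dgamma), (self.beta, self.dbeta)]

    def state(self) -> dict:
        return {
            "gamma": self.gamma,
            "beta": self.beta,
            "running_mean": self.running_mean,
            "running_var": self.running_var,
        }


class _ReLU:
    def __init__(self):
        self._mask: np.ndarray | None = None

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        out = np.maximum(x, 0.0)
        if training:
            self._mask = x > 0
        return out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad * self._mask

    def params(self):
        return []

    def state(self) -> dict:
        return {}


class MLP:
    """Dense[->BN]->ReLU stack with a linear output layer."""

    def __init__(self, widths: list[int], batch_norm: bool, rng: np.random.Generator):
        """``widths`` includes input and output, e.g. [6, 64, 32, 16, 32, 64, 6]."""
        self.widths = list(widths)
        self.batch_norm = batch_norm
        self.layers: list = []
        for i in range(len(widths) - 2):
            self.layers.append(_Dense(widths[i], widths[i + 1], rng))
            if batch_norm:
                self.layers.append(_BatchNorm(widths[i + 1]))
            self.layers.append(_ReLU())
        self.layers.append(_Dense(widths[-2], widths[-1], rng))

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, training)
        return x

    def backward(self, grad: np.ndarray) -> None:
        for layer in reversed(self.layers):
            grad = layer.backward(grad)

    def params(self):
        out = []
        for layer in self.layers:
            out.extend(layer.params())
        return out

    # -- serialization -----------------------------------------------------
    def state_dict(self) -> list[dict]:
        return [{k: v.tolist() for k, v in layer.state().items()} for layer in self.layers]

    def load_state_dict(self, states: list[dict]) -> None:
        if len(states) != len(self.layers):
            raise ValueError("state dict does not match architecture")
        for layer, st in zip(self.layers, states):
            for k, v in st.items():
                getattr(layer, k)[...] = np.asarray(v, dtype=np.float64)


class Adam:
    """Adaptive-moment optimizer over (param, grad) array pairs."""

    def __init__(self, params, lr: float, beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p) for p, _ in params]
        self.v = [np.zeros_like(p) for p, _ in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for (p, g), m, v in zip(self.params, self.m, self.v):
            m *= self.beta1
            m += (1 - self.beta1) * g
            v *= self.beta2
            v += (1 - self.beta2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
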