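"""Minimal dense-layer toolkit with hand-written reverse-mode gradients.

The embedding model is a stack of small MLPs glued together with
gather/scatter operations, so a full autodiff framework is unnecessary:
each layer caches its input on ``forward`` and accumulates parameter
gradients on ``backward``. All computation is float64 NumPy, which keeps
training bit-reproducible for a fixed seed on any platform.
"""

from __future__ import annotations

import numpy as np
from scipy.special import expit

__all__ = ["Dense", "SiLU", "MLP", "Adam"]


class Dense:
    """Affine layer y = x W + b with uniform fan-in initialization
    U(−1/√d_in, 1/√d_in) for both weights and bias."""

    def __init__(self, rng: np.random.Generator, d_in: int, d_out: int):
        bound = 1.0 / np.sqrt(d_in)
        self.W = rng.uniform(-bound, bound, size=(d_in, d_out))
        self.b = rng.uniform(-bound, bound, size=d_out)
        self.gW = np.zeros_like(self.W)
        self.gb = np.zeros_like(self.b)
        self._x: np.ndarray | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.W + self.b

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        self.gW += self._x.T @ grad_out
        self.gb += grad_out.sum(axis=0)
        return grad_out @ self.W.T

    def parameters(self):
        yield self.W, self.gW
        yield self.b, self.gb

    def zero_grad(self) -> None:
        self.gW[:] = 0.0
        self.gb[:] = 0.0


class SiLU:
    """Swish/SiLU activation x·σ(x)."""

    def __init__(self):
        self._x: np.ndarray | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x * expit(x)

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        sig = expit(self._x)
        return grad_out * sig * (1.0 + self._x * (1.0 - sig))

    def parameters(self):
        return iter(())

    def zero_grad(self) -> None:
        pass


class MLP:
    """Dense/SiLU stack. ``dims`` lists layer widths; SiLU follows every
    Dense except, optionally, the last."""

    def __init__(
        self,
        rng: np.random.Generator,
        dims: list[int],
        final_activation: bool = False,
    ):
        self.layers: list[Dense | SiLU] = []
        n_dense = len(dims) - 1
        for k in range(n_dense):
            self.layers.append(Dense(rng, dims[k], dims[k + 1]))
            if k < n_dense - 1 or final_activation:
                self.layers.append(SiLU())

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            grad_out = layer.backward(grad_out)
        return grad_out

    def parameters(self):
        for layer in self.layers:
            yield from layer.parameters()

    def zero_grad(self) -> None:
        for layer in self.layers:
            layer.zero_grad()


class Adam:
    """Adam optimizer over a list of (param, grad) array pairs.

    ``weight_decay`` is the classic L2 coupling (added to the gradient
    before the moment updates)."""

    def __init__(
        self,
        params: list[tuple[np.ndarray, np.ndarray]],
        lr: float = 1e-3,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
        weight_decay: float = 0.0,
    ):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.m = [np.zeros_like(p) for p, _ in params]
        self.v = [np.zeros_like(p) for p, _ in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        bc1 = 1.0 - self.beta1**self.t
        bc2 = 1.0 - self.beta2**self.t
        for (p, g), m, v in zip(self.params, self.m, self.v):
            if self.weight_decay:
                g = g + self.weight_decay * p
            m *= self.beta1
            m += (1.0 - self.beta1) * g
            v *= self.beta2
            v += (1.0 - self.beta2) * g * g
            p -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)

    def zero_grad(self) -> None:
        for _, g in self.params:
            g[:] = 0.0
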