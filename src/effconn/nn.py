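"""Neural-network building blocks on top of the tensor engine.

Layers hold :class:`~effconn._tensor.Tensor` parameters with
``requires_grad=True``; :class:`Adam` updates them in place.  Initialization
is fully determined by the ``numpy.random.Generator`` passed in, which is how
the package keeps training bitwise-reproducible for a fixed seed.
"""

from __future__ import annotations

from typing import Callable, Iterable, Sequence

import numpy as np

from ._tensor import Tensor, layer_norm, relu, tanh

__all__ = ["Linear", "LayerNorm", "MLP", "Adam", "get_activation"]

_ACTIVATIONS: dict[str, Callable[[Tensor], Tensor]] = {
    "relu": relu,
    "tanh": tanh,
    "identity": lambda x: x,
}


def get_activation(name: str) -> Callable[[Tensor], Tensor]:
    try:
        return _ACTIVATIONS[name]
    except KeyError:
        raise ValueError(
            f"unknown activation {name!r}; choose from {sorted(_ACTIVATIONS)}"
        ) from None


class Linear:
    """Affine map ``y = x @ W + b`` with W of shape (in_dim, out_dim)."""

    def __init__(
        self,
        in_dim: int,
        out_dim: int,
        rng: np.random.Generator,
        weight_scale: float | None = None,
    ):
        scale = weight_scale if weight_scale is not None else 1.0 / np.sqrt(in_dim)
        self.weight = Tensor(rng.normal(0.0, scale, size=(in_dim, out_dim)), requires_grad=True)
        self.bias = Tensor(np.zeros(out_dim), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias

    def parameters(self) -> list[Tensor]:
        return [self.weight, self.bias]


class LayerNorm:
    def __init__(self, dim: int, eps: float = 1e-5):
        self.gain = Tensor(np.ones(dim), requires_grad=True)
        self.bias = Tensor(np.zeros(dim), requires_grad=True)
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        return layer_norm(x, self.gain, self.bias, self.eps)

    def parameters(self) -> list[Tensor]:
        return [self.gain, self.bias]


class MLP:
    """Fully connected stack; the activation is applied between layers only."""

    def __init__(self, dims: Sequence[int], activation: str, rng: np.random.Generator):
        if len(dims) < 2:
            raise ValueError("MLP needs at least an input and an output dimension")
        self.layers = [Linear(a, b, rng) for a, b in zip(dims[:-1], dims[1:])]
        self.activation = get_activation(activation)

    def __call__(self, x: Tensor) -> Tensor:
        for layer in self.layers[:-1]:
            x = self.activation(layer(x))
        return self.layers[-1](x)

    def parameters(self) -> list[Tensor]:
        return [p for layer in self.layers for p in layer.parameters()]


class Adam:
    """Adaptive-moment gradient descent (the standard bias-corrected form)."""

    def __init__(
        self,
        params: Iterable[Tensor],
        lr: float,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
    ):
        self.params = list(params)
        self.lr = float(lr)
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self._m[i] = self.b1 * self._m[i] + (1 - self.b1) * g
            self._v[i] = self.b2 * self._v[i] + (1 - self.b2) * g * g
            mhat = self._m[i] / (1 - self.b1**self.t)
            vhat = self._v[i] / (1 - self.b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
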