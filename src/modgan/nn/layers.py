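"""Neural-network building blocks on top of the autodiff engine.

Conventions follow the image-to-image translation literature: weights are
drawn from N(0, 0.02), instance normalisation carries no learned affine
parameters, leaky-ReLU slope defaults to 0.2, dropout is active only when a
module is in training mode.
"""

from __future__ import annotations

import numpy as np

from .autograd import Tensor, conv2d, conv_transpose2d

__all__ = [
    "Parameter",
    "Module",
    "Conv2d",
    "ConvTranspose2d",
    "Linear",
    "Dropout",
    "instance_norm_2d",
    "instance_norm_1d",
    "adain",
    "Adam",
]

INIT_STD = 0.02


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Module:
    """Minimal container: tracks parameters, sub-modules and train mode."""

    def __init__(self):
        self.training = True

    @staticmethod
    def _walk(value):
        if isinstance(value, (Parameter, Module)):
            yield value
        elif isinstance(value, (list, tuple)):
            for item in value:
                yield from Module._walk(item)

    def parameters(self) -> list[Parameter]:
        params: list[Parameter] = []
        for value in self.__dict__.values():
            for node in self._walk(value):
                if isinstance(node, Parameter):
                    params.append(node)
                else:
                    params.extend(node.parameters())
        return params

    def train(self, mode: bool = True):
        self.training = mode
        for value in self.__dict__.values():
            for node in self._walk(value):
                if isinstance(node, Module):
                    node.train(mode)
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    # -- flat (de)serialisation -------------------------------------------
    def state_arrays(self) -> list[np.ndarray]:
        return [p.data for p in self.parameters()]

    def load_state_arrays(self, arrays: list[np.ndarray]) -> None:
        params = self.parameters()
        if len(arrays) != len(params):
            raise ValueError(
                f"checkpoint has {len(arrays)} arrays, model has {len(params)}"
            )
        for p, a in zip(params, arrays):
            if p.data.shape != a.shape:
                raise ValueError(f"shape mismatch {p.data.shape} vs {a.shape}")
            p.data = np.asarray(a, dtype=np.float64).copy()

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Conv2d(Module):
    def __init__(self, cin: int, cout: int, kernel: int, stride: int = 1,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng()
        self.stride = stride
        self.weight = Parameter(rng.normal(0.0, INIT_STD, (cout, cin, kernel, kernel)))
        self.bias = Parameter(np.zeros(cout))

    def forward(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias, stride=self.stride, padding="same")


class ConvTranspose2d(Module):
    def __init__(self, cin: int, cout: int, kernel: int, stride: int = 1,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng()
        self.stride = stride
        self.weight = Parameter(rng.normal(0.0, INIT_STD, (cin, cout, kernel, kernel)))
        self.bias = Parameter(np.zeros(cout))

    def forward(self, x: Tensor) -> Tensor:
        return conv_transpose2d(x, self.weight, self.bias, stride=self.stride)


class Linear(Module):
    def __init__(self, fin: int, fout: int, rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng()
        self.weight = Parameter(rng.normal(0.0, INIT_STD, (fin, fout)))
        self.bias = Parameter(np.zeros(fout))

    def forward(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class Dropout(Module):
    """Seeded inverted dropout; identity in eval mode or at rate 0."""

    def __init__(self, rate: float, rng: np.random.Generator | None = None):
        super().__init__()
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self.rng = rng or np.random.default_rng()

    def forward(self, x: Tensor) -> Tensor:
        if not self.training or self.rate == 0.0:
            return x
        keep = 1.0 - self.rate
        mask = (self.rng.random(x.shape) < keep) / keep
        return x * Tensor(mask)


def instance_norm_2d(x: Tensor, eps: float = 1e-5) -> Tensor:
    """Per-instance, per-channel normalisation over spatial dims (no affine)."""
    mu = x.mean(axis=(2, 3), keepdims=True)
    centred = x - mu
    var = (centred * centred).mean(axis=(2, 3), keepdims=True)
    return centred / (var + eps).sqrt()


def instance_norm_1d(x: Tensor, eps: float = 1e-5) -> Tensor:
    """Normalise each row (sample) of a (N, F) tensor over features."""
    mu = x.mean(axis=1, keepdims=True)
    centred = x - mu
    var = (centred * centred).mean(axis=1, keepdims=True)
    return centred / (var + eps).sqrt()


def adain(features: Tensor, style_scale, style_shift, eps: float = 1e-5) -> Tensor:
    """Adaptive instance normalisation.

    Normalises each channel of ``features`` (N, C, H, W) over its spatial
    extent, then scales and shifts it with externally supplied per-channel
    style parameters (arrays or tensors of length C, or shape (N, C)).
    """
    from .autograd import as_tensor

    n, c = features.shape[:2]
    scale = as_tensor(style_scale)
    shift = as_tensor(style_shift)
    if scale.shape[-1] != c or shift.shape[-1] != c:
        raise ValueError(
            f"style parameter length {scale.shape[-1]}/{shift.shape[-1]} "
            f"does not match channel count {c}"
        )
    normed = instance_norm_2d(features, eps=eps)
    scale = scale.reshape((1, c, 1, 1) if scale.ndim == 1 else (n, c, 1, 1))
    shift = shift.reshape((1, c, 1, 1) if shift.ndim == 1 else (n, c, 1, 1))
    return normed * scale + shift


class Adam:
    """Adam optimiser (the image-translation default: lr 2e-4, betas .5/.999)."""

    def __init__(self, params: list[Parameter], lr: float = 2e-4,
                 betas: tuple[float, float] = (0.5, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr, self.betas, self.eps = lr, betas, eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.betas
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            self.m[i] = b1 * self.m[i] + (1 - b1) * p.grad
            self.v[i] = b2 * self.v[i] + (1 - b2) * p.grad**2
            mhat = self.m[i] / (1 - b1**self.t)
            vhat = self.v[i] / (1 - b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None
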