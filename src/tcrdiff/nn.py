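"""Neural-network layers and the Adam optimizer used by the denoiser and predictor.

Built on :mod:`tcrdiff._autograd`. Initialization follows the fan-in scaled
uniform scheme; all randomness flows through an explicit ``numpy.random.Generator``
so every construction and training run is seed-deterministic.
"""

from __future__ import annotations

import numpy as np

from ._autograd import Tensor, conv1d

__all__ = ["Module", "Linear", "Conv1d", "GroupNorm", "Dropout", "Adam"]


class Module:
    """Base class: parameter collection and train/eval mode propagation."""

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        for v in self.__dict__.values():
            if isinstance(v, Tensor) and v.requires_grad:
                params.append(v)
            elif isinstance(v, Module):
                params.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
        return params

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def state_arrays(self) -> list[np.ndarray]:
        return [p.data for p in self.parameters()]

    def load_state_arrays(self, arrays: list[np.ndarray]) -> None:
        params = self.parameters()
        if len(arrays) != len(params):
            raise ValueError(f"expected {len(params)} arrays, got {len(arrays)}")
        for p, a in zip(params, arrays):
            if p.data.shape != a.shape:
                raise ValueError(f"shape mismatch: {p.data.shape} vs {a.shape}")
            p.data = np.asarray(a, dtype=np.float64)


def _fan_in_uniform(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    bound = 1.0 / np.sqrt(fan_in)
    return rng.uniform(-bound, bound, size=shape)


class Linear(Module):
    """Affine layer; ``gain`` scales the init bound (√6 ≈ He-uniform, for
    deep SiLU stacks where the default fan-in bound attenuates the signal)."""

    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator,
                 gain: float = 1.0):
        self.in_features = in_features
        self.out_features = out_features
        self.weight = Tensor(gain * _fan_in_uniform(rng, (in_features, out_features), in_features), requires_grad=True)
        self.bias = Tensor(_fan_in_uniform(rng, (out_features,), in_features), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class Conv1d(Module):
    def __init__(self, in_ch: int, out_ch: int, kernel: int, rng: np.random.Generator,
                 stride: int = 1, pad: int | None = None):
        self.stride = stride
        self.pad = kernel // 2 if pad is None else pad
        fan_in = in_ch * kernel
        self.weight = Tensor(_fan_in_uniform(rng, (out_ch, in_ch, kernel), fan_in), requires_grad=True)
        self.bias = Tensor(_fan_in_uniform(rng, (out_ch,), fan_in), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return conv1d(x, self.weight, self.bias, stride=self.stride, pad=self.pad)


class GroupNorm(Module):
    """Group normalization over (channel-group, position) per sample."""

    def __init__(self, num_groups: int, num_channels: int, eps: float = 1e-5):
        if num_channels % num_groups:
            raise ValueError("channels must divide evenly into groups")
        self.groups = num_groups
        self.channels = num_channels
        self.eps = eps
        self.gamma = Tensor(np.ones(num_channels), requires_grad=True)
        self.beta = Tensor(np.zeros(num_channels), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        n, c, l = x.shape
        g = self.groups
        xg = x.reshape(n, g, (c // g) * l)
        mu = xg.mean(axis=2, keepdims=True)
        xc = xg - mu
        var = (xc ** 2.0).mean(axis=2, keepdims=True)
        normed = xc * (var + self.eps) ** -0.5
        out = normed.reshape(n, c, l)
        return out * self.gamma.reshape(1, c, 1) + self.beta.reshape(1, c, 1)


class Dropout(Module):
    """Inverted dropout; identity in eval mode."""

    def __init__(self, p: float):
        if not 0.0 <= p < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.p = p

    def __call__(self, x: Tensor, rng: np.random.Generator | None, train: bool) -> Tensor:
        if not train or self.p == 0.0:
            return x
        if rng is None:
            raise ValueError("training-mode dropout needs a Generator")
        mask = (rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * Tensor(mask)


class Adam:
    """Adam with the standard bias-corrected moment estimates."""

    def __init__(self, params: list[Tensor], lr: float = 1e-4,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
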