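"""Layers and optimizer built on the :mod:`piradscaps.autodiff` engine.

Only what the model needs: plain and depthwise-separable convolutions,
linear layers, a convolutional GRU cell, and Adam.  Parameters are
initialized from a caller-supplied :class:`numpy.random.Generator`, so a
model build is fully reproducible from one integer seed.
"""

from __future__ import annotations

import numpy as np

from piradscaps.autodiff import Tensor, concat


class Module:
    """Minimal parameter container with recursive discovery."""

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        for _, p in self.named_parameters():
            params.append(p)
        return params

    def named_parameters(self, prefix: str = "") -> list[tuple[str, Tensor]]:
        out: list[tuple[str, Tensor]] = []
        for name, val in vars(self).items():
            full = f"{prefix}{name}"
            if isinstance(val, Tensor) and val.requires_grad:
                out.append((full, val))
            elif isinstance(val, Module):
                out.extend(val.named_parameters(full + "."))
            elif isinstance(val, (list, tuple)):
                for i, item in enumerate(val):
                    if isinstance(item, Module):
                        out.extend(item.named_parameters(f"{full}.{i}."))
        return out

    def n_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self.named_parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        own = dict(self.named_parameters())
        missing = set(own) ^ set(state)
        if missing:
            raise KeyError(f"state dict mismatch on parameters: {sorted(missing)}")
        for k, p in own.items():
            if p.data.shape != state[k].shape:
                raise ValueError(f"shape mismatch for {k}: {p.data.shape} vs {state[k].shape}")
            p.data = state[k].astype(np.float32).copy()


def _he(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape).astype(np.float32)


class Conv2d(Module):
    def __init__(self, c_in: int, c_out: int, kernel: int, stride: int = 1,
                 padding: int = 0, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng()
        self.stride, self.padding = stride, padding
        self.weight = Tensor(_he(rng, (c_out, c_in, kernel, kernel), c_in * kernel * kernel),
                             requires_grad=True)
        self.bias = Tensor(np.zeros(c_out, np.float32), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x.conv2d(self.weight, self.bias, stride=self.stride, padding=self.padding)


class DepthwiseConv2d(Module):
    def __init__(self, channels: int, kernel: int, stride: int = 1,
                 padding: int = 0, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng()
        self.stride, self.padding = stride, padding
        self.weight = Tensor(_he(rng, (channels, kernel, kernel), kernel * kernel),
                             requires_grad=True)
        self.bias = Tensor(np.zeros(channels, np.float32), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x.depthwise_conv2d(self.weight, self.bias, stride=self.stride,
                                  padding=self.padding)


class SeparableConv2d(Module):
    """Depthwise k×k followed by pointwise 1×1 — the lightweight block."""

    def __init__(self, c_in: int, c_out: int, kernel: int, stride: int = 1,
                 padding: int = 0, rng: np.random.Generator | None = None):
        self.depthwise = DepthwiseConv2d(c_in, kernel, stride, padding, rng)
        self.pointwise = Conv2d(c_in, c_out, 1, rng=rng)

    def __call__(self, x: Tensor) -> Tensor:
        return self.pointwise(self.depthwise(x))


class Linear(Module):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng()
        self.weight = Tensor(_he(rng, (n_in, n_out), n_in), requires_grad=True)
        self.bias = Tensor(np.zeros(n_out, np.float32), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class ConvGRUCell(Module):
    """Gated recurrent update over spatial feature stacks.

    ``h_s = (1 - z) * h_{s-1} + z * tanh(Wh * [r * h_{s-1}, e_s])`` with
    update gate ``z`` and reset gate ``r`` computed by 3×3 convolutions of
    the concatenated previous state and current input.  State shape always
    equals input shape.
    """

    def __init__(self, channels: int, kernel: int = 3,
                 rng: np.random.Generator | None = None):
        pad = kernel // 2
        self.channels = channels
        self.update_gate = Conv2d(2 * channels, channels, kernel, padding=pad, rng=rng)
        self.reset_gate = Conv2d(2 * channels, channels, kernel, padding=pad, rng=rng)
        self.candidate = Conv2d(2 * channels, channels, kernel, padding=pad, rng=rng)

    def __call__(self, h: Tensor, e: Tensor) -> Tensor:
        if h.shape != e.shape:
            raise ValueError(f"GRU state/input shape mismatch: {h.shape} vs {e.shape}")
        he = concat([h, e], axis=1)
        z = self.update_gate(he).sigmoid()
        r = self.reset_gate(he).sigmoid()
        cand = self.candidate(concat([r * h, e], axis=1)).tanh()
        return (1.0 - z) * h + z * cand

    def init_state(self, like: Tensor) -> Tensor:
        return Tensor(np.zeros(like.shape, np.float32))


class Adam:
    """Adam with optional per-step learning-rate reassignment."""

    def __init__(self, params: list[Tensor], lr: float = 1e-3,
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
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m += (1.0 - self.b1) * (g - m)
            v += (1.0 - self.b2) * (g * g - v)
            p.data -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None
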