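"""Neural-network building blocks on top of the autodiff engine.

Layers hold :class:`~spike2image.autodiff.Tensor` parameters; modules are
composable via :class:`Sequential`.  Weight initialisation is Kaiming-uniform
(fan-in, LeakyReLU gain) and fully determined by the numpy Generator passed
to each constructor, so two models built from the same seed are bitwise
identical.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor, conv2d, conv_transpose2d

DTYPE = np.float32


def _kaiming_uniform(rng: np.random.Generator, shape, fan_in: int, slope: float = 0.2):
    gain = np.sqrt(2.0 / (1.0 + slope**2))
    bound = gain * np.sqrt(3.0 / fan_in)
    return rng.uniform(-bound, bound, size=shape).astype(DTYPE)


class Module:
    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        for attr in vars(self).values():
            if isinstance(attr, Tensor) and attr.requires_grad:
                params.append(attr)
            elif isinstance(attr, Module):
                params.extend(attr.parameters())
            elif isinstance(attr, (list, tuple)):
                for item in attr:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
        return params

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def train_mode(self, flag: bool = True) -> None:
        for attr in vars(self).values():
            if isinstance(attr, Module):
                attr.train_mode(flag)
            elif isinstance(attr, (list, tuple)):
                for item in attr:
                    if isinstance(item, Module):
                        item.train_mode(flag)
        if hasattr(self, "training"):
            self.training = flag

    def __call__(self, x: Tensor) -> Tensor:
        return self.forward(x)

    def forward(self, x: Tensor) -> Tensor:  # pragma: no cover - abstract
        raise NotImplementedError


class Linear(Module):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        self.weight = Tensor(
            _kaiming_uniform(rng, (n_in, n_out), fan_in=n_in), requires_grad=True
        )
        bound = 1.0 / np.sqrt(n_in)
        self.bias = Tensor(
            rng.uniform(-bound, bound, size=n_out).astype(DTYPE), requires_grad=True
        )

    def forward(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class Conv2d(Module):
    def __init__(
        self,
        in_ch: int,
        out_ch: int,
        ksize: int,
        stride: int,
        padding: int,
        rng: np.random.Generator,
        *,
        fixed_weight: np.ndarray | None = None,
    ):
        self.stride = stride
        self.padding = padding
        if fixed_weight is not None:
            self.weight = Tensor(fixed_weight.astype(DTYPE), requires_grad=False)
            self.bias = Tensor(np.zeros(out_ch, dtype=DTYPE), requires_grad=False)
        else:
            fan_in = in_ch * ksize * ksize
            self.weight = Tensor(
                _kaiming_uniform(rng, (out_ch, in_ch, ksize, ksize), fan_in),
                requires_grad=True,
            )
            bound = 1.0 / np.sqrt(fan_in)
            self.bias = Tensor(
                rng.uniform(-bound, bound, size=out_ch).astype(DTYPE),
                requires_grad=True,
            )

    def forward(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias, self.stride, self.padding)


class ConvTranspose2d(Module):
    def __init__(
        self,
        in_ch: int,
        out_ch: int,
        ksize: int,
        stride: int,
        padding: int,
        rng: np.random.Generator,
    ):
        self.stride = stride
        self.padding = padding
        fan_in = in_ch * ksize * ksize
        self.weight = Tensor(
            _kaiming_uniform(rng, (in_ch, out_ch, ksize, ksize), fan_in),
            requires_grad=True,
        )
        bound = 1.0 / np.sqrt(fan_in)
        self.bias = Tensor(
            rng.uniform(-bound, bound, size=out_ch).astype(DTYPE), requires_grad=True
        )

    def forward(self, x: Tensor) -> Tensor:
        return conv_transpose2d(x, self.weight, self.bias, self.stride, self.padding)


class LeakyReLU(Module):
    def __init__(self, slope: float = 0.2):
        self.slope = slope

    def forward(self, x: Tensor) -> Tensor:
        return x.leaky_relu(self.slope)


class Sigmoid(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.sigmoid()


class Dropout(Module):
    """Inverted dropout; identity in eval mode.

    Draws its masks from a Generator owned by the training loop so a full
    run is reproducible from one seed.
    """

    def __init__(self, p: float, rng: np.random.Generator):
        if not 0.0 <= p < 1.0:
            raise ValueError("dropout probability must be in [0, 1)")
        self.p = p
        self.rng = rng
        self.training = True

    def forward(self, x: Tensor) -> Tensor:
        if not self.training or self.p == 0.0:
            return x
        keep = 1.0 - self.p
        mask = (self.rng.random(x.shape) < keep).astype(x.data.dtype) / keep
        return x * Tensor(mask)


class Sequential(Module):
    def __init__(self, *mods: Module):
        self.mods = list(mods)

    def forward(self, x: Tensor) -> Tensor:
        for m in self.mods:
            x = m(x)
        return x


class Adam:
    """Adam optimizer with an externally settable learning rate."""

    def __init__(
        self,
        params: list[Tensor],
        lr: float,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
    ):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad.astype(p.data.dtype)
            m *= self.b1
            m += (1.0 - self.b1) * g
            v *= self.b2
            v += (1.0 - self.b2) * g * g
            p.data = p.data - self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
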