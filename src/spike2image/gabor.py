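"""Gabor kernels, filter banks, and the decoder's Gabor first layer.

A Gabor filter — a Gaussian envelope times a sinusoidal carrier — is the
canonical model of orientation- and frequency-tuned simple cells in primary
visual cortex.  Using a bank of them as the first convolution of the image
autoencoder biases the network toward the oriented, band-pass structure
those neurons report, without those filters having to be learned.

Kernels are DC-corrected (envelope-weighted mean subtracted) so a constant
input produces exactly zero response: luminance cannot leak into the
orientation channels.

Conventions: ``theta`` is the carrier axis measured from the x (column)
axis, rows increase downward; even (cosine) phase by default, so kernels
are pi-periodic in orientation and a bank spanning [0, pi) has no
duplicates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .layers import DTYPE, Conv2d, Module, Tensor


@dataclass(frozen=True)
class GaborParams:
    """One kernel: orientation, wavelength, phase, envelope scale/ellipticity."""

    theta: float
    wavelength_px: float
    phase: float = 0.0
    sigma_px: float = 2.0
    aspect: float = 0.5
    ksize: int = 9

    def __post_init__(self) -> None:
        if self.ksize % 2 == 0 or self.ksize <= 0:
            raise ValueError("ksize must be an odd positive integer")
        if self.wavelength_px < 2.0:
            raise ValueError("wavelength_px must be >= 2 (Nyquist)")
        if self.sigma_px <= 0 or self.aspect <= 0:
            raise ValueError("sigma_px and aspect must be positive")


def gabor_kernel(p: GaborParams) -> np.ndarray:
    """Real Gabor kernel, DC-corrected to zero sum."""
    r = (p.ksize - 1) / 2.0
    cols, rows = np.meshgrid(np.arange(p.ksize) - r, np.arange(p.ksize) - r)
    x, y = cols, rows
    xr = x * np.cos(p.theta) + y * np.sin(p.theta)
    yr = -x * np.sin(p.theta) + y * np.cos(p.theta)
    envelope = np.exp(-(xr**2 + (p.aspect * yr) ** 2) / (2.0 * p.sigma_px**2))
    carrier = np.cos(2.0 * np.pi * xr / p.wavelength_px + p.phase)
    kern = envelope * carrier
    # subtract envelope-weighted mean -> exact zero DC response
    kern = kern - envelope * (kern.sum() / envelope.sum())
    return kern


def default_wavelength(ksize: int) -> float:
    return max(ksize / 2.0, 2.0)


def default_sigma(wavelength_px: float) -> float:
    # ~1.5-octave bandwidth, typical of V1 simple cells
    return 0.56 * wavelength_px


@dataclass(frozen=True)
class GaborBank:
    """An ordered orientation x scale family of kernels."""

    params: tuple[GaborParams, ...]

    @property
    def kernels(self) -> list[np.ndarray]:
        return [gabor_kernel(p) for p in self.params]

    @property
    def orientations(self) -> list[float]:
        return sorted({p.theta for p in self.params})

    @property
    def scales(self) -> list[int]:
        return sorted({p.ksize for p in self.params})

    @property
    def max_ksize(self) -> int:
        return max(p.ksize for p in self.params)

    def __len__(self) -> int:
        return len(self.params)

    def stacked_kernels(self) -> np.ndarray:
        """(n_kernels, 1, K, K) array, smaller kernels zero-padded to K."""
        k = self.max_ksize
        out = np.zeros((len(self.params), 1, k, k))
        for i, kern in enumerate(self.kernels):
            pad = (k - kern.shape[0]) // 2
            out[i, 0, pad : pad + kern.shape[0], pad : pad + kern.shape[1]] = kern
        return out


def make_bank(
    orientation_step_deg: float = 30.0,
    ksizes: tuple[int, ...] = (7, 9, 11, 13),
    phase: float = 0.0,
    aspect: float = 0.5,
    wavelength_rule=default_wavelength,
    sigma_rule=default_sigma,
) -> GaborBank:
    """Orientations every ``orientation_step_deg`` over [0, 180) x one kernel
    per scale; the defaults give a 6-orientation x 4-scale, 24-kernel bank.
    """
    if orientation_step_deg <= 0 or 180.0 % orientation_step_deg != 0:
        raise ValueError("orientation_step_deg must divide 180")
    n_orient = int(round(180.0 / orientation_step_deg))
    thetas = [np.deg2rad(i * orientation_step_deg) for i in range(n_orient)]
    params = []
    for theta in thetas:
        for ksize in ksizes:
            lam = wavelength_rule(ksize)
            params.append(
                GaborParams(
                    theta=theta,
                    wavelength_px=lam,
                    phase=phase,
                    sigma_px=sigma_rule(lam),
                    aspect=aspect,
                    ksize=ksize,
                )
            )
    return GaborBank(tuple(params))


class GaborFixedConv(Module):
    """Non-trainable first convolution whose kernels are the Gabor bank."""

    def __init__(self, bank: GaborBank):
        if len(bank) == 0:
            raise ValueError("Gabor bank is empty")
        k = bank.max_ksize
        self.out_channels = len(bank)
        self.conv = Conv2d(
            1,
            len(bank),
            k,
            stride=1,
            padding=k // 2,
            rng=np.random.default_rng(0),
            fixed_weight=bank.stacked_kernels(),
        )

    def forward(self, x: Tensor) -> Tensor:
        return self.conv(x)


class GaborModulatedConv(Module):
    """Trainable kernels elementwise-modulated by the Gabor bank.

    Each of ``n_trainable`` learned kernels is multiplied by every bank
    kernel at forward time, giving ``n_trainable * len(bank)`` output
    channels whose oriented/band-pass structure is imposed by the bank while
    the amplitudes are learned.
    """

    def __init__(self, bank: GaborBank, n_trainable: int, rng: np.random.Generator):
        if len(bank) == 0:
            raise ValueError("Gabor bank is empty")
        k = bank.max_ksize
        self.bank_kernels = Tensor(bank.stacked_kernels().astype(DTYPE))
        self.n_trainable = n_trainable
        self.n_bank = len(bank)
        self.ksize = k
        self.out_channels = n_trainable * len(bank)
        scale = 1.0 / np.sqrt(k * k)
        self.weight = Tensor(
            rng.uniform(-scale, scale, size=(n_trainable, 1, 1, k, k)).astype(DTYPE),
            requires_grad=True,
        )
        self.bias = Tensor(np.zeros(self.out_channels, dtype=DTYPE), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        from .autodiff import conv2d

        bank = self.bank_kernels.reshape(1, self.n_bank, 1, self.ksize, self.ksize)
        eff = (self.weight * bank).reshape(
            self.out_channels, 1, self.ksize, self.ksize
        )
        return conv2d(x, eff, self.bias, stride=1, padding=self.ksize // 2)


def gabor_first_layer(
    bank: GaborBank,
    mode: str = "fixed",
    n_trainable: int = 1,
    rng: np.random.Generator | None = None,
) -> Module:
    """Build the first-convolution module for the decoder.

    ``fixed`` freezes the bank as the kernels; ``modulated`` multiplies
    trainable kernels by the bank each forward pass.
    """
    if mode == "fixed":
        return GaborFixedConv(bank)
    if mode == "modulated":
        return GaborModulatedConv(bank, n_trainable, rng or np.random.default_rng(0))
    raise ValueError(f"unknown Gabor layer mode {mode!r}")
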