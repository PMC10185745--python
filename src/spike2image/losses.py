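"""Training objectives for spike-to-image reconstruction.

The composite loss mixes a structural term with a receptive-field-weighted
pixel term:

    L = mu * L_SSIM + (1 - mu) * W-weighted MSE,      L_SSIM = -SSIM(x, y)

where ``W`` is the image-shaped receptive-field weight map and ``mu``
(default 0.1) balances structure against weighted pixel error.  ``mu = 0``
with uniform ``W`` is the plain-MSE ablation ("method 1"); ``mu = 1`` is the
pure SSIM ablation ("method 2").

Inside the loss, images are on the unit scale [0, 1] (the decoder's output
range), so the SSIM constants are computed with P = 1 and the two terms have
comparable magnitude; evaluation metrics are reported separately on the
0-255 scale.

Two call surfaces are provided: scalar functions on images/arrays (used for
evaluation and testing), and ``*_t`` functions on batched autodiff tensors
(used by the training loop; gradients flow through both terms).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .autodiff import Tensor
from .images import as_pixel_array, check_same_shape
from .metrics import MetricConstants
from .rf_weights import WeightMatrix

__all__ = [
    "LossConfig",
    "ssim_loss",
    "weighted_mse_loss",
    "combined_loss",
    "ssim_t",
    "ssim_loss_t",
    "weighted_mse_loss_t",
    "combined_loss_t",
]


@dataclass(frozen=True)
class LossConfig:
    """Mixing weight, SSIM variant, constants and spatial weights."""

    mu_mix: float = 0.1
    ssim_mode: str = "global"
    metric_constants: MetricConstants = field(
        default_factory=lambda: MetricConstants.for_range(1.0)
    )
    weight_matrix: WeightMatrix | None = None  # None -> uniform weights
    window_size: int = 11
    window_sigma: float = 1.5

    def __post_init__(self) -> None:
        if not 0.0 <= self.mu_mix <= 1.0:
            raise ValueError("mu_mix must lie in [0, 1]")
        if self.ssim_mode not in ("global", "windowed"):
            raise ValueError("ssim_mode must be 'global' or 'windowed'")


# -- differentiable (batched tensor) versions --------------------------------
#
# x, y are (N, 1, H, W); y may be a plain ndarray.


def _lift4(x) -> Tensor:
    t = x if isinstance(x, Tensor) else Tensor(np.asarray(x))
    if t.ndim == 2:
        t = t.reshape(1, 1, *t.shape)
    elif t.ndim == 3:
        t = t.reshape(t.shape[0], 1, t.shape[1], t.shape[2])
    return t


def _gaussian_window(size: int, sigma: float, dtype) -> np.ndarray:
    r = (size - 1) / 2.0
    g1 = np.exp(-((np.arange(size) - r) ** 2) / (2 * sigma**2))
    g2 = np.outer(g1, g1)
    return (g2 / g2.sum()).astype(dtype)


def ssim_t(x, y, cfg: LossConfig) -> Tensor:
    """Batch-mean SSIM as a differentiable scalar tensor.

    ``global`` mode uses whole-image moments (the printed-formula variant);
    ``windowed`` mode averages the SSIM map over valid Gaussian windows.
    """
    x4, y4 = _lift4(x), _lift4(y)
    c = cfg.metric_constants
    if cfg.ssim_mode == "global":
        ax = (2, 3)
        mx = x4.mean(axis=ax, keepdims=True)
        my = y4.mean(axis=ax, keepdims=True)
        vx = ((x4 - mx) ** 2).mean(axis=ax, keepdims=True)
        vy = ((y4 - my) ** 2).mean(axis=ax, keepdims=True)
        cov = ((x4 - mx) * (y4 - my)).mean(axis=ax, keepdims=True)
        num = (2.0 * mx * my + c.c1) * (2.0 * cov + c.c2)
        den = (mx**2 + my**2 + c.c1) * (vx + vy + c.c2)
        return (num / den).mean()

    from .autodiff import conv2d

    win = _gaussian_window(cfg.window_size, cfg.window_sigma, np.float64)
    wt = Tensor(win[None, None])
    zero = Tensor(np.zeros(1))

    def smooth(t: Tensor) -> Tensor:
        return conv2d(t, wt, zero, stride=1, padding=0)

    ux, uy = smooth(x4), smooth(y4)
    vx = smooth(x4 * x4) - ux * ux
    vy = smooth(y4 * y4) - uy * uy
    cov = smooth(x4 * y4) - ux * uy
    num = (2.0 * ux * uy + c.c1) * (2.0 * cov + c.c2)
    den = (ux**2 + uy**2 + c.c1) * (vx + vy + c.c2)
    return (num / den).mean()


def ssim_loss_t(x, y, cfg: LossConfig) -> Tensor:
    return -ssim_t(x, y, cfg)


def weighted_mse_loss_t(x, y, cfg: LossConfig) -> Tensor:
    """Batch mean of (1/(H W)) sum_ij W_ij (x_ij - y_ij)^2."""
    x4, y4 = _lift4(x), _lift4(y)
    diff2 = (x4 - y4) ** 2
    if cfg.weight_matrix is not None:
        w = cfg.weight_matrix.weights
        if w.shape != x4.shape[-2:]:
            raise ValueError(
                f"weight matrix shape {w.shape} does not match image "
                f"shape {x4.shape[-2:]}"
            )
        # match the image dtype so uniform weights are a bitwise no-op
        diff2 = diff2 * Tensor(w[None, None].astype(diff2.data.dtype, copy=False))
    return diff2.mean()


def combined_loss_t(x, y, cfg: LossConfig) -> Tensor:
    """mu * (-SSIM) + (1 - mu) * weighted MSE, differentiable."""
    mu = cfg.mu_mix
    wmse = weighted_mse_loss_t(x, y, cfg)
    if mu == 0.0:
        return wmse
    ls = ssim_loss_t(x, y, cfg)
    if mu == 1.0:
        return ls
    return mu * ls + (1.0 - mu) * wmse


# -- scalar (evaluation/test) surface ----------------------------------------


def _default_cfg(x) -> LossConfig:
    from .images import range_of

    return LossConfig(metric_constants=MetricConstants.for_range(range_of(x, 1.0)))


def ssim_loss(x, y, cfg: LossConfig | None = None) -> float:
    """Negative SSIM of one image pair, in [-1, 1]; -1 iff identical."""
    check_same_shape(x, y)
    cfg = cfg or _default_cfg(x)
    return float(ssim_loss_t(as_pixel_array(x), as_pixel_array(y), cfg).item())


def weighted_mse_loss(x, y, w: "WeightMatrix | np.ndarray | None" = None) -> float:
    """Spatially weighted mean squared error of one image pair."""
    check_same_shape(x, y)
    if w is not None and not isinstance(w, WeightMatrix):
        w = WeightMatrix(np.asarray(w, dtype=np.float64), normalized=False)
    cfg = LossConfig(weight_matrix=w)
    return float(weighted_mse_loss_t(as_pixel_array(x), as_pixel_array(y), cfg).item())


def combined_loss(x, y, cfg: LossConfig | None = None) -> float:
    """The composite objective for one image pair."""
    check_same_shape(x, y)
    cfg = cfg or _default_cfg(x)
    return float(combined_loss_t(as_pixel_array(x), as_pixel_array(y), cfg).item())
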