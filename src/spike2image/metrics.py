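"""Image-quality metrics: MSE, PSNR, SSIM (global and windowed) and VIFP.

These four measures form the evaluation protocol for spike-train image
reconstruction and the SSIM additionally feeds the training loss.  Two SSIM
variants are provided:

``ssim_global``
    The single-window form computed from whole-image means, standard
    deviations and covariance.  This is the quantity the composite loss uses.
``ssim_windowed``
    The conventional mean-of-local-windows SSIM with an 11x11 Gaussian
    (sigma = 1.5) window and population-weighted local statistics, matching
    the original Wang et al. formulation (and therefore reference
    implementations such as scikit-image with ``gaussian_weights=True``).

VIFP is the pixel-domain visual information fidelity: a multi-scale,
Gaussian-window, additive-noise channel model in which the metric is the
ratio of the information the distorted image retains about the (modelled)
source to the information the reference image carries.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter

from .images import GrayImage, as_pixel_array, check_same_shape, range_of

__all__ = [
    "MetricConstants",
    "ImagePairStats",
    "mse",
    "psnr",
    "pair_stats",
    "ssim_components",
    "ssim_global",
    "ssim_windowed",
    "vifp",
    "metric_report",
]


@dataclass(frozen=True)
class MetricConstants:
    """Stabilising constants and exponents of the SSIM family.

    ``c1 = (k1 P)^2`` and ``c2 = (k2 P)^2`` guard the luminance and contrast
    terms against division by zero; ``c3 = c2 / 2`` so that the three-factor
    product collapses to the familiar two-factor SSIM formula.  The exponents
    ``alpha``, ``beta``, ``gamma_exp`` weight luminance, contrast and
    structure and default to 1.
    """

    k1: float = 0.01
    k2: float = 0.03
    range_max: float = 255.0
    alpha: float = 1.0
    beta: float = 1.0
    gamma_exp: float = 1.0

    @property
    def c1(self) -> float:
        return (self.k1 * self.range_max) ** 2

    @property
    def c2(self) -> float:
        return (self.k2 * self.range_max) ** 2

    @property
    def c3(self) -> float:
        return self.c2 / 2.0

    @classmethod
    def for_range(cls, range_max: float, **kw) -> "MetricConstants":
        return cls(range_max=range_max, **kw)


@dataclass(frozen=True)
class ImagePairStats:
    """Whole-image first and second moments of an image pair."""

    mean_x: float
    mean_y: float
    std_x: float
    std_y: float
    cov_xy: float


def mse(x, y, reduction: str = "mean") -> float:
    """Mean (or summed) squared pixel difference.

    ``reduction="mean"`` divides by the pixel count; ``"sum"`` totals the
    per-pixel squared differences, the convention used when reporting
    reconstruction error summed over all pixels.
    """
    check_same_shape(x, y)
    diff = as_pixel_array(x) - as_pixel_array(y)
    sq = diff * diff
    if reduction == "mean":
        return float(sq.mean())
    if reduction == "sum":
        return float(sq.sum())
    raise ValueError(f"unknown reduction {reduction!r}; use 'mean' or 'sum'")


def psnr(x, y, range_max: float | None = None) -> float:
    """Peak signal-to-noise ratio, ``10 log10(P^2 / MSE)`` in dB.

    Identical images give ``+inf`` rather than raising, so batch evaluation
    stays total.
    """
    check_same_shape(x, y)
    if range_max is None:
        range_max = range_of(x)
    err = mse(x, y, reduction="mean")
    if err == 0.0:
        return float("inf")
    return float(10.0 * np.log10(range_max**2 / err))


def pair_stats(x, y) -> ImagePairStats:
    """Global (whole-image, population-denominator) moments of a pair."""
    check_same_shape(x, y)
    ax, ay = as_pixel_array(x), as_pixel_array(y)
    mx, my = float(ax.mean()), float(ay.mean())
    vx = float(((ax - mx) ** 2).mean())
    vy = float(((ay - my) ** 2).mean())
    cov = float(((ax - mx) * (ay - my)).mean())
    return ImagePairStats(mx, my, np.sqrt(vx), np.sqrt(vy), cov)


def ssim_components(
    stats: ImagePairStats, consts: MetricConstants
) -> tuple[float, float, float]:
    """Luminance, contrast and structure comparison factors.

    l = (2 mu_x mu_y + c1) / (mu_x^2 + mu_y^2 + c1)
    c = (2 sigma_x sigma_y + c2) / (sigma_x^2 + sigma_y^2 + c2)
    s = (sigma_xy + c3) / (sigma_x sigma_y + c3)
    """
    mx, my = stats.mean_x, stats.mean_y
    sx, sy = stats.std_x, stats.std_y
    lum = (2 * mx * my + consts.c1) / (mx**2 + my**2 + consts.c1)
    con = (2 * sx * sy + consts.c2) / (sx**2 + sy**2 + consts.c2)
    struct = (stats.cov_xy + consts.c3) / (sx * sy + consts.c3)
    return float(lum), float(con), float(struct)


def ssim_global(x, y, consts: MetricConstants | None = None) -> float:
    """Single-window SSIM from whole-image statistics.

    With unit exponents this equals
    ``(2 mu_x mu_y + c1)(2 sigma_xy + c2) /
    ((mu_x^2 + mu_y^2 + c1)(sigma_x^2 + sigma_y^2 + c2))``.
    """
    check_same_shape(x, y)
    if consts is None:
        consts = MetricConstants.for_range(range_of(x))
    stats = pair_stats(x, y)
    lum, con, struct = ssim_components(stats, consts)
    return float(
        np.sign(lum) * abs(lum) ** consts.alpha
        * np.sign(con) * abs(con) ** consts.beta
        * np.sign(struct) * abs(struct) ** consts.gamma_exp
    )


def ssim_windowed(
    x,
    y,
    consts: MetricConstants | None = None,
    window_size: int = 11,
    window_sigma: float = 1.5,
) -> float:
    """Mean local SSIM over Gaussian-weighted sliding windows.

    Local means/variances/covariance are computed with a reflected-boundary
    Gaussian filter of the given size and width; a border of half the window
    is cropped before averaging, matching standard practice.
    """
    check_same_shape(x, y)
    ax, ay = as_pixel_array(x), as_pixel_array(y)
    if window_size % 2 != 1:
        raise ValueError("window_size must be odd")
    if window_size > min(ax.shape):
        raise ValueError(
            f"window_size {window_size} exceeds image extent {ax.shape}"
        )
    if consts is None:
        consts = MetricConstants.for_range(range_of(x))

    pad = (window_size - 1) // 2
    # truncate chosen so the ndimage kernel radius equals the window radius
    truncate = (pad + 0.4) / window_sigma

    def smooth(a):
        return gaussian_filter(a, sigma=window_sigma, truncate=truncate, mode="reflect")

    ux, uy = smooth(ax), smooth(ay)
    uxx, uyy, uxy = smooth(ax * ax), smooth(ay * ay), smooth(ax * ay)
    vx = uxx - ux * ux
    vy = uyy - uy * uy
    vxy = uxy - ux * uy

    c1, c2 = consts.c1, consts.c2
    num = (2 * ux * uy + c1) * (2 * vxy + c2)
    den = (ux**2 + uy**2 + c1) * (vx + vy + c2)
    smap = num / den
    interior = smap[pad:-pad, pad:-pad] if pad > 0 else smap
    return float(interior.mean())


def _vifp_scale_windows(scale: int, n_scales: int) -> tuple[int, float]:
    # canonical ladder 17/9/5/3 at 4 scales; smaller ladders for small images
    size = 2 ** (n_scales + 1 - scale) + 1
    return size, size / 5.0


def max_vifp_scales(shape: tuple[int, int], limit: int = 4) -> int:
    """Largest scale count whose Gaussian windows fit the image."""
    short = min(shape)
    for n in range(limit, 0, -1):
        if 2**n + 1 <= short and short // 2 ** (n - 1) >= 3:
            return n
    raise ValueError(f"image too small for VIFP at any scale: {shape}")


def vifp(
    ref,
    dist,
    n_scales: int | None = None,
    sigma_nsq: float = 2.0,
) -> float:
    """Pixel-domain visual information fidelity.

    At each of ``n_scales`` dyadic scales, local Gaussian statistics give a
    per-pixel gain ``g`` and residual variance for a signal-attenuation +
    additive-noise model of the distortion; the metric is the ratio of
    summed log-information in the distorted image to that in the reference.
    A perfect copy scores 1; information-destroying distortions approach 0.
    """
    check_same_shape(ref, dist)
    r = as_pixel_array(ref).astype(np.float64)
    d = as_pixel_array(dist).astype(np.float64)
    if n_scales is None:
        n_scales = max_vifp_scales(r.shape)

    num = 0.0
    den = 0.0
    for scale in range(1, n_scales + 1):
        size, sigma = _vifp_scale_windows(scale, n_scales)
        if min(r.shape) < size:
            raise ValueError(
                f"image too small for VIFP scale {scale}: needs at least "
                f"{size} pixels per side, got {r.shape}"
            )
        if scale > 1:
            r = gaussian_filter(r, sigma=sigma)[::2, ::2]
            d = gaussian_filter(d, sigma=sigma)[::2, ::2]
            if min(r.shape) < size:
                raise ValueError(
                    f"image too small for VIFP scale {scale} after downsampling"
                )

        mu1 = gaussian_filter(r, sigma=sigma)
        mu2 = gaussian_filter(d, sigma=sigma)
        sigma1_sq = gaussian_filter(r * r, sigma=sigma) - mu1 * mu1
        sigma2_sq = gaussian_filter(d * d, sigma=sigma) - mu2 * mu2
        sigma12 = gaussian_filter(r * d, sigma=sigma) - mu1 * mu2

        sigma1_sq = np.maximum(sigma1_sq, 0.0)
        sigma2_sq = np.maximum(sigma2_sq, 0.0)

        g = sigma12 / (sigma1_sq + 1e-10)
        sv_sq = sigma2_sq - g * sigma12

        g = np.where(sigma1_sq < 1e-10, 0.0, g)
        sv_sq = np.where(sigma1_sq < 1e-10, sigma2_sq, sv_sq)
        sv_sq = np.where(sigma2_sq < 1e-10, 0.0, sv_sq)
        g = np.where(sigma2_sq < 1e-10, 0.0, g)
        sv_sq = np.where(g < 0.0, sigma2_sq, sv_sq)
        g = np.maximum(g, 0.0)
        sv_sq = np.maximum(sv_sq, 1e-10)

        num += float(np.log10(1.0 + g * g * sigma1_sq / (sv_sq + sigma_nsq)).sum())
        den += float(np.log10(1.0 + sigma1_sq / sigma_nsq).sum())

    if den == 0.0:
        return 1.0 if num == 0.0 else 0.0
    return float(num / den)


def metric_report(
    reference,
    reconstruction,
    range_max: float | None = None,
) -> dict[str, float]:
    """All four metrics of the evaluation protocol for one image pair.

    Returns a JSON-ready record with both MSE conventions, PSNR in dB,
    windowed SSIM and VIFP.
    """
    if range_max is None:
        range_max = range_of(reference)
    consts = MetricConstants.for_range(range_max)
    return {
        "mse": mse(reference, reconstruction, reduction="mean"),
        "mse_sum": mse(reference, reconstruction, reduction="sum"),
        "psnr_db": psnr(reference, reconstruction, range_max=range_max),
        "ssim": ssim_windowed(reference, reconstruction, consts),
        "vifp": vifp(reference, reconstruction),
    }
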