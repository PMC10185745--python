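"""Grayscale image container and I/O helpers.

All decoding, loss and metric code in this package operates on single-channel
images.  :class:`GrayImage` is a thin wrapper around a 2D float array that
carries the one piece of metadata the metrics need: the maximum representable
intensity ``range_max`` (the ``P`` in the PSNR definition).  Images loaded
from 8-bit files get ``range_max=255``; unit-scaled tensors produced by the
decoder get ``range_max=1``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from PIL import Image


@dataclass(frozen=True)
class GrayImage:
    """A 2D grayscale image with a known intensity range.

    Parameters
    ----------
    pixels
        2D array of intensities in ``[0, range_max]``.
    range_max
        Maximum representable intensity ``P`` (255 for 8-bit data,
        1.0 for unit-scaled arrays).
    """

    pixels: np.ndarray
    range_max: float = 255.0

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=np.float64)
        if px.ndim != 2 or px.shape[0] < 1 or px.shape[1] < 1:
            raise ValueError(f"GrayImage requires a 2D array, got shape {px.shape}")
        if self.range_max <= 0:
            raise ValueError("range_max must be positive")
        object.__setattr__(self, "pixels", px)

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    @classmethod
    def from_uint8(cls, arr: np.ndarray) -> "GrayImage":
        return cls(np.asarray(arr, dtype=np.float64), range_max=255.0)

    @classmethod
    def from_unit(cls, arr: np.ndarray) -> "GrayImage":
        return cls(np.asarray(arr, dtype=np.float64), range_max=1.0)

    def to_uint8(self) -> np.ndarray:
        scaled = self.pixels * (255.0 / self.range_max)
        return np.clip(np.rint(scaled), 0, 255).astype(np.uint8)

    def to_unit(self) -> np.ndarray:
        """Pixels rescaled to [0, 1]."""
        return self.pixels / self.range_max

    def rescaled(self, range_max: float) -> "GrayImage":
        return GrayImage(self.pixels * (range_max / self.range_max), range_max)


def as_pixel_array(img: "GrayImage | np.ndarray") -> np.ndarray:
    """Accept either a GrayImage or a bare 2D array; return float64 pixels."""
    if isinstance(img, GrayImage):
        return img.pixels
    arr = np.asarray(img, dtype=np.float64)
    if arr.ndim != 2:
        raise ValueError(f"expected a 2D image array, got shape {arr.shape}")
    return arr


def range_of(img: "GrayImage | np.ndarray", default: float = 255.0) -> float:
    return img.range_max if isinstance(img, GrayImage) else default


def check_same_shape(x: "GrayImage | np.ndarray", y: "GrayImage | np.ndarray") -> None:
    ax, ay = as_pixel_array(x), as_pixel_array(y)
    if ax.shape != ay.shape:
        raise ValueError(f"image shapes differ: {ax.shape} vs {ay.shape}")


def load_png(path) -> GrayImage:
    """Load an image file as 8-bit grayscale."""
    with Image.open(path) as im:
        return GrayImage.from_uint8(np.asarray(im.convert("L")))


def save_png(img: GrayImage, path) -> None:
    Image.fromarray(img.to_uint8(), mode="L").save(path)


def resize_gray(img: GrayImage, shape: tuple[int, int]) -> GrayImage:
    """Deterministic resize; area (box) interpolation, suited to downscaling."""
    rows, cols = shape
    pil = Image.fromarray(img.to_uint8(), mode="L")
    out = pil.resize((cols, rows), Image.BOX)
    return GrayImage.from_uint8(np.asarray(out))
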