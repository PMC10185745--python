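"""Receptive-field-derived spatial weight matrices for the reconstruction loss.

Each recorded neuron reports stimulus contrast from a localised region of
visual space (its receptive field, RF).  Pixels covered by many RFs are
well constrained by the population response, pixels covered by none are
essentially unobserved.  The weight matrix ``W`` encodes this: a Gaussian
bump of unit peak amplitude is placed at every RF centre and the bumps are
summed, so overlapping RFs add up and the reconstruction error is weighted
most heavily where the recording actually carries information.

Coordinates are 0-based pixels, row 0 at the top; centres may be fractional
and may lie outside the image (the kernel is then truncated at the border).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np
import pandas as pd


class Polarity(enum.Enum):
    ON = "ON"
    OFF = "OFF"
    UNSPECIFIED = "unspecified"


@dataclass(frozen=True)
class ReceptiveFieldSpec:
    """Centre, spatial scale and polarity of one neuron's receptive field."""

    center_row: float
    center_col: float
    sigma_px: float
    polarity: Polarity = Polarity.UNSPECIFIED

    def __post_init__(self) -> None:
        if self.sigma_px <= 0:
            raise ValueError("sigma_px must be positive")


@dataclass(frozen=True)
class WeightMatrix:
    """Image-shaped nonnegative loss weights; mean 1 when normalized."""

    weights: np.ndarray
    normalized: bool

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=np.float64)
        if w.ndim != 2:
            raise ValueError("weight matrix must be 2D")
        if (w < 0).any():
            raise ValueError("weight matrix entries must be nonnegative")
        object.__setattr__(self, "weights", w)

    @property
    def shape(self) -> tuple[int, int]:
        return self.weights.shape

    @classmethod
    def uniform(cls, shape: tuple[int, int]) -> "WeightMatrix":
        return cls(np.ones(shape), normalized=True)


def default_sigma_px(image_shape: tuple[int, int]) -> float:
    """Fallback RF spread when the data give positions but not sizes."""
    return min(image_shape) / 8.0


def gaussian_kernel_2d(
    shape: tuple[int, int],
    center: tuple[float, float],
    sigma_px: float,
) -> np.ndarray:
    """Unnormalised isotropic Gaussian, peak value 1 at an on-grid centre."""
    if sigma_px <= 0:
        raise ValueError("sigma_px must be positive")
    rows, cols = shape
    r0, c0 = center
    rr = np.arange(rows, dtype=np.float64)[:, None] - r0
    cc = np.arange(cols, dtype=np.float64)[None, :] - c0
    return np.exp(-(rr**2 + cc**2) / (2.0 * sigma_px**2))


def build_weight_matrix(
    rfs: list[ReceptiveFieldSpec],
    shape: tuple[int, int],
    normalize: bool = True,
) -> WeightMatrix:
    """Sum unit-peak Gaussians at the RF centres; optionally rescale to mean 1.

    Overlapping receptive fields add, so the weight is larger wherever more
    neurons observe the image.  An empty RF list yields the uniform matrix,
    under which the weighted squared error reduces to the plain one.
    """
    if not rfs:
        return WeightMatrix.uniform(shape)
    w = np.zeros(shape, dtype=np.float64)
    for rf in rfs:
        w += gaussian_kernel_2d(shape, (rf.center_row, rf.center_col), rf.sigma_px)
    if normalize:
        w = w / w.mean()
    return WeightMatrix(w, normalized=normalize)


def rf_centers_from_table(
    table: pd.DataFrame,
    image_shape: tuple[int, int],
    coordinate_mode: str = "pixel",
    pixels_per_degree: float | None = None,
    sigma_px: float | None = None,
) -> list[ReceptiveFieldSpec]:
    """Convert a per-neuron RF table to pixel-space specs.

    ``pixel`` mode expects columns ``row``, ``col`` (0-based pixels).
    ``degrees_with_scale`` mode expects ``deg_x``, ``deg_y`` relative to the
    image centre (x rightward, y upward) plus ``pixels_per_degree``; (0, 0)
    degrees maps to the image-centre pixel.  An optional ``sigma_px`` column
    overrides the per-call or default RF spread, and an optional ``polarity``
    column ("ON"/"OFF") is carried through.
    """
    if sigma_px is None:
        sigma_px = default_sigma_px(image_shape)
    rows, cols = image_shape
    specs: list[ReceptiveFieldSpec] = []
    for _, rec in table.iterrows():
        if coordinate_mode == "pixel":
            r, c = float(rec["row"]), float(rec["col"])
        elif coordinate_mode == "degrees_with_scale":
            if pixels_per_degree is None:
                raise ValueError(
                    "degrees_with_scale mode requires pixels_per_degree"
                )
            center_r = (rows - 1) / 2.0
            center_c = (cols - 1) / 2.0
            # y in degrees points up; image rows grow downward
            r = center_r - float(rec["deg_y"]) * pixels_per_degree
            c = center_c + float(rec["deg_x"]) * pixels_per_degree
        else:
            raise ValueError(f"unknown coordinate_mode {coordinate_mode!r}")
        sig = float(rec["sigma_px"]) if "sigma_px" in rec.index else sigma_px
        pol = (
            Polarity(rec["polarity"])
            if "polarity" in rec.index and pd.notna(rec["polarity"])
            else Polarity.UNSPECIFIED
        )
        specs.append(ReceptiveFieldSpec(r, c, sig, pol))
    return specs


def load_rf_csv(
    path,
    image_shape: tuple[int, int],
    coordinate_mode: str = "pixel",
    pixels_per_degree: float | None = None,
) -> list[ReceptiveFieldSpec]:
    """Read an RF-centre CSV (columns per :func:`rf_centers_from_table`)."""
    return rf_centers_from_table(
        pd.read_csv(path), image_shape, coordinate_mode, pixels_per_degree
    )


def save_rf_csv(rfs: list[ReceptiveFieldSpec], path) -> None:
    pd.DataFrame(
        {
            "neuron_id": np.arange(len(rfs)),
            "row": [rf.center_row for rf in rfs],
            "col": [rf.center_col for rf in rfs],
            "sigma_px": [rf.sigma_px for rf in rfs],
            "polarity": [rf.polarity.value for rf in rfs],
        }
    ).to_csv(path, index=False)
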