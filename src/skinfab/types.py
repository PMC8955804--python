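"""Core containers shared across the pipeline.

All rasters are row-major ``(height, width[, channels])`` float arrays with the
origin at the top-left and 0-based indices. Reflectance lives in ``(0, 1]``;
optical density is ``-log(reflectance)``, the space in which the two-pigment
skin model is linear.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Reflectance floor applied before any log transform (16-bit quantisation step).
EPSILON: float = 2.0 ** -16


def clamp_reflectance(rgb: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Clamp reflectance into ``[EPSILON, 1]``; return (clamped, was-clamped mask)."""
    clamped = np.clip(rgb, EPSILON, 1.0)
    mask = np.any(rgb != clamped, axis=-1) if rgb.ndim == 3 else (rgb != clamped)
    return clamped, mask


@dataclass
class PigmentBasis:
    """Melanin/hemoglobin absorbance geometry of the two-pigment skin model.

    Parameters
    ----------
    melanin_vector, hemoglobin_vector
        Optical density per unit concentration for the R, G, B channels.
        Absorbers only: components must be non-negative.
    illumination_direction
        Unit direction along which shading (illumination intensity) acts in
        density space; ``(1,1,1)/sqrt(3)`` by default.
    bias
        Baseline optical density — the stationary part of skin colour.
    """

    melanin_vector: np.ndarray
    hemoglobin_vector: np.ndarray
    illumination_direction: np.ndarray = field(
        default_factory=lambda: np.ones(3) / np.sqrt(3.0)
    )
    bias: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.melanin_vector = np.asarray(self.melanin_vector, dtype=float)
        self.hemoglobin_vector = np.asarray(self.hemoglobin_vector, dtype=float)
        self.illumination_direction = np.asarray(
            self.illumination_direction, dtype=float
        )
        self.bias = np.asarray(self.bias, dtype=float)
        for name in ("melanin_vector", "hemoglobin_vector",
                     "illumination_direction", "bias"):
            if getattr(self, name).shape != (3,):
                raise ValueError(f"{name} must be a 3-vector")
        for name in ("melanin_vector", "hemoglobin_vector"):
            v = getattr(self, name)
            if np.any(v < -1e-9):
                raise ValueError(
                    f"{name} has negative components {v}; pigments only absorb"
                )
            setattr(self, name, np.clip(v, 0.0, None))
        n = np.linalg.norm(self.illumination_direction)
        if n == 0:
            raise ValueError("illumination_direction must be non-zero")
        self.illumination_direction = self.illumination_direction / n
        if self.angle_between() <= 1e-6:
            raise ValueError(
                "melanin and hemoglobin vectors are (near-)parallel: "
                f"angle {self.angle_between():.2e} rad"
            )

    def angle_between(self) -> float:
        """Angle in radians between the two pigment vectors."""
        a, b = self.melanin_vector, self.hemoglobin_vector
        c = np.dot(a, b) / (np.linalg.norm(a) * np.linalg.norm(b))
        return float(np.arccos(np.clip(c, -1.0, 1.0)))


@dataclass
class ConcentrationMap:
    """Per-pixel melanin, hemoglobin and shading fields.

    ``melanin`` and ``hemoglobin`` are unitless relative concentrations;
    ``shading`` is the signed log-intensity offset along the illumination
    direction (positive = brighter).
    """

    melanin: np.ndarray
    hemoglobin: np.ndarray
    shading: np.ndarray

    def __post_init__(self) -> None:
        self.melanin = np.asarray(self.melanin, dtype=float)
        self.hemoglobin = np.asarray(self.hemoglobin, dtype=float)
        self.shading = np.asarray(self.shading, dtype=float)
        shapes = {
            "melanin": self.melanin.shape,
            "hemoglobin": self.hemoglobin.shape,
            "shading": self.shading.shape,
        }
        if len(set(shapes.values())) != 1:
            raise ValueError(f"concentration fields differ in shape: {shapes}")
        if self.melanin.ndim != 2:
            raise ValueError("concentration fields must be 2-D")
        for name in ("melanin", "hemoglobin", "shading"):
            if not np.all(np.isfinite(getattr(self, name))):
                raise ValueError(f"{name} field contains non-finite values")

    @property
    def height(self) -> int:
        return self.melanin.shape[0]

    @property
    def width(self) -> int:
        return self.melanin.shape[1]


@dataclass
class SkinImage:
    """Linear-reflectance RGB raster in ``(0, 1]``.

    ``provenance`` records how the raster was obtained (``captured``,
    ``rendered`` or ``flat-fielded``); ``clamp_mask`` flags pixels that hit the
    reflectance floor or ceiling so round-trip checks can exclude them.
    """

    rgb: np.ndarray
    provenance: str = "captured"
    clamp_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.rgb = np.asarray(self.rgb, dtype=float)
        if self.rgb.ndim != 3 or self.rgb.shape[-1] != 3:
            raise ValueError("rgb must have shape (height, width, 3)")
        clamped, mask = clamp_reflectance(self.rgb)
        if self.clamp_mask is None:
            self.clamp_mask = mask
        self.rgb = clamped

    @property
    def height(self) -> int:
        return self.rgb.shape[0]

    @property
    def width(self) -> int:
        return self.rgb.shape[1]

    def density(self) -> np.ndarray:
        """Optical density ``-log(reflectance)``, shape ``(H, W, 3)``."""
        return -np.log(self.rgb)
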