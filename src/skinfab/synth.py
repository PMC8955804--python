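"""Forward optical model and synthetic fixtures.

Renders RGB skin images from known melanin/hemoglobin concentration maps under
the log-linear (modified Lambert-Beer) model, adds sensor noise, simulates the
print-and-capture loop for calibration patches, and generates phantom
concentration maps — so the separation and calibration stages are testable
without a camera or a printer.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .types import EPSILON, ConcentrationMap, PigmentBasis, SkinImage

#: Plausible absorbance shapes for fixtures only — hemoglobin absorbs green
#: most, melanin rises toward blue. Nothing downstream depends on these
#: numbers; recovery tests compare against whatever basis was actually used.
DEFAULT_MELANIN_VECTOR = np.array([0.74, 0.90, 1.10])
DEFAULT_HEMOGLOBIN_VECTOR = np.array([0.40, 1.10, 0.75])
DEFAULT_BIAS = np.array([0.18, 0.22, 0.25])


def default_basis() -> PigmentBasis:
    """Fixture pigment basis with the default absorbance shapes."""
    return PigmentBasis(
        melanin_vector=DEFAULT_MELANIN_VECTOR.copy(),
        hemoglobin_vector=DEFAULT_HEMOGLOBIN_VECTOR.copy(),
        bias=DEFAULT_BIAS.copy(),
    )


def render_skin(conc: ConcentrationMap, basis: PigmentBasis) -> SkinImage:
    """Render a linear-RGB skin image from concentration fields.

    Per pixel and channel ``c``::

        rgb_c = exp(-(mel * mel_vec_c + hem * hem_vec_c + bias_c)
                    + shading * illum_c)

    then clamped to ``[EPSILON, 1]``. Deterministic.
    """
    density = (
        conc.melanin[..., None] * basis.melanin_vector
        + conc.hemoglobin[..., None] * basis.hemoglobin_vector
        + basis.bias
    )
    log_reflectance = -density + conc.shading[..., None] * basis.illumination_direction
    return SkinImage(rgb=np.exp(log_reflectance), provenance="rendered")


def add_sensor_noise(img: SkinImage, sigma: float, seed: int) -> SkinImage:
    """Add i.i.d. Gaussian sensor noise (std ``sigma`` in reflectance units).

    ``sigma=0`` returns the input values bit-for-bit; identical seeds give
    identical outputs.
    """
    if sigma < 0:
        raise ValueError(f"noise sigma must be >= 0, got {sigma}")
    if sigma == 0:
        return SkinImage(rgb=img.rgb.copy(), provenance=img.provenance)
    rng = np.random.default_rng(seed)
    noisy = img.rgb + rng.normal(0.0, sigma, size=img.rgb.shape)
    return SkinImage(rgb=noisy, provenance=img.provenance)


@dataclass
class VirtualPress:
    """Layered-transmittance stand-in for printing and photographing a patch.

    Each ink channel contributes optical density proportional to its coverage;
    light crosses the melanin layer, then the hemoglobin layer, reflects off an
    ideal white layer and crosses both again. The deeper hemoglobin layer is
    down-weighted (``layer_weights``) to mimic partial masking by scattering,
    which also keeps the patch-grid -> RGB map injective.

    ``ink_density`` rows are the R,G,B densities of full-coverage C, M, Y, K.
    """

    ink_density: np.ndarray = field(
        default_factory=lambda: np.array(
            [
                [1.50, 0.30, 0.10],  # cyan absorbs red
                [0.20, 1.50, 0.25],  # magenta absorbs green
                [0.05, 0.30, 1.20],  # yellow absorbs blue
                [1.60, 1.60, 1.60],  # black absorbs all
            ]
        )
    )
    layer_weights: tuple[float, float] = (1.0, 0.8)

    def __call__(self, mel_cmyk: np.ndarray, hem_cmyk: np.ndarray) -> np.ndarray:
        return virtual_print_capture(mel_cmyk, hem_cmyk, self)


def virtual_print_capture(
    mel_cmyk: np.ndarray, hem_cmyk: np.ndarray, press: VirtualPress | None = None
) -> np.ndarray:
    """Observed linear RGB of a two-layer patch under the virtual press.

    Accepts single 4-vectors or ``(n, 4)`` batches; CMYK must lie in [0, 1].
    Deterministic, smooth, and monotone: more of any ink never brightens any
    channel.
    """
    if press is None:
        press = VirtualPress()
    mel = np.asarray(mel_cmyk, dtype=float)
    hem = np.asarray(hem_cmyk, dtype=float)
    if mel.shape[-1] != 4 or hem.shape[-1] != 4:
        raise ValueError("CMYK inputs must have 4 components")
    for name, arr in (("mel_cmyk", mel), ("hem_cmyk", hem)):
        if np.any(arr < 0) or np.any(arr > 1):
            raise ValueError(f"{name} outside [0, 1]")
    w_mel, w_hem = press.layer_weights
    density = (w_mel * mel + w_hem * hem) @ press.ink_density
    return np.clip(np.exp(-density), EPSILON, 1.0)


def _smooth_field(rng: np.random.Generator, height: int, width: int,
                  n_modes: int = 3) -> np.ndarray:
    """Low-frequency random field in roughly [-1, 1] from a few cosine modes."""
    y, x = np.mgrid[0:height, 0:width]
    y = y / max(height - 1, 1)
    x = x / max(width - 1, 1)
    out = np.zeros((height, width))
    for _ in range(n_modes):
        fy, fx = rng.uniform(0.5, 2.0, size=2)
        phase = rng.uniform(0, 2 * np.pi)
        amp = rng.uniform(0.4, 1.0)
        out += amp * np.cos(2 * np.pi * (fy * y + fx * x) + phase)
    m = np.max(np.abs(out))
    return out / m if m > 0 else out


def _base_field(rng: np.random.Generator, height: int, width: int,
                sigma_frac: float = 0.1) -> np.ndarray:
    """Unit-variance smooth random field (Gaussian-filtered white noise)."""
    from scipy.ndimage import gaussian_filter

    f = gaussian_filter(rng.normal(size=(height, width)),
                        sigma_frac * min(height, width))
    s = f.std()
    return f / s if s > 0 else f


def _sparse_spots(rng: np.random.Generator, height: int, width: int,
                  density: float, sigma: float, amp: float) -> np.ndarray:
    """Sparse blurred spots (freckle/mottle texture), non-negative."""
    from scipy.ndimage import gaussian_filter

    spikes = (rng.random((height, width)) < density) * rng.exponential(
        1.0, (height, width)
    )
    f = gaussian_filter(spikes, sigma)
    f = amp * f / max(f.std(), 1e-9)
    return np.minimum(f, 5.0 * amp)  # spot darkness is bounded


def make_phantom(
    kind: str,
    width: int,
    height: int,
    seed: int = 0,
    return_info: bool = False,
) -> ConcentrationMap | tuple[ConcentrationMap, dict]:
    """Reproducible synthetic concentration maps.

    Kinds
    -----
    ``gradient``
        Melanin ramps left-to-right (columns), hemoglobin top-to-bottom
        (rows); no shading. The separable ground truth for projection tests.
    ``blobs``
        Gaussian hemoglobin spots on a uniform melanin background; no shading.
    ``palm_like``
        Low-frequency melanin field, vessel-like hemoglobin ridges and a
        smooth shading field — the realistic end-to-end fixture.

    With ``return_info=True`` also returns generator internals (e.g. blob
    centers) for verification.
    """
    if width <= 0 or height <= 0:
        raise ValueError("phantom dimensions must be positive")
    rng = np.random.default_rng(seed)
    info: dict = {"kind": kind, "seed": seed}
    shading = np.zeros((height, width))
    if kind == "gradient":
        col = np.linspace(0.1, 0.9, width)
        row = np.linspace(0.1, 0.9, height)
        melanin = np.tile(col, (height, 1))
        hemoglobin = np.tile(row[:, None], (1, width))
    elif kind == "blobs":
        melanin = np.full((height, width), 0.35)
        hemoglobin = np.full((height, width), 0.10)
        n_blobs = 3
        y, x = np.mgrid[0:height, 0:width]
        centers = []
        for _ in range(n_blobs):
            cy = int(rng.integers(height // 4, 3 * height // 4))
            cx = int(rng.integers(width // 4, 3 * width // 4))
            s = max(2.0, 0.08 * min(height, width))
            hemoglobin += 0.5 * np.exp(-((y - cy) ** 2 + (x - cx) ** 2) / (2 * s**2))
            centers.append((cy, cx))
        info["centers"] = centers
    elif kind == "palm_like":
        # Skin pigment fields mix a smooth base with abundant fine-scale
        # texture: melanin carries freckle-like spots, hemoglobin carries
        # vessel ridges and mottling. The fine structure dominates the
        # variance, as in close-up photographs of real skin.
        y, x = np.mgrid[0:height, 0:width]
        xn = x / max(width - 1, 1)
        yn = y / max(height - 1, 1)
        melanin = (
            0.42
            + 0.10 * _base_field(rng, height, width)
            + _sparse_spots(rng, height, width, density=0.04, sigma=1.5, amp=0.28)
        )
        hemoglobin = (
            0.25
            + 0.03 * _base_field(rng, height, width)
            + _sparse_spots(rng, height, width, density=0.04, sigma=1.5, amp=0.10)
        )
        for _ in range(5):  # vessel-like ridges: smooth sinusoidal curves
            y0 = rng.uniform(0.10, 0.90)
            amp = rng.uniform(0.05, 0.15)
            freq = rng.uniform(1.0, 2.5)
            phase = rng.uniform(0, 2 * np.pi)
            width_n = rng.uniform(0.010, 0.030)
            path = y0 + amp * np.sin(2 * np.pi * freq * xn + phase)
            hemoglobin += 0.30 * np.exp(-((yn - path) ** 2) / (2 * width_n**2))
        shading = 0.08 * _smooth_field(rng, height, width, n_modes=2)
        shading -= 0.04 * ((xn - 0.5) ** 2 + (yn - 0.5) ** 2)  # gentle falloff
    else:
        raise ValueError(
            f"unknown phantom kind {kind!r}; valid kinds: gradient, blobs, palm_like"
        )
    conc = ConcentrationMap(melanin=melanin, hemoglobin=hemoglobin, shading=shading)
    return (conc, info) if return_info else conc
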