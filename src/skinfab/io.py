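"""Reading and writing images and concentration maps.

Skin photographs arrive as 8- or 16-bit PNG/TIFF. By default they are assumed
sRGB-encoded and are decoded to linear reflectance on read (disable with
``srgb=False`` if the camera pipeline is already linear). Concentration maps
persist as a trio of float32 TIFFs plus a JSON sidecar naming the channels.
"""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import tifffile

from .types import ConcentrationMap, SkinImage

_CHANNELS = ("melanin", "hemoglobin", "shading")


def srgb_decode(v: np.ndarray) -> np.ndarray:
    """sRGB electro-optical transfer: encoded [0,1] -> linear [0,1]."""
    v = np.asarray(v, dtype=float)
    return np.where(v <= 0.04045, v / 12.92, ((v + 0.055) / 1.055) ** 2.4)


def srgb_encode(v: np.ndarray) -> np.ndarray:
    """Inverse of :func:`srgb_decode`."""
    v = np.asarray(v, dtype=float)
    return np.where(v <= 0.0031308, 12.92 * v, 1.055 * v ** (1 / 2.4) - 0.055)


def read_image(path, srgb: bool = True, provenance: str = "captured") -> SkinImage:
    """Load an 8/16-bit RGB image as linear reflectance."""
    arr = iio.imread(path)
    if arr.ndim == 2:
        arr = np.stack([arr] * 3, axis=-1)
    arr = arr[..., :3]
    if arr.dtype == np.uint8:
        scale = 255.0
    elif arr.dtype == np.uint16:
        scale = 65535.0
    else:
        scale = 1.0
    rgb = arr.astype(float) / scale
    if srgb:
        rgb = srgb_decode(rgb)
    return SkinImage(rgb=rgb, provenance=provenance)


def write_image(path, img: SkinImage, srgb: bool = True, bits: int = 16) -> None:
    """Write linear reflectance as an 8/16-bit image (sRGB-encoded by default).

    16-bit RGB goes to TIFF (PNG writers here cap RGB at 8 bits per channel);
    8-bit can be PNG or TIFF.
    """
    rgb = srgb_encode(img.rgb) if srgb else img.rgb
    rgb = np.clip(rgb, 0.0, 1.0)
    suffix = Path(path).suffix.lower()
    if bits == 8:
        iio.imwrite(path, (rgb * 255 + 0.5).astype(np.uint8))
    elif bits == 16:
        data = (rgb * 65535 + 0.5).astype(np.uint16)
        if suffix in (".tif", ".tiff"):
            tifffile.imwrite(path, data)
        else:
            raise ValueError(
                "16-bit RGB requires a .tif/.tiff path; use bits=8 for PNG"
            )
    else:
        raise ValueError("bits must be 8 or 16")


def write_concentration_map(conc: ConcentrationMap, out_dir, prefix: str = "conc") -> None:
    """Persist the three fields as float32 TIFFs + a JSON sidecar."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sidecar = {"channels": {}}
    for name in _CHANNELS:
        fname = f"{prefix}_{name}.tiff"
        tifffile.imwrite(out / fname, getattr(conc, name).astype(np.float32))
        sidecar["channels"][name] = fname
    (out / f"{prefix}.json").write_text(json.dumps(sidecar, indent=2))


def read_concentration_map(out_dir, prefix: str = "conc") -> ConcentrationMap:
    """Load a concentration-map trio written by :func:`write_concentration_map`."""
    out = Path(out_dir)
    sidecar = json.loads((out / f"{prefix}.json").read_text())
    fields = {
        name: tifffile.imread(out / fname).astype(float)
        for name, fname in sidecar["channels"].items()
    }
    return ConcentrationMap(**fields)
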