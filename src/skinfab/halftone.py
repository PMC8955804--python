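"""Error-diffusion halftoning and printer-grid resampling.

Each continuous CMYK channel is binarised independently by Floyd-Steinberg
error diffusion at the largest dot size (every fired pixel is a full dot,
which keeps stacked layers even). Images are resampled to the printer's
anisotropic grid *before* halftoning so dot statistics live on the device
raster.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

CHANNEL_NAMES = ("C", "M", "Y", "K")


@dataclass
class ContinuousChannel:
    """A single ink channel with coverage values in [0, 1]."""

    values: np.ndarray
    channel_name: str
    layer_name: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("channel values must be 2-D")
        if np.any(self.values < 0) or np.any(self.values > 1):
            raise ValueError(
                f"channel {self.channel_name!r} has values outside [0, 1]"
            )


@dataclass
class BinaryChannel:
    """A halftoned ink bitmap; strictly 0/1, largest dot size."""

    bits: np.ndarray
    channel_name: str
    layer_name: str = ""
    dot_size: str = "largest"

    def __post_init__(self) -> None:
        self.bits = np.asarray(self.bits)
        if not np.all((self.bits == 0) | (self.bits == 1)):
            raise ValueError("bits must be strictly binary")
        self.bits = self.bits.astype(np.uint8)


def floyd_steinberg(ch: ContinuousChannel) -> BinaryChannel:
    """Classic 4-neighbour error diffusion.

    Plain raster scan (top-to-bottom, left-to-right), threshold 0.5 with ties
    firing a dot; the quantisation error is pushed 7/16 right, 3/16 down-left,
    5/16 down, 1/16 down-right. Diffusion targets outside the image are
    dropped; accumulated values are never clamped before thresholding.
    """
    work = ch.values.astype(float).copy()
    h, w = work.shape
    bits = np.zeros((h, w), dtype=np.uint8)
    for r in range(h):
        row = work[r]
        below = work[r + 1] if r + 1 < h else None
        for c in range(w):
            old = row[c]
            bit = 1 if old >= 0.5 else 0
            bits[r, c] = bit
            err = old - bit
            if c + 1 < w:
                row[c + 1] += err * (7 / 16)
            if below is not None:
                if c > 0:
                    below[c - 1] += err * (3 / 16)
                below[c] += err * (5 / 16)
                if c + 1 < w:
                    below[c + 1] += err * (1 / 16)
    return BinaryChannel(bits=bits, channel_name=ch.channel_name,
                         layer_name=ch.layer_name)


def halftone_cmyk(channels: list[ContinuousChannel]) -> list[BinaryChannel]:
    """Halftone the four CMYK channels of one layer, independently."""
    if len(channels) != 4:
        raise ValueError(f"expected 4 CMYK channels, got {len(channels)}")
    return [floyd_steinberg(ch) for ch in channels]


def resample_to_printer(
    img: np.ndarray,
    src_dpi: tuple[float, float],
    dst_dpi: tuple[float, float],
) -> np.ndarray:
    """Nearest-neighbour resampling between dot-pitch grids.

    DPI pairs are ``(horizontal, vertical)``; the axes scale independently
    (the target device prints 720 dpi horizontally and 1200 dpi vertically).
    Output dims are ``round(input_dims * dst/src)`` per axis. Nearest
    neighbour preserves concentration boundaries.
    """
    sh, sv = src_dpi
    dh, dv = dst_dpi
    if min(sh, sv, dh, dv) <= 0:
        raise ValueError("dpi values must be positive")
    img = np.asarray(img)
    h, w = img.shape[:2]
    out_w = int(round(w * dh / sh))
    out_h = int(round(h * dv / sv))
    if out_w < 1 or out_h < 1:
        raise ValueError("resampled image would be empty")
    rows = np.minimum((np.arange(out_h) * h) // out_h, h - 1).astype(int)
    cols = np.minimum((np.arange(out_w) * w) // out_w, w - 1).astype(int)
    return img[np.ix_(rows, cols)] if img.ndim == 2 else img[rows][:, cols]
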