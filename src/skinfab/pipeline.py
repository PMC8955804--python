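"""End-to-end orchestration: flat-field -> separate -> CMYK -> halftone -> stack.

``run_pipeline`` is fully seed-deterministic: a configuration plus a seed
fixes every output byte (no timestamps enter the job directory). Calibration
is self-contained — the patch grid is built from the *estimated* pigment
basis, pushed through the virtual print-and-capture loop and fitted with the
configured estimator, mirroring a photographed patch chart.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import io as skio
from .calibration import (
    build_patch_set,
    fit_lut,
    fit_mlp,
    fit_regression,
    measure_patch_set,
    pigment_color,
)
from .halftone import (
    CHANNEL_NAMES,
    BinaryChannel,
    ContinuousChannel,
    floyd_steinberg,
    resample_to_printer,
)
from .layerstack import build_stack, write_job
from .separation import separate
from .synth import VirtualPress
from .types import EPSILON, SkinImage

logger = logging.getLogger("skinfab")


@dataclass
class PipelineConfig:
    """Everything that determines a pipeline run (serialised into manifests).

    ``roi`` is ``None`` (central window) or ``(x, y, w, h)``;
    ``method`` selects the concentration->CMYK estimator; dpi pairs are
    ``(horizontal, vertical)``.
    """

    roi: tuple[int, int, int, int] | None = None
    illum: tuple[float, float, float] = (1.0, 1.0, 1.0)
    method: str = "regression"
    n_mel: int = 30
    n_hem: int = 30
    mel_range: tuple[float, float] = (0.0, 1.0)
    hem_range: tuple[float, float] = (0.0, 1.0)
    clear1_n: int = 1
    clear2_n: int = 2
    clear3_n: int = 4
    src_dpi: tuple[float, float] = (360.0, 360.0)
    dst_dpi: tuple[float, float] = (720.0, 1200.0)
    seed: int = 0
    srgb_decode: bool = True
    mlp_epochs: int = 30

    def validate(self) -> None:
        if self.method not in ("lut", "regression", "mlp"):
            raise ValueError(f"unknown calibration method {self.method!r}")
        if self.n_mel < 2 or self.n_hem < 2:
            raise ValueError("patch grid needs at least 2 levels per pigment")
        for name in ("clear1_n", "clear2_n", "clear3_n"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if min(*self.src_dpi, *self.dst_dpi) <= 0:
            raise ValueError("dpi values must be positive")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def flat_field(img: SkinImage, reference: SkinImage) -> SkinImage:
    """Cancel illumination non-uniformity with a diffuse-reflector image.

    Divides the skin image by the reference, pixel-wise and per channel; any
    common smooth gain field cancels exactly. The reference must be strictly
    above the reflectance floor everywhere.
    """
    if img.rgb.shape != reference.rgb.shape:
        raise ValueError(
            f"image {img.rgb.shape} and reference {reference.rgb.shape} "
            "dimensions differ"
        )
    bad = np.argwhere(np.any(reference.rgb <= EPSILON, axis=-1))
    if len(bad):
        raise ValueError(
            f"reference has {len(bad)} pixel(s) at/below the reflectance floor, "
            f"first at (row, col) = ({int(bad[0][0])}, {int(bad[0][1])})"
        )
    return SkinImage(rgb=img.rgb / reference.rgb, provenance="flat-fielded")


def _fit_estimator(cfg: PipelineConfig, basis):
    ps = build_patch_set(
        cfg.n_mel, cfg.n_hem, basis,
        mel_range=cfg.mel_range, hem_range=cfg.hem_range,
    )
    measured = measure_patch_set(ps, VirtualPress(), basis, seed=cfg.seed)
    if cfg.method == "lut":
        return fit_lut(measured)
    if cfg.method == "regression":
        return fit_regression(measured)
    return fit_mlp(measured, epochs=cfg.mlp_epochs, seed=cfg.seed)


def run_pipeline(
    cfg: PipelineConfig,
    image: SkinImage | str | Path,
    reference: SkinImage | str | Path | None = None,
    out_dir: str | Path = "job",
    save_intermediates: bool = False,
) -> dict:
    """Execute the full workflow and write a print job directory.

    Stages: optional flat-fielding, pigment separation, negative-concentration
    clamping, concentration->CMYK via the configured estimator, resampling to
    the printer grid, Floyd-Steinberg halftoning, stack assembly and job
    writing. Returns the job manifest.
    """
    cfg.validate()
    out = Path(out_dir)

    def load(src, tag):
        if isinstance(src, SkinImage):
            return src
        return skio.read_image(src, srgb=cfg.srgb_decode, provenance=tag)

    stage = "load"
    try:
        img = load(image, "captured")
        if reference is not None:
            stage = "flat_field"
            img = flat_field(img, load(reference, "captured"))

        stage = "separate"
        logger.info("separating pigments (roi=%s, seed=%d)", cfg.roi, cfg.seed)
        conc, basis = separate(img, roi=cfg.roi, illum=np.asarray(cfg.illum, float),
                               seed=cfg.seed)
        mel = np.clip(conc.melanin, 0.0, None)  # diagnostics keep negatives;
        hem = np.clip(conc.hemoglobin, 0.0, None)  # calibration does not

        stage = "calibrate"
        logger.info("fitting %s estimator on %dx%d patch grid",
                    cfg.method, cfg.n_mel, cfg.n_hem)
        estimator = _fit_estimator(cfg, basis)

        stage = "convert"
        h, w = mel.shape
        feats = np.concatenate(
            [
                pigment_color(mel.ravel(), basis.melanin_vector, basis.bias),
                pigment_color(hem.ravel(), basis.hemoglobin_vector, basis.bias),
            ],
            axis=1,
        )
        cmyk8 = estimator.predict(feats).reshape(h, w, 8)

        stage = "halftone"
        def binarise(cmyk: np.ndarray, layer: str) -> list[BinaryChannel]:
            bits = []
            for j, name in enumerate(CHANNEL_NAMES):
                res = resample_to_printer(cmyk[..., j], cfg.src_dpi, cfg.dst_dpi)
                bits.append(
                    floyd_steinberg(
                        ContinuousChannel(values=res, channel_name=name,
                                          layer_name=layer)
                    )
                )
            return bits

        mel_bits = binarise(cmyk8[..., :4], "melanin")
        hem_bits = binarise(cmyk8[..., 4:], "hemoglobin")

        stage = "stack"
        provenance = {"config": cfg.to_dict(), "seed": cfg.seed}
        stack = build_stack(
            mel_bits, hem_bits,
            clear2_n=cfg.clear2_n, clear3_n=cfg.clear3_n, clear1_n=cfg.clear1_n,
            dpi=cfg.dst_dpi, provenance=provenance,
        )

        stage = "write"
        manifest = write_job(stack, out)
        if save_intermediates:
            skio.write_concentration_map(conc, out, prefix="maps")
            basis_info = {
                "melanin_vector": basis.melanin_vector.tolist(),
                "hemoglobin_vector": basis.hemoglobin_vector.tolist(),
                "illumination_direction": basis.illumination_direction.tolist(),
                "bias": basis.bias.tolist(),
            }
            (out / "basis.json").write_text(json.dumps(basis_info, indent=2))
        return manifest
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc
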