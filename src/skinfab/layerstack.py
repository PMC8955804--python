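"""Multilayer print-job assembly.

The printed stack, top to bottom: a protective clear layer, the melanin
(epidermis) colour layer, a clear spacer, the hemoglobin (dermis) colour
layer, a clear spacer, and an opaque white reflective base (the "paper").
Clear-layer thickness is expressed as a sublayer count; the colored layers
are always a single layer because concentration is carried by area gradation
(the halftone dot pattern).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image

from .halftone import CHANNEL_NAMES, BinaryChannel

MANIFEST_SCHEMA_VERSION = 1
CANONICAL_ORDER = ("clear1", "melanin", "clear2", "hemoglobin", "clear3", "white")


@dataclass
class LayerSpec:
    """One layer of the print job.

    ``kind`` is ``clear`` (no ink content), ``color`` (4 binary CMYK
    bitmaps) or ``white`` (full-coverage single channel).
    """

    kind: str
    name: str
    sublayer_count: int
    content: list[BinaryChannel] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.kind not in ("clear", "color", "white"):
            raise ValueError(f"unknown layer kind {self.kind!r}")
        if self.sublayer_count < 1:
            raise ValueError(f"layer {self.name}: sublayer_count must be >= 1")
        if self.kind == "clear" and self.content:
            raise ValueError(f"clear layer {self.name} must carry no ink content")
        if self.kind == "color":
            if len(self.content) != 4:
                raise ValueError(
                    f"color layer {self.name} needs 4 binary channels, "
                    f"got {len(self.content)}"
                )
            dims = {ch.bits.shape for ch in self.content}
            if len(dims) != 1:
                raise ValueError(
                    f"color layer {self.name} channels differ in shape: {dims}"
                )
        if self.kind == "white":
            if len(self.content) != 1:
                raise ValueError("white layer carries exactly one channel")
            if not np.all(self.content[0].bits == 1):
                raise ValueError("white reflective layer must be full coverage")


@dataclass
class LayerStack:
    """Ordered top-to-bottom print job with provenance."""

    layers: list[LayerSpec]
    dims: tuple[int, int]
    dpi: tuple[float, float]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        names = tuple(layer.name for layer in self.layers)
        if names != CANONICAL_ORDER:
            raise ValueError(
                f"layer order must be {CANONICAL_ORDER}, got {names}"
            )
        for layer in self.layers:
            if layer.kind == "color" and layer.sublayer_count != 1:
                raise ValueError(
                    f"colored layer {layer.name} must be a single layer "
                    "(concentration is expressed in area gradation)"
                )

    @property
    def total_physical_layers(self) -> int:
        return sum(layer.sublayer_count for layer in self.layers)

    def layer(self, name: str) -> LayerSpec:
        for layer in self.layers:
            if layer.name == name:
                return layer
        raise KeyError(name)


def build_stack(
    mel_bits: list[BinaryChannel],
    hem_bits: list[BinaryChannel],
    clear2_n: int,
    clear3_n: int,
    clear1_n: int = 1,
    dpi: tuple[float, float] = (720.0, 1200.0),
    provenance: dict | None = None,
) -> LayerStack:
    """Assemble the canonical six-layer stack.

    Total physical layer count is ``clear1_n + 1 + clear2_n + 1 + clear3_n +
    1``. Colored bitmaps must share dimensions.
    """
    for n, name in ((clear1_n, "clear1"), (clear2_n, "clear2"), (clear3_n, "clear3")):
        if n < 1:
            raise ValueError(f"{name} sublayer count must be >= 1, got {n}")
    dims = {ch.bits.shape for ch in [*mel_bits, *hem_bits]}
    if len(dims) != 1:
        raise ValueError(f"melanin/hemoglobin bitmaps differ in shape: {dims}")
    shape = dims.pop()
    white = BinaryChannel(
        bits=np.ones(shape, dtype=np.uint8), channel_name="W", layer_name="white"
    )
    layers = [
        LayerSpec(kind="clear", name="clear1", sublayer_count=clear1_n),
        LayerSpec(kind="color", name="melanin", sublayer_count=1, content=list(mel_bits)),
        LayerSpec(kind="clear", name="clear2", sublayer_count=clear2_n),
        LayerSpec(kind="color", name="hemoglobin", sublayer_count=1, content=list(hem_bits)),
        LayerSpec(kind="clear", name="clear3", sublayer_count=clear3_n),
        LayerSpec(kind="white", name="white", sublayer_count=1, content=[white]),
    ]
    return LayerStack(
        layers=layers, dims=shape, dpi=dpi, provenance=provenance or {}
    )


def enumerate_samples(counts=(2, 4, 6)) -> list[tuple[int, int]]:
    """Cross the clear-spacer thicknesses: clear2 outer, clear3 inner, ascending.

    The default {2, 4, 6} x {2, 4, 6} gives the nine standard sample
    configurations.
    """
    counts = sorted(set(int(c) for c in counts))
    if not counts:
        raise ValueError("counts must be non-empty")
    return [(c2, c3) for c2 in counts for c3 in counts]


def config_hash(config: dict) -> str:
    """Stable short hash of a JSON-serialisable configuration."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def write_job(stack: LayerStack, out_dir) -> dict:
    """Write one 1-bit PNG per ink channel per color layer, plus a manifest.

    The white layer's full-coverage mask is also written; clear layers carry
    no bitmap. Round-trips losslessly through :func:`read_job`.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "schema_version": MANIFEST_SCHEMA_VERSION,
        "dims": list(stack.dims),
        "dpi": list(stack.dpi),
        "provenance": stack.provenance,
        "config_hash": config_hash(stack.provenance),
        "layers": [],
    }
    for layer in stack.layers:
        entry = {
            "name": layer.name,
            "kind": layer.kind,
            "sublayer_count": layer.sublayer_count,
            "files": {},
        }
        for ch in layer.content:
            fname = f"{layer.name}_{ch.channel_name}.png"
            img = Image.fromarray((ch.bits * 255).astype(np.uint8)).convert("1")
            try:
                img.save(out / fname)
            except OSError as exc:
                raise OSError(f"failed writing {out / fname}: {exc}") from exc
            entry["files"][ch.channel_name] = fname
        manifest["layers"].append(entry)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def validate_manifest(manifest: dict) -> None:
    """Check a job manifest against the published schema; raise on violation."""
    required = {"schema_version": int, "dims": list, "dpi": list,
                "provenance": dict, "config_hash": str, "layers": list}
    for key, typ in required.items():
        if key not in manifest:
            raise ValueError(f"manifest missing key {key!r}")
        if not isinstance(manifest[key], typ):
            raise ValueError(f"manifest key {key!r} must be {typ.__name__}")
    if manifest["schema_version"] != MANIFEST_SCHEMA_VERSION:
        raise ValueError(f"unsupported schema version {manifest['schema_version']}")
    if len(manifest["dims"]) != 2 or len(manifest["dpi"]) != 2:
        raise ValueError("dims and dpi must be 2-element lists")
    names = tuple(entry.get("name") for entry in manifest["layers"])
    if names != CANONICAL_ORDER:
        raise ValueError(f"manifest layer order {names} != {CANONICAL_ORDER}")
    for entry in manifest["layers"]:
        for key, typ in (("kind", str), ("sublayer_count", int), ("files", dict)):
            if not isinstance(entry.get(key), typ):
                raise ValueError(
                    f"layer {entry.get('name')!r}: {key} must be {typ.__name__}"
                )


def read_job(job_dir) -> LayerStack:
    """Load a written job directory back into a LayerStack."""
    job = Path(job_dir)
    manifest = json.loads((job / "manifest.json").read_text())
    validate_manifest(manifest)
    layers = []
    for entry in manifest["layers"]:
        content = []
        # canonical channel order (the manifest serialises keys sorted)
        names = [c for c in (*CHANNEL_NAMES, "W") if c in entry["files"]]
        names += [c for c in entry["files"] if c not in names]
        for ch_name in names:
            fname = entry["files"][ch_name]
            bits = (np.asarray(Image.open(job / fname).convert("L")) > 127).astype(
                np.uint8
            )
            content.append(
                BinaryChannel(bits=bits, channel_name=ch_name,
                              layer_name=entry["name"])
            )
        layers.append(
            LayerSpec(
                kind=entry["kind"],
                name=entry["name"],
                sublayer_count=entry["sublayer_count"],
                content=content,
            )
        )
    return LayerStack(
        layers=layers,
        dims=tuple(manifest["dims"]),
        dpi=tuple(manifest["dpi"]),
        provenance=manifest["provenance"],
    )
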