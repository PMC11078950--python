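"""Stack I/O (OME-TIFF / multi-page TIFF), run configuration and pipeline.

Stacks are stored as uncompressed multi-page TIFF.  On read, pixel-size
metadata embedded in the file takes precedence over the configuration (the
precedence is logged); integer data are promoted to float.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile
import yaml

from . import __version__
from .core import ImageStack, IndicatorMap, MusicalParams, reconstruct
from .density import multiscale_variance
from .optics import OpticsConfig
from .phantom import (CameraModel, FluctuationModel, generate_fibrils,
                      place_emitters, render_stack, simulate_fluctuations)

logger = logging.getLogger(__name__)


class StackFormatError(ValueError):
    """Raised for unreadable, truncated or ambiguous stack files."""


def read_stack(path, pixel_size_um: float | None = None,
               channel: int | None = None,
               frame_interval_s: float | None = None) -> ImageStack:
    """Read a (OME-)TIFF fluctuation stack as float frames.

    ``pixel_size_um`` is the *object-space* pixel size fallback used when
    the file carries no physical-size metadata; embedded OME metadata wins
    and the precedence is logged.  Multi-channel files require ``channel``.
    """
    path = Path(path)
    try:
        with tifffile.TiffFile(path) as tf:
            data = tf.asarray()
            meta_px = _ome_pixel_size(tf)
            if meta_px is None and tf.shaped_metadata:
                meta_px = tf.shaped_metadata[0].get("PhysicalSizeX")
            compressed = any(p.compression != 1 for p in tf.pages[:1])
    except Exception as exc:  # noqa: BLE001 - surface as a format error
        raise StackFormatError(f"cannot read stack {path}: {exc}") from exc
    if compressed:
        logger.info("stack %s uses compression; accepted", path)
    data = np.asarray(data)
    if data.ndim == 2:
        raise StackFormatError("single-frame image: a stack of >= 2 frames "
                               "is required")
    if data.ndim == 4:
        if channel is None:
            raise StackFormatError(
                f"multi-channel stack {path} needs an explicit channel index")
        data = data[:, channel] if data.shape[1] <= 8 else data[..., channel]
    if data.ndim != 3:
        raise StackFormatError(f"unsupported stack dimensionality {data.shape}")
    if meta_px is not None:
        if pixel_size_um is not None and not np.isclose(meta_px, pixel_size_um):
            logger.info("pixel size: file metadata %.6g µm overrides "
                        "config %.6g µm", meta_px, pixel_size_um)
        pixel_size_um = meta_px
    if pixel_size_um is None:
        raise StackFormatError(
            "no pixel size in file metadata; pass pixel_size_um")
    return ImageStack(frames=data.astype(np.float32),
                      pixel_pitch_object=float(pixel_size_um),
                      frame_interval=frame_interval_s,
                      metadata={"source": str(path)})


def _ome_pixel_size(tf: "tifffile.TiffFile") -> float | None:
    try:
        if tf.ome_metadata:
            import xml.etree.ElementTree as ET
            root = ET.fromstring(tf.ome_metadata)
            for el in root.iter():
                if el.tag.endswith("Pixels") and "PhysicalSizeX" in el.attrib:
                    return float(el.attrib["PhysicalSizeX"])
    except Exception:  # noqa: BLE001 - metadata is best-effort
        logger.warning("unparseable OME metadata; falling back to config")
    return None


def write_stack(path, stack: ImageStack, dtype=np.uint16) -> None:
    """Write a stack as uncompressed multi-page TIFF with pixel-size metadata."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    data = stack.frames
    if np.issubdtype(np.dtype(dtype), np.integer):
        info = np.iinfo(dtype)
        data = np.clip(np.round(data), info.min, info.max).astype(dtype)
    else:
        data = data.astype(dtype)
    # plain multi-page TIFF with self-describing (shaped) metadata: the
    # OME writer embeds a fresh UUID per file, which would break the
    # bit-for-bit reproducibility the manifest promises
    px = stack.pixel_pitch_object
    tifffile.imwrite(
        path, data, photometric="minisblack",
        metadata={"axes": "TYX", "PhysicalSizeX": px,
                  "PhysicalSizeXUnit": "µm",
                  "PhysicalSizeY": px, "PhysicalSizeYUnit": "µm"},
        ome=False)


def write_indicator_map(path, imap: IndicatorMap) -> None:
    """32-bit float TIFF plus a JSON sidecar with parameters and provenance."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, imap.values.astype(np.float32),
                     photometric="minisblack")
    tifffile.imwrite(path.with_suffix(".mask.tif"),
                     imap.valid_mask.astype(np.uint8),
                     photometric="minisblack")
    sidecar = {
        "params": dataclasses.asdict(imap.params),
        "pixel_pitch_um": imap.pixel_pitch,
        "provenance": imap.provenance,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def read_indicator_map(path) -> IndicatorMap:
    path = Path(path)
    values = tifffile.imread(path)
    mask_path = path.with_suffix(".mask.tif")
    mask = (tifffile.imread(mask_path).astype(bool) if mask_path.exists()
            else np.ones(values.shape, dtype=bool))
    side = json.loads(path.with_suffix(".json").read_text())
    return IndicatorMap(values=values, valid_mask=mask,
                        params=MusicalParams(**side["params"]),
                        pixel_pitch=side["pixel_pitch_um"],
                        provenance=side.get("provenance", {}))


# ---------------------------------------------------------------------------
# Run configuration and pipeline


_KNOWN_BLOCKS = {"optics", "musical", "phantom", "camera", "fluctuation",
                 "analysis", "seed", "paths", "log_level"}


@dataclass
class RunConfig:
    """Validated configuration for a simulate → reconstruct → analyze run."""

    optics: OpticsConfig
    musical: MusicalParams = field(default_factory=MusicalParams)
    phantom: dict | None = None
    camera: CameraModel = field(default_factory=CameraModel)
    fluctuation: FluctuationModel = field(default_factory=FluctuationModel)
    analysis: dict | None = None
    seed: int = 0
    paths: dict = field(default_factory=dict)
    log_level: str = "INFO"


def _build(cls, block: dict, name: str):
    allowed = {f.name for f in dataclasses.fields(cls)}
    unknown = set(block) - allowed
    if unknown:
        raise ValueError(f"unknown keys in {name!r} block: {sorted(unknown)}")
    return cls(**block)


def load_config(path) -> RunConfig:
    """Parse and validate a YAML run configuration; unknown keys rejected."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    unknown = set(raw) - _KNOWN_BLOCKS
    if unknown:
        raise ValueError(f"unknown config blocks: {sorted(unknown)}")
    if "optics" not in raw:
        raise ValueError("config requires an 'optics' block")
    return RunConfig(
        optics=_build(OpticsConfig, raw["optics"], "optics"),
        musical=_build(MusicalParams, raw.get("musical", {}), "musical"),
        phantom=raw.get("phantom"),
        camera=_build(CameraModel, raw.get("camera", {}), "camera"),
        fluctuation=_build(FluctuationModel, raw.get("fluctuation", {}),
                           "fluctuation"),
        analysis=raw.get("analysis"),
        seed=int(raw.get("seed", 0)),
        paths=raw.get("paths", {}),
        log_level=raw.get("log_level", "INFO"),
    )


@dataclass
class RunManifest:
    """Reproducibility record written for every pipeline run."""

    config: dict
    version: str
    input_checksums: dict = field(default_factory=dict)
    output_checksums: dict = field(default_factory=dict)
    timings_s: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)

    def write(self, path) -> None:
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2,
                                         default=str))


def _sha256(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def simulate_phantom_stack(config: RunConfig):
    """Build the phantom and render its stack per the config's blocks."""
    ph_cfg = dict(config.phantom or {})
    field_size = tuple(ph_cfg.pop("field_size_um", (20.0, 20.0)))
    n_fibrils = int(ph_cfg.pop("n_fibrils", 12))
    linear_density = float(ph_cfg.pop("linear_density_per_um", 3.0))
    jitter_sd = float(ph_cfg.pop("jitter_sd_um", 0.05))
    brightness = float(ph_cfg.pop("brightness", 500.0))
    n_frames = int(ph_cfg.pop("n_frames", 200))
    dense_fraction = float(ph_cfg.pop("dense_fraction", 0.5))
    waviness = float(ph_cfg.pop("waviness", 0.4))
    if ph_cfg:
        raise ValueError(f"unknown keys in 'phantom' block: {sorted(ph_cfg)}")
    seed = config.seed
    phantom = generate_fibrils(field_size, n_fibrils, waviness=waviness,
                               dense_fraction=dense_fraction, seed=seed)
    place_emitters(phantom, linear_density, jitter_sd=jitter_sd,
                   seed=seed + 1, brightness=brightness)
    bmat = simulate_fluctuations(phantom.emitter_brightness,
                                 config.fluctuation, n_frames, seed=seed + 2)
    stack = render_stack(phantom, bmat, config.optics, config.camera,
                         seed=seed + 3)
    return phantom, stack


def run_pipeline(config: RunConfig, out_dir) -> RunManifest:
    """Execute simulate (optional) → reconstruct → analyze (optional).

    Writes all stage outputs plus a manifest under ``out_dir``; raises on
    any stage failure after persisting the partial manifest.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=_config_dict(config), version=__version__)
    manifest_path = out / "manifest.json"
    caught: list[str] = []
    stack = None
    try:
        with warnings.catch_warnings(record=True) as wrec:
            warnings.simplefilter("always")
            if config.phantom is not None:
                t0 = time.perf_counter()
                phantom, stack = simulate_phantom_stack(config)
                write_stack(out / "stack.ome.tif", stack)
                np.savetxt(out / "emitters.csv",
                           np.column_stack([phantom.emitters,
                                            phantom.emitter_brightness]),
                           delimiter=",", header="row_um,col_um,brightness",
                           comments="")
                tifffile.imwrite(out / "density_raster.tif",
                                 phantom.density_raster.astype(np.float32))
                manifest.timings_s["simulate"] = time.perf_counter() - t0
            elif "stack" in config.paths:
                stack_path = config.paths["stack"]
                manifest.input_checksums[str(stack_path)] = _sha256(stack_path)
                stack = read_stack(stack_path,
                                   pixel_size_um=config.optics.pixel_pitch_object)
            if stack is not None and config.musical is not None:
                t0 = time.perf_counter()
                imap = reconstruct(stack, config.musical, config.optics)
                write_indicator_map(out / "indicator_map.tif", imap)
                manifest.timings_s["reconstruct"] = time.perf_counter() - t0
            if stack is not None and config.analysis is not None:
                t0 = time.perf_counter()
                scales = config.analysis.get("scales_um", [90, 45, 25, 10, 5])
                target = (imap.masked if config.musical is not None
                          else stack.mean_frame())
                target = np.nan_to_num(target, nan=0.0)
                pitch = (imap.pixel_pitch if config.musical is not None
                         else stack.pixel_pitch_object)
                usable = [s for s in scales
                          if 3 <= round(s / pitch) <= min(target.shape)]
                report = multiscale_variance(target, usable, pitch,
                                             seed=config.seed)
                (out / "analysis.json").write_text(
                    json.dumps(report.as_dict(), indent=2))
                manifest.timings_s["analyze"] = time.perf_counter() - t0
            caught = [str(w.message) for w in wrec]
    except Exception as exc:
        manifest.warnings = caught + [f"FAILED: {exc}"]
        manifest.write(manifest_path)
        raise
    manifest.warnings = caught
    for p in sorted(out.iterdir()):
        if p.is_file() and p.name != "manifest.json":
            manifest.output_checksums[p.name] = _sha256(p)
    manifest.write(manifest_path)
    return manifest


def _config_dict(config: RunConfig) -> dict:
    d = dataclasses.asdict(config)
    return d
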