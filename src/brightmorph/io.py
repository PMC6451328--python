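"""Readers and writers: rasters, label maps, overlays, CSV, scene fixtures."""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import tifffile

from .morphometry import RegionRecord, records_to_frame
from .segment import LabelMap
from .synthdata import SyntheticScene


def read_raw_image(path: str | Path) -> np.ndarray:
    """Read a TIFF/PNG/JPEG raster (8- or 16-bit, 1 or 3 channels).

    An RGBA plane is truncated to RGB.
    """
    arr = iio.imread(Path(path))
    if arr.ndim == 3 and arr.shape[2] == 4:
        arr = arr[:, :, :3]
    return arr


def write_label_map(path: str | Path, labels: LabelMap) -> None:
    """Serialize a label map as 16-bit single-channel TIFF/PNG."""
    data = labels.labels
    if data.max() > np.iinfo(np.uint16).max:
        raise ValueError("label map exceeds 16-bit range")
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, data.astype(np.uint16))
    else:
        iio.imwrite(path, data.astype(np.uint16))


def read_label_map(path: str | Path, pixel_size_um: float) -> LabelMap:
    return LabelMap(iio.imread(Path(path)).astype(np.int32), pixel_size_um)


def render_overlay(labels: LabelMap, background: np.ndarray) -> np.ndarray:
    """Random-color label overlay on a grayscale background, as uint8 RGB."""
    from skimage.color import label2rgb

    bg = np.asarray(background, dtype=float)
    rgb = label2rgb(labels.labels, image=bg, bg_label=0, alpha=0.35)
    return (np.clip(rgb, 0, 1) * 255).astype(np.uint8)


def write_overlay_png(path: str | Path, labels: LabelMap, background: np.ndarray) -> None:
    iio.imwrite(Path(path), render_overlay(labels, background))


def write_records_csv(path: str | Path, records: list[RegionRecord]) -> None:
    """One row per region; fixed column order; '.' decimal, UTF-8."""
    records_to_frame(records).to_csv(Path(path), index=False)


def save_scene(scene: SyntheticScene, outdir: str | Path, stem: str) -> dict[str, Path]:
    """Persist a synthetic scene: image TIFF, truth-label TIFF, truth JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    img_path = outdir / f"{stem}.tif"
    raw = scene.raw
    tifffile.imwrite(img_path, (np.clip(raw, 0, 1) * 65535).astype(np.uint16))
    truth_path = outdir / f"{stem}_truth.tif"
    write_label_map(truth_path, scene.truth_labels)
    table_path = outdir / f"{stem}_truth.json"
    payload = {
        "params": scene.params,
        "pixel_size_um": scene.truth_labels.pixel_size_um,
        "objects": json.loads(scene.truth_table.to_json(orient="records")),
    }
    table_path.write_text(json.dumps(payload, indent=1))
    return {"image": img_path, "truth": truth_path, "table": table_path}
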