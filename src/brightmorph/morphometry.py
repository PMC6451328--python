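"""Per-object shape and intensity descriptors.

Cells are treated as spheroids: length and width are the major and minor
axis lengths of the ellipse with the same second central moments as the
pixel set, scaled by the pixel size. Eccentricity and solidity (area over
convex-hull area) discriminate round, elongated, and bent morphologies;
mean intensity is measured on the raw (non-inverted, non-stretched) channel
so it is comparable across contrast settings.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from skimage.measure import regionprops

from .image import CalibratedImage
from .segment import LabelMap

log = logging.getLogger(__name__)

#: fixed CSV column order (units embedded in the names)
RECORD_COLUMNS = [
    "label",
    "centroid_x",
    "centroid_y",
    "area_px",
    "area_um2",
    "length_um",
    "width_um",
    "eccentricity",
    "solidity",
    "convex_area_px",
    "mean_intensity",
    "touches_border",
]


@dataclass(frozen=True)
class RegionRecord:
    """Morphometry of one segmented object.

    Coordinates are 0-based with x = column (rightward) and y = row
    (downward); centroids are real-valued pixel centers.
    """

    label: int
    centroid_x: float
    centroid_y: float
    area_px: int
    area_um2: float
    length_um: float
    width_um: float
    eccentricity: float
    solidity: float
    convex_area_px: int
    mean_intensity: float
    touches_border: bool


def measure_regions(labels: LabelMap, intensity: CalibratedImage) -> list[RegionRecord]:
    """One :class:`RegionRecord` per label of the segmentation.

    Degenerate (1-px or collinear) objects get their minor axis floored at
    one pixel with a warning.
    """
    if labels.shape != intensity.shape:
        raise ValueError("labels and intensity image must share shape")
    px = labels.pixel_size_um
    h, w = labels.shape
    out: list[RegionRecord] = []
    for rp in regionprops(labels.labels, intensity_image=intensity.pixels):
        major = rp.axis_major_length
        minor = rp.axis_minor_length
        if minor < 1.0:
            log.warning("region %d is degenerate; width floored at 1 px", rp.label)
            minor = 1.0
            major = max(major, minor)
        ecc = float(np.sqrt(max(0.0, 1.0 - (minor / major) ** 2))) if major > 0 else 0.0
        minr, minc, maxr, maxc = rp.bbox
        out.append(
            RegionRecord(
                label=int(rp.label),
                centroid_x=float(rp.centroid[1]),
                centroid_y=float(rp.centroid[0]),
                area_px=int(rp.area),
                area_um2=float(rp.area) * px * px,
                length_um=float(major) * px,
                width_um=float(minor) * px,
                eccentricity=ecc,
                solidity=float(rp.solidity),
                convex_area_px=int(rp.area_convex),
                mean_intensity=float(rp.intensity_mean),
                touches_border=bool(minr == 0 or minc == 0 or maxr == h or maxc == w),
            )
        )
    return out


def records_to_frame(records: list[RegionRecord]) -> pd.DataFrame:
    """Records as a DataFrame with the fixed column order."""
    if not records:
        return pd.DataFrame(columns=RECORD_COLUMNS)
    return pd.DataFrame([asdict(r) for r in records])[RECORD_COLUMNS]


def summarize(records: list[RegionRecord]) -> pd.DataFrame:
    """Mean, sample standard deviation and n of every numeric field.

    A single record summarizes with sd 0; an empty list yields an empty
    table. Row order follows the record column order.
    """
    df = records_to_frame(records)
    numeric = [
        c for c in RECORD_COLUMNS if c not in ("label", "touches_border")
    ]
    if df.empty:
        return pd.DataFrame(columns=["mean", "sd", "n"])
    rows = {}
    for c in numeric:
        vals = df[c].astype(float)
        sd = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
        rows[c] = {"mean": float(vals.mean()), "sd": sd, "n": len(vals)}
    return pd.DataFrame.from_dict(rows, orient="index")[["mean", "sd", "n"]]
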