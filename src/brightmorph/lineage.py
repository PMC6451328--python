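"""Bud–mother separation, parent assignment, and size ratios.

Buds are smaller than mother cells, so an area threshold partitions the
segmented objects into buds and mothers. Each bud is assigned the mother
with the smallest boundary-to-boundary distance (buds physically touch their
mothers; centroid distance would misassign elongated mothers), with ties
broken toward the smaller label and crowded cases flagged as ambiguous.
The daughter/parent size ratio uses the equivalent-circle diameter, which is
rotation-invariant and well defined for circular buds; the major-axis-length
ratio is reported alongside.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from .morphometry import RegionRecord
from .segment import LabelMap

log = logging.getLogger(__name__)

#: a second mother within this boundary gap (px) marks the assignment ambiguous
AMBIGUITY_GAP_PX = 2.0


@dataclass(frozen=True)
class BudAssignment:
    bud_label: int
    parent_label: int
    gap_px: float
    diameter_ratio: float
    ambiguous: bool


def equivalent_diameter_um(record: RegionRecord, pixel_size_um: float) -> float:
    """Diameter of the circle with the object's area, in µm."""
    return 2.0 * math.sqrt(record.area_px / math.pi) * pixel_size_um


def default_bud_threshold(records: list[RegionRecord]) -> int:
    """Default area threshold: 40% of the median object area (px).

    With buds in the minority the median sits among the mother cells, so the
    threshold lands between the two size classes. Recomputed per image;
    overridable.
    """
    if not records:
        return 1
    areas = sorted(r.area_px for r in records)
    return max(1, int(round(0.4 * float(np.median(areas)))))


def split_buds(
    records: list[RegionRecord], area_threshold_px: int | None = None
) -> tuple[list[RegionRecord], list[RegionRecord]]:
    """Partition records into (buds, mothers) by area.

    Buds have ``area_px < threshold``; an object exactly at the threshold is
    a mother. The partition is exhaustive and disjoint.
    """
    if area_threshold_px is None:
        area_threshold_px = default_bud_threshold(records)
    buds = [r for r in records if r.area_px < area_threshold_px]
    mothers = [r for r in records if r.area_px >= area_threshold_px]
    return buds, mothers


def assign_parents(
    buds: list[RegionRecord],
    mothers: list[RegionRecord],
    labels: LabelMap,
) -> list[BudAssignment]:
    """Assign each bud the mother with the minimum boundary-to-boundary distance.

    Ties break toward the smaller mother label; a bud with two or more
    mothers within :data:`AMBIGUITY_GAP_PX` is flagged ambiguous (the known
    failure mode of buds emerging in crowded regions).
    """
    if not mothers and buds:
        raise ValueError(
            "no mother cells: cannot assign buds "
            + str(sorted(b.label for b in buds))
        )
    px = labels.pixel_size_um
    mother_by_label = {m.label: m for m in mothers}
    lab = labels.labels
    out: list[BudAssignment] = []
    for bud in sorted(buds, key=lambda r: r.label):
        # distance from every pixel to the bud; min over a mother's pixels is
        # the boundary-to-boundary gap (touching cells -> 1 px)
        dist = ndi.distance_transform_edt(lab != bud.label)
        gaps = []
        for m in sorted(mothers, key=lambda r: r.label):
            gaps.append((float(dist[lab == m.label].min()), m.label))
        gaps.sort()  # by (gap, label): ties resolve to the smaller label
        best_gap, best_label = gaps[0]
        n_close = sum(1 for g, _ in gaps if g <= AMBIGUITY_GAP_PX)
        parent = mother_by_label[best_label]
        ratio = (
            equivalent_diameter_um(bud, px) / equivalent_diameter_um(parent, px)
        )
        out.append(
            BudAssignment(
                bud_label=bud.label,
                parent_label=best_label,
                gap_px=best_gap,
                diameter_ratio=ratio,
                ambiguous=n_close >= 2,
            )
        )
    return out


def size_ratios(
    assignments: list[BudAssignment], records: list[RegionRecord]
) -> pd.DataFrame:
    """Join morphometry onto assignments; one row per bud, ordered by label.

    Columns: bud_label, parent_label, gap_px, diameter_ratio, length_ratio,
    eccentricity_bud, eccentricity_parent, ambiguous.
    """
    by_label = {r.label: r for r in records}
    rows = []
    for a in sorted(assignments, key=lambda x: x.bud_label):
        try:
            bud = by_label[a.bud_label]
            parent = by_label[a.parent_label]
        except KeyError as exc:
            raise ValueError(f"missing morphometry record for label {exc}") from None
        rows.append(
            {
                "bud_label": a.bud_label,
                "parent_label": a.parent_label,
                "gap_px": a.gap_px,
                "diameter_ratio": a.diameter_ratio,
                "length_ratio": bud.length_um / parent.length_um,
                "eccentricity_bud": bud.eccentricity,
                "eccentricity_parent": parent.eccentricity,
                "ambiguous": a.ambiguous,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "bud_label",
            "parent_label",
            "gap_px",
            "diameter_ratio",
            "length_ratio",
            "eccentricity_bud",
            "eccentricity_parent",
            "ambiguous",
        ],
    )
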