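"""Synthetic bright-field scene generator with exact ground truth.

Renders bright-field-like images — bright background, slightly brighter cell
interior, dark cell-wall band, optional linear illumination gradient,
Gaussian blur and additive noise — together with the exact label map and a
truth table of the commanded geometry, for three organism classes: straight
or arc-bent rods (fission yeast), ellipse mothers with attached circular
buds (budding yeast), and sinusoidal tubes (worms). Rendering is a pure
function of (parameters, seed).

Default calibration is 0.1 µm/px for yeast scenes (≈ 60× objective on a CCD)
and 1.0 µm/px for worm scenes. Blur is a Gaussian proxy for defocus; no
optical PSF physics is attempted.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from scipy.spatial import cKDTree

from .image import CalibratedImage
from .segment import LabelMap


# ---------------------------------------------------------------------------
# parameters and scene container
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RenderParams:
    """Photometric rendering knobs (intensities on the [0, 1] scale)."""

    wall_width_px: float = 3.0
    wall_intensity: float = 0.30
    interior_intensity: float = 0.88
    background_intensity: float = 0.78
    illumination_gradient: float = 0.1  # relative amplitude of the linear ramp
    noise_sd: float = 0.01
    blur_sigma_px: float = 0.7


#: worms are imaged at low magnification with strongly uneven illumination
WORM_RENDER = RenderParams(
    wall_width_px=4.0,
    illumination_gradient=0.3,
    blur_sigma_px=1.0,
)


@dataclass
class SyntheticScene:
    """A rendered scene plus its exact ground truth."""

    image: CalibratedImage
    truth_labels: LabelMap
    truth_table: pd.DataFrame
    params: dict
    channels: dict = field(default_factory=dict)
    centerlines: dict = field(default_factory=dict)  # label -> (K, 2) px polyline

    @property
    def raw(self) -> np.ndarray:
        """Raw raster for the pipeline: (H, W, 3) RGB, or 2-D for gray scenes."""
        if "gray" in self.channels:
            return self.channels["gray"]
        return np.stack(
            [self.channels["red"], self.channels["green"], self.channels["blue"]],
            axis=-1,
        )


# ---------------------------------------------------------------------------
# analytic geometry of the commanded shapes
# ---------------------------------------------------------------------------

def capsule_moment_axes(length_um: float, width_um: float) -> tuple[float, float]:
    """Moment-ellipse major/minor axis lengths of an ideal capsule.

    A capsule (rectangle of length L−W capped by half-disks of radius W/2) is
    the commanded footprint of a straight rod with tip-to-tip length L and
    width W. Its moment-matched ellipse axes are what the morphometry module
    measures; the closed form lets commanded and measured values be compared
    like-for-like.
    """
    L, W = float(length_um), float(width_um)
    if L < W:
        raise ValueError("capsule requires length >= width")
    r = W / 2.0
    c = L - W
    area = c * W + math.pi * r * r
    half = math.pi * r**2 / 2.0
    xbar_a = (2.0 / 3.0) * r**3  # ∫x dA over one half-disk about its flat edge
    # each half-disk, shifted to x = c/2: ∫(x + c/2)² dA = πr⁴/8 + c·x̄A + (c/2)²A
    i_long = c**3 * W / 12.0 + 2.0 * (
        math.pi * r**4 / 8.0 + c * xbar_a + (c / 2.0) ** 2 * half
    )
    i_trans = c * W**3 / 12.0 + 2.0 * (math.pi * r**4 / 8.0)
    return 4.0 * math.sqrt(i_long / area), 4.0 * math.sqrt(i_trans / area)


def _resample(points: np.ndarray, spacing: float = 0.35) -> np.ndarray:
    """Resample a polyline at roughly uniform arc-length spacing (px)."""
    d = np.sqrt(((np.diff(points, axis=0)) ** 2).sum(axis=1))
    s = np.concatenate([[0.0], np.cumsum(d)])
    if s[-1] == 0:
        return points[:1]
    t = np.arange(0.0, s[-1] + spacing / 2, spacing)
    return np.column_stack(
        [np.interp(t, s, points[:, 0]), np.interp(t, s, points[:, 1])]
    )


def polyline_length(points: np.ndarray) -> float:
    return float(np.sqrt(((np.diff(points, axis=0)) ** 2).sum(axis=1)).sum())


# ---------------------------------------------------------------------------
# paintable cell shapes (signed distance in px; negative inside)
# ---------------------------------------------------------------------------

class _Capsule:
    """Tube of constant width around a centerline polyline."""

    def __init__(self, poly_px: np.ndarray, half_width_px: float):
        self.poly = _resample(np.asarray(poly_px, dtype=float))
        self.hw = float(half_width_px)
        self.tree = cKDTree(self.poly)

    def bbox(self, pad: float) -> tuple[float, float, float, float]:
        p = self.hw + pad
        return (
            self.poly[:, 0].min() - p,
            self.poly[:, 0].max() + p,
            self.poly[:, 1].min() - p,
            self.poly[:, 1].max() + p,
        )

    def sdf(self, pts: np.ndarray) -> np.ndarray:
        d, _ = self.tree.query(pts)
        return d - self.hw


class _Ellipse:
    """Filled ellipse: semi-axes (a, b) px, orientation psi."""

    def __init__(self, center, a, b, psi):
        self.center = np.asarray(center, dtype=float)
        self.a, self.b, self.psi = float(a), float(b), float(psi)
        t = np.linspace(0, 2 * math.pi, 720, endpoint=False)
        local = np.column_stack([self.a * np.cos(t), self.b * np.sin(t)])
        rot = np.array(
            [[math.cos(psi), -math.sin(psi)], [math.sin(psi), math.cos(psi)]]
        )
        self.boundary = local @ rot.T + self.center
        self.tree = cKDTree(self.boundary)

    def bbox(self, pad: float):
        p = max(self.a, self.b) + pad
        return (
            self.center[0] - p,
            self.center[0] + p,
            self.center[1] - p,
            self.center[1] + p,
        )

    def sdf(self, pts: np.ndarray) -> np.ndarray:
        d, _ = self.tree.query(pts)
        rel = pts - self.center
        c, s = math.cos(self.psi), math.sin(self.psi)
        u = rel[:, 0] * c + rel[:, 1] * s
        v = -rel[:, 0] * s + rel[:, 1] * c
        inside = (u / self.a) ** 2 + (v / self.b) ** 2 < 1.0
        return np.where(inside, -d, d)


class _Circle:
    def __init__(self, center, r):
        self.center = np.asarray(center, dtype=float)
        self.r = float(r)

    def bbox(self, pad: float):
        p = self.r + pad
        return (
            self.center[0] - p,
            self.center[0] + p,
            self.center[1] - p,
            self.center[1] + p,
        )

    def sdf(self, pts: np.ndarray) -> np.ndarray:
        return np.sqrt(((pts - self.center) ** 2).sum(axis=1)) - self.r


# ---------------------------------------------------------------------------
# painting and finishing
# ---------------------------------------------------------------------------

def _paint(shape: tuple[int, int], cells: list, wall_width_px: float):
    """Rasterize cells: per-pixel min signed distance and argmin labels."""
    h, w = shape
    best = np.full(shape, np.inf)
    labels = np.zeros(shape, dtype=np.int32)
    pad = wall_width_px + 3.0
    for i, cell in enumerate(cells, start=1):
        r0, r1, c0, c1 = cell.bbox(pad)
        r0 = max(0, int(math.floor(r0)))
        c0 = max(0, int(math.floor(c0)))
        r1 = min(h, int(math.ceil(r1)) + 1)
        c1 = min(w, int(math.ceil(c1)) + 1)
        if r0 >= r1 or c0 >= c1:
            continue
        rr, cc = np.mgrid[r0:r1, c0:c1]
        pts = np.column_stack([rr.ravel(), cc.ravel()]).astype(float)
        sdf = cell.sdf(pts).reshape(rr.shape)
        sub_best = best[r0:r1, c0:c1]
        sub_lab = labels[r0:r1, c0:c1]
        better = sdf < sub_best
        sub_lab[better & (sdf < 0)] = i
        np.minimum(sub_best, sdf, out=sub_best)
    return best, labels


def _render_channels(
    best_sdf: np.ndarray,
    rp: RenderParams,
    rng: np.random.Generator,
    channel_names: tuple[str, ...],
) -> dict:
    """Clean field -> illumination ramp -> blur -> per-channel noise."""
    field_img = np.full(best_sdf.shape, rp.background_intensity)
    field_img[best_sdf < -rp.wall_width_px / 2.0] = rp.interior_intensity
    field_img[np.abs(best_sdf) <= rp.wall_width_px / 2.0] = rp.wall_intensity
    if rp.illumination_gradient > 0:
        w = best_sdf.shape[1]
        ramp = 1.0 + rp.illumination_gradient * (
            np.arange(w) / max(1, w - 1) - 0.5
        )
        field_img = field_img * ramp[None, :]
    if rp.blur_sigma_px > 0:
        field_img = ndi.gaussian_filter(field_img, rp.blur_sigma_px, mode="reflect")
    out = {}
    for name in channel_names:
        ch = field_img
        if rp.noise_sd > 0:
            ch = ch + rng.normal(0.0, rp.noise_sd, field_img.shape)
        out[name] = np.clip(ch, 0.0, 1.0)
    return out


def _finish_scene(
    cells, shape, pixel_size_um, rp, rng, channel_names, truth_table, centerlines, params
) -> SyntheticScene:
    best, labels = _paint(shape, cells, rp.wall_width_px)
    channels = _render_channels(best, rp, rng, channel_names)
    main = channels["gray"] if "gray" in channels else channels["blue"]
    ch_name = "gray" if "gray" in channels else "blue"
    return SyntheticScene(
        image=CalibratedImage(main, pixel_size_um, channel=ch_name, inverted=False),
        truth_labels=LabelMap(labels, pixel_size_um),
        truth_table=truth_table,
        params=params,
        channels=channels,
        centerlines=centerlines,
    )


class PlacementError(RuntimeError):
    """Raised when non-overlapping placement fails after bounded retries."""


# ---------------------------------------------------------------------------
# rod scenes (fission yeast)
# ---------------------------------------------------------------------------

def _poly_clearance(poly, hw, placed):
    """Smallest boundary gap between a candidate tube and the placed tubes."""
    gap = np.inf
    for other_poly_tree, other_hw in placed:
        d, _ = other_poly_tree.query(poly)
        gap = min(gap, float(d.min()) - hw - other_hw)
    return gap


def generate_rod_scene(
    n: int,
    length_range_um: tuple[float, float] = (7.0, 14.0),
    width_range_um: tuple[float, float] = (3.5, 4.5),
    curvature_range: tuple[float, float] = (0.0, 0.0),
    crowding: str = "sparse",
    seed: int = 0,
    render_params: RenderParams | None = None,
    shape: tuple[int, int] = (512, 512),
    pixel_size_um: float = 0.1,
) -> SyntheticScene:
    """Scene of capsule-shaped (optionally arc-bent) rod cells.

    ``crowding="sparse"`` keeps every cell clear of its neighbours;
    ``"touching"`` places cells in cliques of up to four laterally tangent
    rods (shared walls), with cliques mutually separated. Length is commanded
    tip-to-tip; curvature is in 1/µm along the centerline.
    """
    if crowding not in ("sparse", "touching"):
        raise ValueError(f"crowding must be 'sparse' or 'touching', got {crowding!r}")
    rp = render_params or RenderParams()
    rng = np.random.default_rng(seed)
    h, w = shape
    border = rp.wall_width_px + 6.0

    def sample_geometry():
        L = rng.uniform(*length_range_um) / pixel_size_um
        W = rng.uniform(*width_range_um) / pixel_size_um
        L = max(L, W + 2.0)
        kappa = rng.uniform(*curvature_range) * pixel_size_um  # 1/px
        return L, W, kappa

    placed_trees: list[tuple[cKDTree, float]] = []
    cells: list[_Capsule] = []
    rows = []
    centerlines: dict[int, np.ndarray] = {}
    clearance = 4.0 if crowding == "sparse" else 6.0

    def try_place(polys_hws, max_tries=400):
        """Rigidly place a group of centerlines (in local coords) at random."""
        extent = max(
            float(np.abs(p).max()) + hw for p, hw in polys_hws
        )
        for _ in range(max_tries):
            theta = rng.uniform(0, 2 * math.pi)
            margin = extent + border
            if margin * 2 >= min(h, w):
                continue
            cy = rng.uniform(margin, h - 1 - margin)
            cx = rng.uniform(margin, w - 1 - margin)
            c, s = math.cos(theta), math.sin(theta)
            rot = np.array([[s, c], [c, -s]])  # local (x, y) -> (row, col)
            world = []
            ok = True
            for p, hw_i in polys_hws:
                q = p @ rot.T + np.array([cy, cx])
                if (
                    q[:, 0].min() < border
                    or q[:, 0].max() > h - 1 - border
                    or q[:, 1].min() < border
                    or q[:, 1].max() > w - 1 - border
                ):
                    ok = False
                    break
                world.append(q)
            if not ok:
                continue
            if all(
                _poly_clearance(q, hw_i, placed_trees)
                >= rp.wall_width_px + clearance
                for q, (_, hw_i) in zip(world, polys_hws)
            ):
                return world
        raise PlacementError(
            f"could not place cells after {max_tries} tries; lower n or enlarge the image"
        )

    remaining = n
    while remaining > 0:
        if crowding == "sparse":
            k = 1
        else:
            k = int(min(remaining, rng.integers(2, 5)))
        world = None
        while world is None:
            group = []
            offset = 0.0
            prev_hw = None
            for j in range(k):
                L, W, kappa = sample_geometry()
                hw = W / 2.0
                centerline = L - W
                if prev_hw is not None:
                    offset += prev_hw + hw  # lateral tangency: boundary gap 0
                jitter = rng.uniform(-0.1, 0.1) * centerline
                n_pts = max(2, int(centerline / 0.5) + 1)
                t = np.linspace(-centerline / 2.0, centerline / 2.0, n_pts)
                if kappa > 0:
                    radius = 1.0 / kappa
                    phi = t / radius
                    x = radius * np.sin(phi) + jitter
                    y = radius * (1.0 - np.cos(phi)) + offset
                else:
                    x = t + jitter
                    y = np.full_like(t, offset)
                local = np.column_stack([x, y])
                group.append((local, hw, L, W, kappa))
                prev_hw = hw
            polys_hws = [(g[0], g[1]) for g in group]
            try:
                world = try_place(polys_hws)
            except PlacementError:
                if k == 1:
                    raise  # even a single cell does not fit
                k -= 1  # a crowded clique may not fit late in the packing
        for (local, hw, L, W, kappa), q in zip(group, world):
            label = len(cells) + 1
            q = _resample(q)
            cells.append(_Capsule(q, hw))
            placed_trees.append((cells[-1].tree, hw))
            centerlines[label] = q
            length_um = L * pixel_size_um
            width_um = W * pixel_size_um
            straight = kappa == 0
            mL, mW = (
                capsule_moment_axes(length_um, width_um)
                if straight
                else (np.nan, np.nan)
            )
            rows.append(
                {
                    "label": label,
                    "length_um": length_um,
                    "width_um": width_um,
                    "centerline_length_um": polyline_length(q) * pixel_size_um,
                    "curvature_per_um": kappa / pixel_size_um,
                    "moment_length_um": mL,
                    "moment_width_um": mW,
                }
            )
        remaining -= k

    truth = pd.DataFrame(
        rows,
        columns=[
            "label",
            "length_um",
            "width_um",
            "centerline_length_um",
            "curvature_per_um",
            "moment_length_um",
            "moment_width_um",
        ],
    )
    params = {
        "kind": "rod",
        "n": n,
        "seed": seed,
        "crowding": crowding,
        "shape": list(shape),
        "pixel_size_um": pixel_size_um,
        "render": asdict(rp),
    }
    return _finish_scene(
        cells, shape, pixel_size_um, rp, rng,
        ("blue", "green", "red"), truth, centerlines, params,
    )


# ---------------------------------------------------------------------------
# budding scenes
# ---------------------------------------------------------------------------

def generate_budding_scene(
    n_mothers: int,
    bud_fraction: float = 0.6,
    seed: int = 0,
    render_params: RenderParams | None = None,
    shape: tuple[int, int] = (512, 512),
    pixel_size_um: float = 0.1,
) -> SyntheticScene:
    """Ellipse mothers with tangent circular buds; truth records adjacency.

    Bud diameters are drawn at 0.35–0.55 of the mother's equivalent diameter,
    and the bud is placed tangent to the mother boundary along the local
    outward normal, sharing a wall at the neck. Mothers are mutually well
    separated so every bud touches exactly one candidate parent.
    """
    if not 0 <= bud_fraction <= 1:
        raise ValueError("bud_fraction must lie in [0, 1]")
    rp = render_params or RenderParams()
    rng = np.random.default_rng(seed)
    h, w = shape
    border = rp.wall_width_px + 6.0

    # sample every mother's geometry up front and pack largest-first: big
    # footprints are by far the hardest to place late in a crowded field
    geoms = []
    for _ in range(n_mothers):
        r_eq = rng.uniform(22.0, 28.0)
        q = rng.uniform(1.25, 1.5)
        a, b = r_eq * math.sqrt(q), r_eq / math.sqrt(q)
        psi = rng.uniform(0, math.pi)
        has_bud = rng.uniform() < bud_fraction
        rb = rng.uniform(0.35, 0.55) * r_eq if has_bud else 0.0
        geoms.append((a, b, psi, r_eq, has_bud, rb))
    geoms.sort(key=lambda g: -(g[0] + 2 * g[5]))

    mothers = []  # (center, a, b, psi, r_eq, bud or None)
    max_reach = []
    for a, b, psi, r_eq, has_bud, rb in geoms:
        reach = a + 2 * rb + border
        placedq = False
        for _ in range(800):
            cy = rng.uniform(reach, h - 1 - reach)
            cx = rng.uniform(reach, w - 1 - reach)
            if all(
                math.hypot(cy - m[0][0], cx - m[0][1])
                >= reach + mr + rp.wall_width_px + 6.0
                for m, mr in zip(mothers, max_reach)
            ):
                placedq = True
                break
        if not placedq:
            raise PlacementError(
                "could not place mother cells; lower n_mothers or enlarge the image"
            )
        bud = None
        if has_bud:
            tau = rng.uniform(0, 2 * math.pi)
            c, s = math.cos(psi), math.sin(psi)
            # boundary point and outward normal of the ellipse at parameter tau
            local_p = np.array([a * math.cos(tau), b * math.sin(tau)])
            local_n = np.array([math.cos(tau) / a, math.sin(tau) / b])
            local_n /= np.linalg.norm(local_n)
            rot = np.array([[c, -s], [s, c]])
            p_world = rot @ local_p + np.array([cy, cx])
            n_world = rot @ local_n
            bud_center = p_world + rb * n_world
            bud = (bud_center, rb)
        mothers.append(((cy, cx), a, b, psi, r_eq, bud))
        max_reach.append(a + 2 * rb)

    cells = []
    rows = []
    for (center, a, b, psi, r_eq, bud) in mothers:
        mother_label = len(cells) + 1
        cells.append(_Ellipse(center, a, b, psi))
        rows.append(
            {
                "label": mother_label,
                "kind": "mother",
                "parent_label": np.nan,
                "equiv_diameter_um": 2.0 * math.sqrt(a * b) * pixel_size_um,
                "diameter_ratio": np.nan,
                "axis_ratio": a / b,
            }
        )
        if bud is not None:
            bud_center, rb = bud
            bud_label = len(cells) + 1
            cells.append(_Circle(bud_center, rb))
            rows.append(
                {
                    "label": bud_label,
                    "kind": "bud",
                    "parent_label": mother_label,
                    "equiv_diameter_um": 2.0 * rb * pixel_size_um,
                    "diameter_ratio": rb / math.sqrt(a * b),
                    "axis_ratio": 1.0,
                }
            )

    truth = pd.DataFrame(
        rows,
        columns=[
            "label",
            "kind",
            "parent_label",
            "equiv_diameter_um",
            "diameter_ratio",
            "axis_ratio",
        ],
    )
    params = {
        "kind": "budding",
        "n_mothers": n_mothers,
        "bud_fraction": bud_fraction,
        "seed": seed,
        "shape": list(shape),
        "pixel_size_um": pixel_size_um,
        "render": asdict(rp),
    }
    return _finish_scene(
        cells, shape, pixel_size_um, rp, rng,
        ("blue", "green", "red"), truth, {}, params,
    )


# ---------------------------------------------------------------------------
# worm scenes
# ---------------------------------------------------------------------------

def generate_worm_scene(
    n_worms: int = 2,
    tube_length_um: float = 600.0,
    amplitude_um: float = 45.0,
    width_um: float = 25.0,
    wavelength_um: float = 220.0,
    seed: int = 0,
    render_params: RenderParams | None = None,
    shape: tuple[int, int] = (768, 768),
    pixel_size_um: float = 1.0,
) -> SyntheticScene:
    """Sinusoidal-centerline tubes of constant width, non-overlapping.

    ``tube_length_um`` is the commanded tip-to-tip worm length (the
    centerline is shorter by one width; the rounded caps add half a width at
    each end). The truth table stores the exact centerline arc length. A
    strong illumination gradient is on by default to exercise background
    flattening.
    """
    rp = render_params or WORM_RENDER
    rng = np.random.default_rng(seed)
    h, w = shape
    border = rp.wall_width_px + 6.0

    W_px = width_um / pixel_size_um
    centerline_px = (tube_length_um - width_um) / pixel_size_um
    if centerline_px <= 0:
        raise ValueError("tube_length_um must exceed width_um")
    A_px = amplitude_um / pixel_size_um
    k = 2 * math.pi / (wavelength_um / pixel_size_um)

    def sinusoid(phase):
        dx = 0.5
        xs = [0.0]
        ys = [A_px * math.sin(phase)]
        arc = 0.0
        while arc < centerline_px:
            x = xs[-1] + dx
            y = A_px * math.sin(k * x + phase)
            arc += math.hypot(dx, y - ys[-1])
            xs.append(x)
            ys.append(y)
        pts = np.column_stack([xs, ys])
        return pts - pts.mean(axis=0)

    placed: list[tuple[cKDTree, float]] = []
    cells = []
    rows = []
    centerlines = {}
    for i in range(n_worms):
        phase = rng.uniform(0, 2 * math.pi)
        local = sinusoid(phase)
        ok = False
        for _ in range(400):
            theta = rng.uniform(0, 2 * math.pi)
            c, s = math.cos(theta), math.sin(theta)
            rot = np.array([[s, c], [c, -s]])
            span = np.abs(local).max() + W_px / 2 + border
            if span * 2 >= min(h, w):
                span = min(h, w) / 2 - 1
            cy = rng.uniform(span, h - 1 - span) if span < h - 1 - span else h / 2
            cx = rng.uniform(span, w - 1 - span) if span < w - 1 - span else w / 2
            world = local @ rot.T + np.array([cy, cx])
            if (
                world[:, 0].min() < border + W_px / 2
                or world[:, 0].max() > h - 1 - border - W_px / 2
                or world[:, 1].min() < border + W_px / 2
                or world[:, 1].max() > w - 1 - border - W_px / 2
            ):
                continue
            if _poly_clearance(world, W_px / 2, placed) >= rp.wall_width_px + 10.0:
                ok = True
                break
        if not ok:
            raise PlacementError(
                "could not place worms; lower n_worms or enlarge the image"
            )
        label = len(cells) + 1
        world = _resample(world)
        cells.append(_Capsule(world, W_px / 2))
        placed.append((cells[-1].tree, W_px / 2))
        centerlines[label] = world
        rows.append(
            {
                "label": label,
                "tube_length_um": tube_length_um,
                "centerline_length_um": polyline_length(world) * pixel_size_um,
                "amplitude_um": amplitude_um,
                "width_um": width_um,
            }
        )

    truth = pd.DataFrame(
        rows,
        columns=[
            "label",
            "tube_length_um",
            "centerline_length_um",
            "amplitude_um",
            "width_um",
        ],
    )
    params = {
        "kind": "worm",
        "n_worms": n_worms,
        "tube_length_um": tube_length_um,
        "amplitude_um": amplitude_um,
        "width_um": width_um,
        "wavelength_um": wavelength_um,
        "seed": seed,
        "shape": list(shape),
        "pixel_size_um": pixel_size_um,
        "render": asdict(rp),
    }
    return _finish_scene(
        cells, shape, pixel_size_um, rp, rng, ("gray",), truth, centerlines, params
    )
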