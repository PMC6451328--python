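"""Per-species parameter bundles.

A :class:`SpeciesProfile` collects every tunable the segmentation chain needs
for one organism class. The fission-yeast numbers (Gaussian sigma 0.5 px,
adaptive sensitivity 0.35, minimum wall-component area 150 px, closing radius
2 px, blue channel) are the published operating point for ~0.1 µm/px
bright-field imaging; the budding-yeast and worm profiles keep the same chain
but swap the denoiser (total variation) respectively add background
flattening (tophat), with sizes rescaled to the organism.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import yaml

from .image import CHANNELS

SPECIES = ("fission_yeast", "budding_yeast", "worm")
DENOISERS = ("gaussian", "total_variation")


@dataclass(frozen=True)
class SpeciesProfile:
    species: str
    channels: tuple[str, ...]
    gaussian_sigma_px: float = 0.5
    adaptive_sensitivity: float = 0.35
    min_object_area_px: int = 150
    closing_radius_px: int = 2
    denoiser: str = "gaussian"
    tv_weight: float | None = None
    tophat_radius_px: int | None = None
    bud_area_threshold_px: int | None = None
    # smallest plausible cell-interior (foreground-marker) area; defaults to
    # half the minimum wall-component area when unset
    min_marker_area_px: int | None = None

    def __post_init__(self) -> None:
        if self.species not in SPECIES:
            raise ValueError(f"unknown species {self.species!r}")
        if self.denoiser not in DENOISERS:
            raise ValueError(f"unknown denoiser {self.denoiser!r}")
        object.__setattr__(self, "channels", tuple(self.channels))
        for ch in self.channels:
            if ch not in CHANNELS:
                raise ValueError(f"unknown channel {ch!r}")
        if self.gaussian_sigma_px < 0:
            raise ValueError("gaussian_sigma_px must be >= 0")
        if not (0 < self.adaptive_sensitivity < 1):
            raise ValueError("adaptive_sensitivity must lie in (0, 1)")
        if self.min_object_area_px <= 0 or self.closing_radius_px <= 0:
            raise ValueError("min_object_area_px and closing_radius_px must be positive")
        if self.denoiser == "total_variation" and not (self.tv_weight or 0) > 0:
            raise ValueError("total_variation denoiser requires tv_weight > 0")
        if self.species == "worm" and not (self.tophat_radius_px or 0) > 0:
            raise ValueError("worm profile requires tophat_radius_px > 0")

    def replace(self, **overrides) -> "SpeciesProfile":
        return dataclasses.replace(self, **overrides)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["channels"] = list(self.channels)
        return d

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_dict(cls, d: dict) -> "SpeciesProfile":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown profile fields: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SpeciesProfile":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


# Published fission-yeast operating point: blue channel, Gaussian 0.5 px,
# sensitivity 35%, components < 150 px removed, 2 px disk closing.
FISSION_YEAST = SpeciesProfile(
    species="fission_yeast",
    channels=("blue",),
)

# Budding yeast: TV denoising, markers built on green and blue separately and
# OR-merged; morphological sizes reduced for the smaller cells.
BUDDING_YEAST = SpeciesProfile(
    species="budding_yeast",
    channels=("green", "blue"),
    denoiser="total_variation",
    tv_weight=0.1,
    min_object_area_px=100,
    closing_radius_px=2,
)

# Worm: grayscale input, tophat background flattening (large fields of view
# have strongly non-uniform illumination), sizes scaled to ~1 µm/px.
# even an L1 larva (~100 x 15 µm) encloses well over 1000 px² of interior at
# ~1 µm/px, so smaller enclosed regions are imaging artifacts
WORM = SpeciesProfile(
    species="worm",
    channels=("gray",),
    gaussian_sigma_px=1.0,
    min_object_area_px=300,
    closing_radius_px=3,
    tophat_radius_px=25,
    min_marker_area_px=1000,
)

DEFAULT_PROFILES = {
    "fission_yeast": FISSION_YEAST,
    "budding_yeast": BUDDING_YEAST,
    "worm": WORM,
}


def get_profile(species: str) -> SpeciesProfile:
    try:
        return DEFAULT_PROFILES[species]
    except KeyError:
        raise ValueError(f"unknown species {species!r}; expected one of {SPECIES}") from None
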