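"""Calibrated single-channel image container.

All pipeline stages operate on :class:`CalibratedImage`: a 2-D float array of
intensities in [0, 1] carrying its spatial calibration (µm per pixel) and the
provenance of the channel it was extracted from. The ``inverted`` flag records
whether the image has been flipped so that cell walls are bright on a dark
background, which is the orientation the binarization and watershed stages
expect.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

#: valid channel names; "gray" is reserved for 2-D (single-plane) input.
CHANNELS = ("red", "green", "blue", "gray")

#: index of each color channel in an (H, W, 3) RGB raster.
CHANNEL_INDEX = {"red": 0, "green": 1, "blue": 2}

MIN_DIM = 16


@dataclass(frozen=True)
class CalibratedImage:
    """A 2-D intensity raster in [0, 1] with µm/pixel calibration.

    Parameters
    ----------
    pixels
        2-D float array with finite values in [0, 1]; both dimensions must be
        at least 16 pixels.
    pixel_size_um
        Physical size of one pixel side, in micrometres (> 0).
    channel
        Which plane of the raw raster the pixels came from.
    inverted
        True once the image has been inverted (walls bright).
    """

    pixels: np.ndarray
    pixel_size_um: float
    channel: str = "gray"
    inverted: bool = False

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=np.float64)
        if px.ndim != 2:
            raise ValueError(f"pixels must be 2-D, got shape {px.shape}")
        if min(px.shape) < MIN_DIM:
            raise ValueError(
                f"image dimensions must be >= {MIN_DIM} px, got {px.shape}"
            )
        if not np.all(np.isfinite(px)):
            raise ValueError("pixels contain non-finite values")
        if px.min() < 0.0 or px.max() > 1.0:
            raise ValueError("pixel values must lie in [0, 1]")
        if not (self.pixel_size_um > 0):
            raise ValueError(f"pixel_size_um must be > 0, got {self.pixel_size_um}")
        if self.channel not in CHANNELS:
            raise ValueError(f"unknown channel {self.channel!r}")
        object.__setattr__(self, "pixels", px)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]

    def with_pixels(self, pixels: np.ndarray, *, inverted: bool | None = None) -> "CalibratedImage":
        """Return a copy with new pixel data (same calibration/channel)."""
        inv = self.inverted if inverted is None else inverted
        return replace(self, pixels=pixels, inverted=inv)
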