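"""Shared fixtures and small drawing helpers for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from brightmorph import CalibratedImage
from brightmorph.segment import LabelMap


def make_image(pixels, pixel_size_um=0.1, channel="gray", inverted=False):
    return CalibratedImage(
        np.asarray(pixels, dtype=float), pixel_size_um, channel=channel, inverted=inverted
    )


def mask_to_labels(mask, pixel_size_um=0.1):
    """A single-object boolean mask as a LabelMap."""
    return LabelMap(np.asarray(mask, dtype=bool).astype(np.int32), pixel_size_um)


def ring_mask(shape, center, inner, outer):
    """Annulus (closed wall) mask."""
    yy, xx = np.mgrid[: shape[0], : shape[1]]
    d = np.hypot(yy - center[0], xx - center[1])
    return (d >= inner) & (d <= outer)


def rect_ring(shape, top, left, height, width, thickness=2):
    """Rectangular wall ring."""
    m = np.zeros(shape, dtype=bool)
    m[top : top + height, left : left + width] = True
    m[
        top + thickness : top + height - thickness,
        left + thickness : left + width - thickness,
    ] = False
    return m


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
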