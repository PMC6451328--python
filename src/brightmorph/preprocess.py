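"""Preprocessing: channel selection, inversion/stretch, denoising, flattening.

The chain converts a raw micrograph into the inverted, contrast-adjusted,
denoised (and, for worms, background-flattened) single-channel image on which
binarization and the watershed operate. Every operation maps [0, 1] images to
[0, 1] images, preserves shape and calibration, and uses reflective boundary
handling so the image frame does not manufacture spurious wall pixels.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy import ndimage as ndi
from skimage import morphology
from skimage.restoration import denoise_tv_chambolle

from .image import CHANNEL_INDEX, CalibratedImage

log = logging.getLogger(__name__)


def _bit_depth_max(arr: np.ndarray) -> float:
    """Container-type maximum used for normalization (255 / 65535 / 1.0).

    Dividing by the dtype maximum rather than the observed maximum keeps
    absolute intensity comparable across images.
    """
    if np.issubdtype(arr.dtype, np.integer):
        return float(np.iinfo(arr.dtype).max)
    if np.issubdtype(arr.dtype, np.floating):
        return 1.0
    raise ValueError(f"unsupported raster dtype {arr.dtype}")


def select_channel(raw_image: np.ndarray, channel: str, pixel_size_um: float) -> CalibratedImage:
    """Extract one plane of a raw raster and rescale it to [0, 1].

    ``channel="gray"`` is only valid for 2-D input; color channels require an
    (H, W, 3) raster.
    """
    raw = np.asarray(raw_image)
    if raw.ndim == 2:
        if channel != "gray":
            raise ValueError(
                f"channel {channel!r} requested but image is 2-D grayscale; use channel='gray'"
            )
        plane = raw
    elif raw.ndim == 3 and raw.shape[2] == 3:
        if channel not in CHANNEL_INDEX:
            raise ValueError(
                f"channel {channel!r} invalid for a 3-plane color image; "
                f"expected one of {sorted(CHANNEL_INDEX)}"
            )
        plane = raw[:, :, CHANNEL_INDEX[channel]]
    else:
        raise ValueError(
            f"raw image must be 2-D or (H, W, 3); got shape {raw.shape}"
        )
    scale = _bit_depth_max(plane)
    pixels = np.clip(plane.astype(np.float64) / scale, 0.0, 1.0)
    return CalibratedImage(pixels, pixel_size_um, channel=channel, inverted=False)


def invert_and_stretch(img: CalibratedImage, min_range: float = 0.15) -> CalibratedImage:
    """Invert intensities (walls become bright) and robustly stretch contrast.

    The stretch maps the 1st percentile of the inverted image to 0 and the
    99th to 1, clipping outside; robust to hot pixels. If the robust range
    falls below ``min_range`` (default 15% of full scale, well below the
    inverted wall contrast of any usable bright-field image but above what
    illumination gradients and noise produce on an empty field) the image
    carries no wall contrast to amplify
    (an effectively blank or constant field: stretching would only blow up
    noise), so it is returned inverted but unstretched, with a warning.
    """
    if img.inverted:
        raise ValueError("image is already inverted")
    inv = 1.0 - img.pixels
    p1, p99 = np.percentile(inv, [1.0, 99.0])
    if p99 - p1 < min_range:
        log.warning(
            "robust intensity range %.3f below %.2f (blank or constant image): "
            "contrast stretch skipped",
            p99 - p1,
            min_range,
        )
        return img.with_pixels(inv, inverted=True)
    out = np.clip((inv - p1) / (p99 - p1), 0.0, 1.0)
    return img.with_pixels(out, inverted=True)


def gaussian_denoise(img: CalibratedImage, sigma_px: float) -> CalibratedImage:
    """Gaussian smoothing with reflective boundaries; sigma 0 is the identity."""
    if sigma_px < 0:
        raise ValueError(f"sigma_px must be >= 0, got {sigma_px}")
    if sigma_px == 0:
        return img
    out = ndi.gaussian_filter(img.pixels, sigma=sigma_px, mode="reflect")
    return img.with_pixels(np.clip(out, 0.0, 1.0))


def tv_denoise(img: CalibratedImage, weight: float) -> CalibratedImage:
    """Total-variation (ROF-style) regularized smoothing.

    Edge-preserving: the total variation of the output never exceeds that of
    the input, which keeps thin cell walls sharp while removing noise.
    """
    if not weight > 0:
        raise ValueError(f"tv weight must be > 0, got {weight}")
    out = denoise_tv_chambolle(img.pixels, weight=weight)
    return img.with_pixels(np.clip(out, 0.0, 1.0))


def tophat_flatten(img: CalibratedImage, radius_px: int) -> CalibratedImage:
    """White tophat with a disk: remove background structure wider than the disk.

    Subtracting the morphological opening flattens illumination ramps that are
    broader than the structuring element while retaining thin bright features
    (the cell walls). Requires an inverted (foreground-bright) image.
    """
    if radius_px <= 0:
        raise ValueError(f"tophat radius must be > 0, got {radius_px}")
    if not img.inverted:
        raise ValueError("tophat_flatten expects an inverted (walls-bright) image")
    # decomposed disk footprint: same flattening, far cheaper for large radii
    footprint = morphology.disk(radius_px, decomposition="sequence")
    out = morphology.white_tophat(img.pixels, footprint=footprint)
    return img.with_pixels(np.clip(out, 0.0, 1.0))
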