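"""Image preprocessing: margin cropping, zero padding to square, resizing.

The pipeline order is fixed: crop → zero-pad to square → resize to the
network input side. Downscaling uses local-mean (area) averaging,
upscaling anti-aliased bilinear interpolation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.transform import resize, resize_local_mean

from .records import CohortManifest

__all__ = ["CropSpec", "crop_margins", "zero_pad_square", "resize_to_input",
           "preprocess_image", "preprocess_cohort"]


@dataclass(frozen=True)
class CropSpec:
    """Pixels to strip from each edge (metadata margins)."""

    top: int = 0
    bottom: int = 0
    left: int = 0
    right: int = 0

    def __post_init__(self):
        if min(self.top, self.bottom, self.left, self.right) < 0:
            raise ValueError("crop margins must be non-negative")


def crop_margins(pixels: np.ndarray, crop: CropSpec) -> np.ndarray:
    h, w = pixels.shape
    if crop.top + crop.bottom >= h or crop.left + crop.right >= w:
        raise ValueError(
            f"over-crop: margins {crop} leave no pixels of a {h}x{w} image")
    return pixels[crop.top: h - crop.bottom, crop.left: w - crop.right]


def zero_pad_square(pixels: np.ndarray) -> np.ndarray:
    """Pad with zeros to N x N, N = max(h, w), content centred (floor offsets)."""
    h, w = pixels.shape
    n = max(h, w)
    if h == w:
        return pixels
    top = (n - h) // 2
    left = (n - w) // 2
    out = np.zeros((n, n), dtype=pixels.dtype)
    out[top: top + h, left: left + w] = pixels
    return out


def resize_to_input(pixels: np.ndarray, side: int) -> np.ndarray:
    """Resize a square image to side x side, returning uint8 in [0, 255]."""
    h, w = pixels.shape
    if h != w:
        raise ValueError(f"resize_to_input requires a square image, got {h}x{w}; "
                         "run zero_pad_square first")
    if h == side:
        return pixels.astype(np.uint8)
    img = pixels.astype(np.float64)
    if side < h:
        out = resize_local_mean(img, (side, side))
    else:
        out = resize(img, (side, side), order=1, anti_aliasing=False, preserve_range=True)
    return np.clip(np.round(out), 0, 255).astype(np.uint8)


def preprocess_image(pixels: np.ndarray, crop: CropSpec | None = None,
                     side: int = 180) -> np.ndarray:
    cropped = crop_margins(pixels, crop) if crop is not None else pixels
    return resize_to_input(zero_pad_square(cropped), side)


def preprocess_cohort(manifest: CohortManifest, crop: CropSpec | None = None,
                      side: int = 180) -> CohortManifest:
    recs = [r.with_pixels(preprocess_image(r.pixels, crop, side)) for r in manifest]
    return CohortManifest(recs, split=manifest.split)
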