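"""Random per-epoch augmentation: spatial warps and brightness/noise.

Spatial augmentation draws zoom, shear, shift, rotation and a flip
independently for every image and applies them as one composed affine
warp (bilinear, zero fill) so the image is resampled only once.
Brightness/noise augmentation scales the [0, 1] image by a factor in
``brightness_range`` (factor > 1 brightens) and adds i.i.d. Gaussian
noise, then clips. Stored images are never modified: an augment stream
yields fresh views each epoch.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

import numpy as np
from skimage.transform import AffineTransform, warp

from .records import CohortManifest, ImageRecord

__all__ = ["AugmentPolicy", "spatial_augment", "brightness_noise_augment",
           "augment_record", "augment_stream"]


@dataclass(frozen=True)
class AugmentPolicy:
    zoom_range: float = 0.10
    shear_range: float = 0.10          # shear factor, not degrees
    shift_range: float = 0.10          # fraction of the image side
    horizontal_flip: bool = True
    rotation_range: float = 30.0       # degrees
    brightness_range: tuple[float, float] = (0.7, 1.3)
    noise_variance: float = 0.01       # on the [0, 1] intensity scale
    enabled_groups: frozenset = frozenset({"spatial"})

    def __post_init__(self):
        if min(self.zoom_range, self.shear_range, self.shift_range,
               self.rotation_range, self.noise_variance) < 0:
            raise ValueError("augmentation ranges must be non-negative")
        if self.brightness_range[0] > self.brightness_range[1]:
            raise ValueError("brightness_range must be (low, high) with low <= high")
        unknown = set(self.enabled_groups) - {"spatial", "brightness_noise"}
        if unknown:
            raise ValueError(f"unknown augmentation groups {unknown}")


def policy_from_name(name: str) -> AugmentPolicy | None:
    groups = {"spatial": {"spatial"}, "brightness_noise": {"brightness_noise"},
              "both": {"spatial", "brightness_noise"}, "none": None}[name]
    return None if groups is None else AugmentPolicy(enabled_groups=frozenset(groups))


def spatial_augment(pixels: np.ndarray, policy: AugmentPolicy,
                    rng: np.random.Generator) -> np.ndarray:
    side_y, side_x = pixels.shape
    zoom = rng.uniform(1.0 - policy.zoom_range, 1.0 + policy.zoom_range)
    shear = rng.uniform(-policy.shear_range, policy.shear_range)
    tx = rng.uniform(-policy.shift_range, policy.shift_range) * side_x
    ty = rng.uniform(-policy.shift_range, policy.shift_range) * side_y
    flip = policy.horizontal_flip and rng.random() < 0.5
    angle = np.deg2rad(rng.uniform(-policy.rotation_range, policy.rotation_range))

    centre = np.array([(side_x - 1) / 2.0, (side_y - 1) / 2.0])
    to_centre = AffineTransform(translation=-centre)
    core = (AffineTransform(scale=(zoom, zoom))
            + AffineTransform(shear=np.arctan(shear))
            + AffineTransform(rotation=angle))
    back = AffineTransform(translation=centre + np.array([tx, ty]))
    tform = to_centre + core + back
    out = warp(pixels.astype(np.float64) / 255.0, tform.inverse, order=1,
               mode="constant", cval=0.0)
    if flip:
        out = out[:, ::-1]
    return np.clip(np.round(out * 255.0), 0, 255).astype(np.uint8)


def brightness_noise_augment(pixels: np.ndarray, policy: AugmentPolicy,
                             rng: np.random.Generator) -> np.ndarray:
    img = pixels.astype(np.float64) / 255.0
    factor = rng.uniform(*policy.brightness_range)
    img = img * factor
    if policy.noise_variance > 0:
        img = img + rng.normal(0.0, np.sqrt(policy.noise_variance), img.shape)
    return np.clip(np.round(np.clip(img, 0.0, 1.0) * 255.0), 0, 255).astype(np.uint8)


def augment_record(record: ImageRecord, policy: AugmentPolicy | None,
                   rng: np.random.Generator) -> ImageRecord:
    if policy is None:
        return record
    pixels = record.pixels
    if "spatial" in policy.enabled_groups:
        pixels = spatial_augment(pixels, policy, rng)
    if "brightness_noise" in policy.enabled_groups:
        pixels = brightness_noise_augment(pixels, policy, rng)
    return record.with_pixels(pixels)


def augment_stream(dataset: CohortManifest, policy: AugmentPolicy | None,
                   seed: int) -> Iterator[list[ImageRecord]]:
    """Yield one freshly augmented view of the dataset per epoch, forever."""
    rng = np.random.default_rng(seed)
    while True:
        if policy is None:
            yield list(dataset.records)
        else:
            yield [augment_record(r, policy, rng) for r in dataset]
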