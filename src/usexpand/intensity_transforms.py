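"""Histogram specification against pooled class histograms, and equalization.

Histogram specification remaps an image so that its intensity
distribution matches a pooled 256-bin target built from all training
images of one class in the target domain. The mapping is the classical
CDF/quantile composition x -> Q_target(F_image(x)), which is monotone
non-decreasing in intensity. Equalization is the special case of a
uniform target: x -> round(255 * F_image(x)).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .records import CLASSES, CohortManifest

__all__ = ["ClassHistogram", "pooled_class_histogram", "match_image_to_histogram",
           "equalize"]

_LEVELS = 256


@dataclass
class ClassHistogram:
    """Pooled intensity histogram of one class (256 bins over 0-255)."""

    class_label: str
    bin_counts: np.ndarray

    def __post_init__(self):
        self.bin_counts = np.asarray(self.bin_counts, dtype=np.int64)
        if self.bin_counts.shape != (_LEVELS,):
            raise ValueError("bin_counts must have 256 entries")
        if (self.bin_counts < 0).any() or self.bin_counts.sum() <= 0:
            raise ValueError("bin_counts must be non-negative with positive total")

    @property
    def n_pixels(self) -> int:
        return int(self.bin_counts.sum())

    def cdf(self) -> np.ndarray:
        return np.cumsum(self.bin_counts) / self.n_pixels

    def quantile(self, p: np.ndarray) -> np.ndarray:
        """Smallest intensity whose CDF is >= p (right-continuous inverse)."""
        return np.searchsorted(self.cdf(), np.asarray(p), side="left").clip(0, _LEVELS - 1)

    def median(self) -> int:
        return int(self.quantile(np.array(0.5)))

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame({"intensity": np.arange(_LEVELS), "count": self.bin_counts}).to_csv(
            path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, class_label: str) -> "ClassHistogram":
        df = pd.read_csv(path)
        counts = np.zeros(_LEVELS, dtype=np.int64)
        counts[df["intensity"].to_numpy()] = df["count"].to_numpy()
        return cls(class_label, counts)


def pooled_class_histogram(images: CohortManifest, class_label: str) -> ClassHistogram:
    """Sum the 256-bin histograms of every image of one class."""
    if class_label not in CLASSES:
        raise ValueError(f"unknown class {class_label!r}")
    counts = np.zeros(_LEVELS, dtype=np.int64)
    found = 0
    for rec in images:
        if rec.class_label != class_label:
            continue
        counts += np.bincount(rec.pixels.astype(np.uint8).ravel(), minlength=_LEVELS)
        found += 1
    if found == 0:
        raise ValueError(f"no images of class {class_label!r} to pool")
    return ClassHistogram(class_label, counts)


def _image_cdf(pixels: np.ndarray) -> np.ndarray:
    counts = np.bincount(pixels.astype(np.uint8).ravel(), minlength=_LEVELS)
    return np.cumsum(counts) / pixels.size


def match_image_to_histogram(pixels: np.ndarray, target: ClassHistogram) -> np.ndarray:
    """Remap intensities so the image's histogram matches the target.

    A degenerate single-intensity image has no usable empirical CDF
    shape; by convention every pixel then maps to the target's median.
    """
    pixels = np.asarray(pixels)
    if pixels.min() == pixels.max():
        return np.full_like(pixels, target.median(), dtype=np.uint8)
    lut = target.quantile(_image_cdf(pixels)).astype(np.uint8)
    return lut[pixels.astype(np.uint8)]


def equalize(pixels: np.ndarray) -> np.ndarray:
    """Global histogram equalization: x -> round(255 * F(x))."""
    pixels = np.asarray(pixels)
    lut = np.round(255.0 * _image_cdf(pixels)).astype(np.uint8)
    return lut[pixels.astype(np.uint8)]
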