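"""Seeded two-domain, three-class B-mode phantom generator.

Emulates the statistical structure of a dual-device breast-ultrasound
cohort: a cart-based "standard" domain and a point-of-care ("pocus")
domain that is darker (gamma compression) and noisier, three visually
separable classes, and patient-grouped images.

The image model, in order:

1. an echogenicity map — uniform background with low-frequency
   horizontal banding (tissue layers);
2. a lesion: benign = smooth ellipse with reduced echogenicity and
   posterior enhancement; malignant = irregular, taller-than-wide region
   (harmonically perturbed boundary) with stronger echo reduction and a
   posterior acoustic shadow;
3. fully developed speckle — the echogenicity map times the squared
   magnitude of a PSF-smoothed complex Gaussian field (Rayleigh
   envelope);
4. log compression and rescaling to [0, 1];
5. the domain operator (identity + mild noise for standard; gamma
   darkening + additive Gaussian noise for pocus);
6. optional burnt-in caliper-like annotation glyphs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

from .records import CLASSES, CohortManifest, ImageRecord

__all__ = ["PhantomConfig", "generate_phantom", "apply_domain_shift", "generate_cohort"]


@dataclass
class PhantomConfig:
    """Parameters of the phantom model; defaults are the study conditions."""

    image_side: int = 180
    background_echogenicity: float = 0.55
    banding_amplitude: float = 0.12
    speckle_psf_sigma: float = 1.5
    lesion_radius_range: tuple[float, float] = (0.12, 0.22)  # fraction of side
    malignant_boundary_harmonics: int = 5
    malignant_boundary_amplitude: float = 0.25
    benign_intensity_multiplier: float = 0.45
    malignant_intensity_multiplier: float = 0.25
    posterior_enhancement: float = 1.35
    shadow_attenuation: float = 0.55
    log_gain: float = 30.0
    standard_noise_sigma: float = 0.01
    pocus_gamma: float = 1.8
    pocus_noise_sigma: float = 0.06
    annotation_probability: float = 0.0
    contralateral_probability: float = 0.15
    heterogeneity: float = 0.3
    seed: int = 0

    def __post_init__(self):
        if self.image_side < 32:
            raise ValueError("image_side must be at least 32")
        if not self.pocus_gamma >= 1.0:
            raise ValueError("pocus_gamma must be >= 1 (the pocus operator darkens)")
        if not 0.0 <= self.heterogeneity < 1.0:
            raise ValueError("heterogeneity must lie in [0, 1)")
        for name in ("annotation_probability", "contralateral_probability"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        for name in ("benign_intensity_multiplier", "malignant_intensity_multiplier",
                     "shadow_attenuation", "background_echogenicity"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ValueError(f"{name} must lie in (0, 1], got {v}")


def desk_config(**overrides) -> PhantomConfig:
    """Small-image preset used by fast experiments and tests."""
    defaults = dict(image_side=64, speckle_psf_sigma=1.0)
    defaults.update(overrides)
    return PhantomConfig(**defaults)


# ---------------------------------------------------------------------------
# domain operator


def apply_domain_shift(pixels: np.ndarray, domain: str, config: PhantomConfig,
                       rng: np.random.Generator) -> np.ndarray:
    """Apply the device-specific intensity operator to a [0, 1] image.

    standard: identity plus mild sensor noise. pocus: gamma compression
    (exponent > 1 pushes mass toward the dark end, as point-of-care
    probes do) followed by additive zero-mean Gaussian noise.
    """
    pixels = np.asarray(pixels, dtype=np.float64)
    # drawn for both domains so paired renders stay aligned on one seed
    jit = _jitter(config, rng)
    if domain == "standard":
        out = pixels + rng.normal(0.0, config.standard_noise_sigma, pixels.shape)
    elif domain == "pocus":
        gamma = 1.0 + (config.pocus_gamma - 1.0) * jit
        out = np.power(np.clip(pixels, 0.0, 1.0), gamma)
        if config.pocus_noise_sigma > 0:
            out = out + rng.normal(0.0, config.pocus_noise_sigma, pixels.shape)
    else:
        raise ValueError(f"unknown domain {domain!r}; expected 'standard' or 'pocus'")
    return np.clip(out, 0.0, 1.0)


# ---------------------------------------------------------------------------
# phantom construction


def _jitter(config: PhantomConfig, rng: np.random.Generator) -> float:
    """Per-image multiplicative spread: 1 + heterogeneity * U(-1, 1)."""
    return 1.0 + config.heterogeneity * rng.uniform(-1.0, 1.0)


def _echogenicity_map(side: int, config: PhantomConfig, rng: np.random.Generator) -> np.ndarray:
    rows = np.arange(side)[:, None]
    emap = np.full((side, side), config.background_echogenicity)
    # two to three layer-like horizontal bands at random phase/frequency
    for _ in range(rng.integers(2, 4)):
        freq = rng.uniform(1.0, 3.0) * 2 * np.pi / side
        phase = rng.uniform(0, 2 * np.pi)
        emap = emap * (1.0 + config.banding_amplitude * np.sin(freq * rows + phase))
    return np.clip(emap, 0.05, 1.0)


def _lesion_mask(side: int, config: PhantomConfig, rng: np.random.Generator,
                 irregular: bool) -> tuple[np.ndarray, tuple[int, int], int]:
    """Soft [0,1] lesion mask, its centre, and its lower row extent."""
    r0 = rng.uniform(*config.lesion_radius_range) * side
    cy = int(rng.uniform(0.3, 0.6) * side)
    cx = int(rng.uniform(0.3, 0.7) * side)
    yy, xx = np.mgrid[0:side, 0:side]
    dy, dx = yy - cy, xx - cx
    theta = np.arctan2(dy, dx)
    if irregular:
        # taller than wide with a jagged, harmonically perturbed boundary
        radius = np.hypot(dy, dx * rng.uniform(1.25, 1.6))
        boundary = np.ones_like(theta) * r0
        for k in range(2, 2 + config.malignant_boundary_harmonics):
            amp = config.malignant_boundary_amplitude / config.malignant_boundary_harmonics
            boundary = boundary * (1.0 + amp * np.cos(k * theta + rng.uniform(0, 2 * np.pi)))
        edge_softness = 1.0
    else:
        # smooth ellipse, wider than tall
        radius = np.hypot(dy * rng.uniform(1.1, 1.4), dx)
        boundary = np.full_like(theta, r0)
        edge_softness = 2.5
    mask = 1.0 / (1.0 + np.exp((radius - boundary) / edge_softness))
    bottom = min(side - 1, int(cy + 1.3 * r0))
    return mask, (cy, cx), bottom


def _posterior_band(emap: np.ndarray, mask: np.ndarray, bottom: int, factor: float) -> np.ndarray:
    """Scale the column band below the lesion by ``factor`` (enhance or shadow)."""
    col_weight = mask.max(axis=0)  # lateral footprint of the lesion
    band = np.ones_like(emap)
    band[bottom:, :] = 1.0 + (factor - 1.0) * col_weight[None, :]
    return emap * band


def _speckle(emap: np.ndarray, config: PhantomConfig, rng: np.random.Generator) -> np.ndarray:
    re = gaussian_filter(rng.normal(size=emap.shape), config.speckle_psf_sigma)
    im = gaussian_filter(rng.normal(size=emap.shape), config.speckle_psf_sigma)
    intensity = emap * (re ** 2 + im ** 2)
    compressed = np.log1p(config.log_gain * intensity)
    return compressed / np.log1p(config.log_gain * 1.5)  # nominal full scale


def _burn_annotations(img01: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    out = img01.copy()
    side = out.shape[0]
    for _ in range(rng.integers(1, 4)):
        cy = int(rng.uniform(0.1, 0.9) * side)
        cx = int(rng.uniform(0.1, 0.9) * side)
        arm = max(2, side // 45)
        out[max(0, cy - arm): cy + arm + 1, cx] = 1.0
        out[cy, max(0, cx - arm): cx + arm + 1] = 1.0
    return out


def render_phantom_field(class_label: str, config: PhantomConfig,
                         rng: np.random.Generator,
                         return_mask: bool = False):
    """Device-independent [0, 1] image: steps 1–4 of the model.

    With ``return_mask=True`` also returns the soft lesion mask (all
    zeros for the normal class), for region-statistics checks.
    """
    if class_label not in CLASSES:
        raise ValueError(f"unknown class label {class_label!r}; expected one of {CLASSES}")
    side = config.image_side
    emap = np.clip(_jitter(config, rng), 0.6, 1.4) * _echogenicity_map(side, config, rng)
    mask = np.zeros((side, side))
    if class_label == "benign":
        mask, _, bottom = _lesion_mask(side, config, rng, irregular=False)
        mult = np.clip(config.benign_intensity_multiplier * _jitter(config, rng), 0.05, 0.95)
        emap = emap * (1.0 - (1.0 - mult) * mask)
        emap = _posterior_band(emap, mask, bottom, config.posterior_enhancement)
    elif class_label == "malignant":
        mask, _, bottom = _lesion_mask(side, config, rng, irregular=True)
        mult = np.clip(config.malignant_intensity_multiplier * _jitter(config, rng), 0.05, 0.95)
        emap = emap * (1.0 - (1.0 - mult) * mask)
        emap = _posterior_band(emap, mask, bottom, config.shadow_attenuation)
    out = np.clip(_speckle(emap, config, rng), 0.0, 1.0)
    return (out, mask) if return_mask else out


def generate_phantom(class_label: str, domain: str, config: PhantomConfig | None = None,
                     rng: np.random.Generator | int = 0, *,
                     patient_id: str = "p0") -> ImageRecord:
    """Generate one phantom image record.

    ``rng`` may be a seed or a Generator. The device-independent field is
    drawn first, then the domain operator: two calls that share a seed
    but differ in domain render the same underlying tissue.
    """
    config = config or PhantomConfig()
    rng = np.random.default_rng(rng) if isinstance(rng, (int, np.integer)) else rng
    field01 = render_phantom_field(class_label, config, rng)
    shifted = apply_domain_shift(field01, domain, config, rng)
    if config.annotation_probability > 0 and rng.random() < config.annotation_probability:
        shifted = _burn_annotations(shifted, rng)
    pixels = np.round(shifted * 255.0).astype(np.uint8)
    return ImageRecord(pixels, class_label, domain, patient_id, provenance="synthetic")


# ---------------------------------------------------------------------------
# cohorts


def _allocate_classes(n_patients: int, class_mix: dict[str, float],
                      rng: np.random.Generator) -> list[str]:
    """Largest-remainder allocation of patients to primary classes, shuffled."""
    if abs(sum(class_mix.values()) - 1.0) > 1e-6:
        raise ValueError("class_mix must sum to 1")
    quotas = {c: n_patients * f for c, f in class_mix.items()}
    counts = {c: int(np.floor(q)) for c, q in quotas.items()}
    short = n_patients - sum(counts.values())
    for c in sorted(quotas, key=lambda c: quotas[c] - counts[c], reverse=True)[:short]:
        counts[c] += 1
    labels = [c for c, k in counts.items() for _ in range(k)]
    rng.shuffle(labels)
    return labels


def generate_cohort(n_patients: int, images_per_patient_range: tuple[int, int] = (1, 3),
                    class_mix: dict[str, float] | None = None, domain: str = "pocus",
                    config: PhantomConfig | None = None, seed: int = 0,
                    patient_prefix: str | None = None) -> CohortManifest:
    """Generate a patient-grouped cohort of phantom images.

    Each patient carries one primary finding class; lesion patients may
    additionally contribute a normal image (contralateral acquisition).
    Same seed, same arguments → bit-identical manifest.
    """
    if n_patients < 1:
        raise ValueError("n_patients must be >= 1")
    config = config or PhantomConfig()
    class_mix = class_mix or {"normal": 1 / 3, "benign": 1 / 3, "malignant": 1 / 3}
    for c in class_mix:
        if c not in CLASSES:
            raise ValueError(f"unknown class {c!r} in class_mix")
    rng = np.random.default_rng(seed)
    prefix = patient_prefix if patient_prefix is not None else f"{domain[:3]}{seed}"
    primaries = _allocate_classes(n_patients, class_mix, rng)
    lo, hi = images_per_patient_range
    records: list[ImageRecord] = []
    for i, primary in enumerate(primaries):
        pid = f"{prefix}-{i:04d}"
        n_images = int(rng.integers(lo, hi + 1))
        for _ in range(n_images):
            records.append(generate_phantom(primary, domain, config, rng, patient_id=pid))
        if primary != "normal" and rng.random() < config.contralateral_probability:
            records.append(generate_phantom("normal", domain, config, rng, patient_id=pid))
    return CohortManifest(records)
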