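"""Synthetic straightened-cord images with known punctum ground truth.

The fixture emulates a straightened linescan: a uniform bright band (the
cord) over a darker background, carrying isotropic 2D Gaussian puncta
centered on the mid-row, plus optional Gaussian or Poisson noise, quantized
to the requested bit depth.  Everything is seeded and bit-reproducible.

``low_contrast_variant`` shrinks punctum amplitude and width to emulate
markers whose puncta barely rise above the cord fluorescence — the regime
where fixed-parameter detection visibly under-counts.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace

import numpy as np

from punctaline.image_io import depth_max
from punctaline.measure import FWHM_FACTOR
from punctaline.straighten import StraightenedImage

__all__ = [
    "SynthSpec",
    "SyntheticGroundTruth",
    "generate",
    "low_contrast_variant",
    "standard_fixture_spec",
]


@dataclass(frozen=True)
class SynthSpec:
    """Recipe for one synthetic straightened image.

    ``punctum_positions_px`` may be None, in which case positions are drawn
    uniformly with at least ``min_separation_px`` between neighbors.
    """

    length_px: int = 512
    width_px: int = 15
    background_level: float = 20.0
    background_noise_sd: float = 0.0
    cord_level: float = 10.0
    n_puncta: int = 0
    punctum_amplitudes: tuple[float, ...] = ()
    punctum_sigmas_px: tuple[float, ...] = ()
    punctum_positions_px: tuple[float, ...] | None = ()
    min_separation_px: float = 20.0
    noise_model: str = "gaussian"
    bit_depth: int | str = 8
    pixel_size: float | None = None
    seed: int = 0
    image_id: str = "synthetic"

    def __post_init__(self):
        if self.length_px < 1 or self.width_px < 1:
            raise ValueError("image dimensions must be positive")
        if self.background_level < 0 or self.cord_level < 0 or self.background_noise_sd < 0:
            raise ValueError("levels and noise SD must be >= 0")
        if self.noise_model not in ("gaussian", "poisson"):
            raise ValueError("noise_model must be 'gaussian' or 'poisson'")
        for name in ("punctum_amplitudes", "punctum_sigmas_px"):
            vals = getattr(self, name)
            object.__setattr__(self, name, tuple(float(v) for v in vals))
            if len(getattr(self, name)) != self.n_puncta:
                raise ValueError(f"{name} must have n_puncta entries")
        if any(a <= 0 for a in self.punctum_amplitudes):
            raise ValueError("amplitudes must be > 0")
        if self.punctum_positions_px is not None:
            pos = tuple(float(v) for v in self.punctum_positions_px)
            object.__setattr__(self, "punctum_positions_px", pos)
            if len(pos) != self.n_puncta:
                raise ValueError("punctum_positions_px must have n_puncta entries")


@dataclass(frozen=True)
class SyntheticGroundTruth:
    """True punctum parameters of a generated image."""

    image_id: str
    centers_px: tuple[float, ...]
    sigmas_px: tuple[float, ...]
    fwhms_px: tuple[float, ...]
    amplitudes: tuple[float, ...]
    n_puncta: int
    length_px: int


def _draw_positions(rng: np.random.Generator, spec: SynthSpec) -> tuple[float, ...]:
    lo = 2.0 * max(spec.punctum_sigmas_px, default=0.0)
    hi = spec.length_px - lo
    if hi <= lo:
        raise ValueError("image too short for requested puncta")
    positions: list[float] = []
    for _ in range(10_000):
        cand = float(rng.uniform(lo, hi))
        if all(abs(cand - p) >= spec.min_separation_px for p in positions):
            positions.append(cand)
            if len(positions) == spec.n_puncta:
                return tuple(sorted(positions))
    raise ValueError("could not place puncta with the requested separation")


def generate(spec: SynthSpec) -> tuple[StraightenedImage, SyntheticGroundTruth]:
    """Render a synthetic straightened image and its ground-truth table."""
    rng = np.random.default_rng(spec.seed)
    if spec.punctum_positions_px is None:
        positions = _draw_positions(rng, spec)
    else:
        positions = spec.punctum_positions_px
        seps = [abs(a - b) for a, b in zip(positions, positions[1:])]
        if any(s < spec.min_separation_px for s in seps):
            warnings.warn("explicit punctum positions closer than min separation", stacklevel=2)
    rows = np.arange(spec.width_px, dtype=float)[:, None]
    cols = np.arange(spec.length_px, dtype=float)[None, :]
    mid_row = (spec.width_px - 1) / 2.0
    img = np.full(
        (spec.width_px, spec.length_px), spec.background_level + spec.cord_level, dtype=float
    )
    for center, amp, sigma in zip(positions, spec.punctum_amplitudes, spec.punctum_sigmas_px):
        img += amp * np.exp(-((rows - mid_row) ** 2 + (cols - center) ** 2) / (2.0 * sigma**2))
    if spec.noise_model == "poisson":
        img = rng.poisson(img).astype(float)
    elif spec.background_noise_sd > 0:
        img = img + rng.normal(0.0, spec.background_noise_sd, img.shape)
    if spec.bit_depth != "float":
        img = np.rint(np.clip(img, 0.0, depth_max(spec.bit_depth)))
    else:
        img = np.maximum(img, 0.0)
    truth = SyntheticGroundTruth(
        image_id=spec.image_id,
        centers_px=positions,
        sigmas_px=spec.punctum_sigmas_px,
        fwhms_px=tuple(FWHM_FACTOR * s for s in spec.punctum_sigmas_px),
        amplitudes=spec.punctum_amplitudes,
        n_puncta=spec.n_puncta,
        length_px=spec.length_px,
    )
    image = StraightenedImage(
        pixels=img,
        image_id=spec.image_id,
        pixel_size=spec.pixel_size,
        bit_depth=spec.bit_depth,
    )
    return image, truth


def low_contrast_variant(spec: SynthSpec, contrast_factor: float) -> SynthSpec:
    """Shrink puncta toward the cord level to emulate a low-contrast marker.

    Amplitudes scale by ``contrast_factor``; widths shrink by its square
    root (small dim puncta are also narrow).  factor 1 returns the spec
    unchanged.
    """
    if not 0 < contrast_factor <= 1:
        raise ValueError("contrast_factor must be in (0, 1]")
    return replace(
        spec,
        punctum_amplitudes=tuple(a * contrast_factor for a in spec.punctum_amplitudes),
        punctum_sigmas_px=tuple(s * math.sqrt(contrast_factor) for s in spec.punctum_sigmas_px),
    )


def standard_fixture_spec(
    seed: int = 0,
    n_puncta: int = 20,
    noise_sd: float = 257.0,
    image_id: str = "synthetic",
) -> SynthSpec:
    """The well-resolved reference fixture used throughout the test suite.

    20 puncta at fixed 40 px spacing, amplitudes 25700-41120 (>= 100x the
    default noise SD), sigma 1.5-3 px, 16-bit, on a background + cord
    pedestal of 7710.  Levels are the classic 8-bit regime scaled by 257 so
    the normalized intensities seen by the local threshold are unchanged
    while quantization error is negligible for the FWHM fits.
    """
    rng = np.random.default_rng(seed)
    spacing = 40.0
    positions = tuple(40.0 + spacing * i for i in range(n_puncta))
    length = int(positions[-1] + 60)
    return SynthSpec(
        length_px=length,
        width_px=15,
        background_level=20.0 * 257.0,
        background_noise_sd=noise_sd,
        cord_level=10.0 * 257.0,
        n_puncta=n_puncta,
        punctum_amplitudes=tuple(rng.uniform(100.0 * 257.0, 160.0 * 257.0, n_puncta)),
        punctum_sigmas_px=tuple(rng.uniform(1.5, 3.0, n_puncta)),
        punctum_positions_px=positions,
        min_separation_px=30.0,
        noise_model="gaussian",
        bit_depth=16,
        pixel_size=None,
        seed=seed,
        image_id=image_id,
    )
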