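"""Per-punctum measurement: intensity profile, Gaussian fit, FWHM, discard rule.

Intensities are always measured on the original (unblurred) straightened
image; the blur in the detection chain exists only to stabilize the
threshold.  The profile of an ROI is the per-column mean over its bounding
box rows (horizontal plot-profile semantics on a rectangle).

A 4-parameter Gaussian ``y = a + (b - a) * exp(-(x - c)^2 / (2 d^2))`` is
fit by unweighted least squares.  FWHM = 2*sqrt(2 ln 2)*d.  A punctum whose
fitted FWHM exceeds its ROI width — the classic one-sided-ramp misfit — is
flagged ``discard = 1``; the caller may filter those rows or replace the
FWHM with the ROI width.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from punctaline.detect import PunctumROI
from punctaline.straighten import StraightenedImage

__all__ = [
    "FWHM_FACTOR",
    "IntensityProfile",
    "GaussianFit",
    "PunctumRecord",
    "extract_profile",
    "fit_gaussian",
    "fwhm_from_fit",
    "measure_puncta",
]

#: FWHM of a Gaussian of unit standard deviation
FWHM_FACTOR = 2.0 * math.sqrt(2.0 * math.log(2.0))


@dataclass(frozen=True)
class IntensityProfile:
    """Left-to-right intensity profile across an ROI's bounding box."""

    positions: np.ndarray  # column indices, px
    values: np.ndarray  # per-column mean intensity

    def __post_init__(self):
        pos = np.asarray(self.positions, dtype=float)
        val = np.asarray(self.values, dtype=float)
        if pos.shape != val.shape or pos.ndim != 1 or pos.size < 1:
            raise ValueError("positions and values must be matching 1D arrays")
        object.__setattr__(self, "positions", pos)
        object.__setattr__(self, "values", val)


@dataclass(frozen=True)
class GaussianFit:
    """Fitted parameters of y = a + (b - a) exp(-(x - c)^2 / (2 d^2))."""

    a: float
    b: float
    c: float
    d: float
    converged: bool

    def predict(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        return self.a + (self.b - self.a) * np.exp(-((x - self.c) ** 2) / (2.0 * self.d**2))


@dataclass(frozen=True)
class PunctumRecord:
    """Measurements for one punctum, matching the per-punctum output CSV."""

    image_id: str
    roi_id: int
    roi_width: float
    max_intensity: float
    fwhm: float  # NaN when the fit failed and no replacement was requested
    discard: int
    fwhm_replaced: bool
    units: str  # "um" or "px" for roi_width and fwhm


def _gauss(x, a, b, c, d):
    return a + (b - a) * np.exp(-((x - c) ** 2) / (2.0 * d * d))


def extract_profile(img: StraightenedImage, roi: PunctumROI) -> IntensityProfile:
    """Column means of the original image over the ROI's bounding-box rows."""
    r0, c0, h, w = roi.bbox
    rows, cols = img.pixels.shape
    if r0 < 0 or c0 < 0 or r0 + h > rows or c0 + w > cols:
        raise ValueError(f"ROI bbox {roi.bbox} outside image of shape {img.pixels.shape}")
    block = np.asarray(img.pixels, dtype=float)[r0 : r0 + h, c0 : c0 + w]
    return IntensityProfile(positions=np.arange(c0, c0 + w, dtype=float), values=block.mean(axis=0))


def fit_gaussian(profile: IntensityProfile, max_iter: int = 1000) -> GaussianFit:
    """Least-squares 4-parameter Gaussian fit of an intensity profile.

    Initialization: a = min, b = max, c = argmax position, d = span / 4.
    Profiles shorter than 4 samples, optimizer failures, and non-finite or
    non-positive widths all yield ``converged=False``.
    """
    x = profile.positions
    y = profile.values
    if x.size < 4 or np.ptp(y) == 0:
        return GaussianFit(float(y.min()), float(y.max()), float(x[int(np.argmax(y))]), np.nan, False)
    span = float(x[-1] - x[0]) if x[-1] > x[0] else 1.0
    p0 = (float(y.min()), float(y.max()), float(x[int(np.argmax(y))]), span / 4.0)
    try:
        popt, _ = curve_fit(_gauss, x, y, p0=p0, maxfev=max_iter, xtol=1e-8, ftol=1e-8)
    except (RuntimeError, ValueError):
        return GaussianFit(*p0, converged=False)
    a, b, c, d = (float(v) for v in popt)
    d = abs(d)  # d enters the model squared; report the positive root
    converged = math.isfinite(d) and d > 0 and all(math.isfinite(v) for v in (a, b, c))
    return GaussianFit(a, b, c, d, converged)


def fwhm_from_fit(fit: GaussianFit) -> float:
    """Full width at half maximum of a converged fit, in px; NaN otherwise."""
    if not fit.converged:
        return math.nan
    return FWHM_FACTOR * fit.d


def measure_puncta(
    img: StraightenedImage,
    rois: list[PunctumROI],
    replace_discarded: bool = False,
) -> list[PunctumRecord]:
    """Measure every ROI of a straightened image.

    ``discard = 1`` iff the fitted FWHM exceeds the ROI width or the fit
    failed.  With ``replace_discarded``, discarded FWHMs are replaced by the
    ROI width (and flagged ``fwhm_replaced``).  Widths and FWHM are reported
    in µm when the image is calibrated, else px.
    """
    scale = img.pixel_size if img.pixel_size is not None else 1.0
    units = "um" if img.pixel_size is not None else "px"
    pixels = np.asarray(img.pixels, dtype=float)
    records = []
    for roi in rois:
        profile = extract_profile(img, roi)
        fit = fit_gaussian(profile)
        fwhm_px = fwhm_from_fit(fit)
        roi_width = roi.bbox[3] * scale
        fwhm = fwhm_px * scale if math.isfinite(fwhm_px) else math.nan
        discard = 1 if (not fit.converged or fwhm > roi_width) else 0
        replaced = False
        if replace_discarded and discard == 1:
            fwhm = roi_width
            replaced = True
        max_intensity = float(max(pixels[r, c] for r, c in roi.pixel_set))
        records.append(
            PunctumRecord(
                image_id=img.image_id,
                roi_id=roi.roi_id,
                roi_width=roi_width,
                max_intensity=max_intensity,
                fwhm=fwhm,
                discard=discard,
                fwhm_replaced=replaced,
                units=units,
            )
        )
    return records
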