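"""Punctum detection: Gaussian blur, local adaptive thresholding, size filter.

The detection chain is blur → threshold → connected components → minimum
size filter.  The default thresholding method is Phansalkar's local rule

    foreground  iff  t > mu * (1 + p*exp(-q*mu) + k*(sd/r - 1))

where ``t`` is the pixel intensity normalized to [0, 1] by the bit-depth
maximum and ``mu``/``sd`` are the mean and population standard deviation of
normalized intensities over a circular neighborhood of the given radius,
truncated to in-image pixels at borders.  Defaults k=0.25, r=0.5, p=2, q=10
match the widely used ImageJ plugin.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.measure import label, regionprops

from punctaline.image_io import depth_max
from punctaline.straighten import StraightenedImage

__all__ = [
    "DetectionParams",
    "PunctumROI",
    "PRESETS",
    "disk_footprint",
    "gaussian_blur",
    "phansalkar_threshold",
    "otsu_threshold",
    "find_puncta",
    "detect",
    "preview_settings",
]

SUPPORTED_METHODS = ("phansalkar", "otsu")


@dataclass(frozen=True)
class DetectionParams:
    """The four tunable thresholding settings plus method constants.

    ``min_size`` is a punctum area lower bound in µm² when the image carries
    a pixel size, else px².  ``sigma`` is the blur strength (px), ``radius``
    the local-threshold window radius (px).
    """

    min_size: float = 0.2
    sigma: float = 1.0
    radius: int = 6
    method: str = "phansalkar"
    phansalkar_k: float = 0.25
    phansalkar_r: float = 0.5
    phansalkar_p: float = 2.0
    phansalkar_q: float = 10.0
    connectivity: int = 8

    def __post_init__(self):
        if self.min_size < 0:
            raise ValueError("min_size must be >= 0")
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if self.radius < 1:
            raise ValueError("radius must be >= 1")
        if self.method not in SUPPORTED_METHODS:
            raise ValueError(f"method must be one of {SUPPORTED_METHODS}")
        if self.connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")


#: parameter sets used for the two validation datasets
PRESETS: dict[str, DetectionParams] = {
    "nuIs24": DetectionParams(min_size=0.2, sigma=1.0, radius=6, method="phansalkar"),
    "nuIs152": DetectionParams(min_size=0.3, sigma=0.75, radius=1, method="phansalkar"),
}


@dataclass(frozen=True)
class PunctumROI:
    """One detected punctum: its connected pixel set and tight bounding box.

    ``bbox`` is (row0, col0, height, width), half-open.  ``area`` is the
    component pixel count times pixel_size² when calibrated, else the count.
    """

    roi_id: int
    pixel_set: frozenset[tuple[int, int]]
    bbox: tuple[int, int, int, int]
    area: float
    area_units: str = "px^2"

    @property
    def width(self) -> int:
        return self.bbox[3]


def disk_footprint(radius: int) -> np.ndarray:
    """Boolean disk: offsets (dr, dc) with dr² + dc² <= radius²."""
    rr, cc = np.mgrid[-radius : radius + 1, -radius : radius + 1]
    return (rr * rr + cc * cc) <= radius * radius


def gaussian_blur(img: StraightenedImage, sigma: float) -> StraightenedImage:
    """2D Gaussian blur with reflective boundaries; sigma 0 is the identity."""
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if sigma == 0:
        return img
    blurred = ndimage.gaussian_filter(np.asarray(img.pixels, dtype=float), sigma, mode="reflect")
    return replace(img, pixels=blurred)


def phansalkar_threshold(
    img: StraightenedImage,
    radius: int,
    k: float = 0.25,
    r: float = 0.5,
    p: float = 2.0,
    q: float = 10.0,
) -> np.ndarray:
    """Phansalkar local adaptive threshold; returns a boolean foreground mask.

    Local statistics use a circular window truncated at image borders.
    Normalization is by the bit-depth maximum, so an all-zero image maps to
    an all-background mask without any division by zero.
    """
    if radius < 1:
        raise ValueError("radius must be >= 1")
    t = np.asarray(img.pixels, dtype=np.float64) / depth_max(img.bit_depth)
    footprint = disk_footprint(radius).astype(np.float64)
    counts = ndimage.correlate(np.ones_like(t), footprint, mode="constant", cval=0.0)
    sums = ndimage.correlate(t, footprint, mode="constant", cval=0.0)
    sumsq = ndimage.correlate(t * t, footprint, mode="constant", cval=0.0)
    mu = sums / counts
    var = np.maximum(sumsq / counts - mu * mu, 0.0)
    sd = np.sqrt(var)
    thresh = mu * (1.0 + p * np.exp(-q * mu) + k * (sd / r - 1.0))
    return t > thresh


def otsu_threshold(img: StraightenedImage) -> np.ndarray:
    """Global Otsu threshold, kept as a sanity baseline."""
    pixels = np.asarray(img.pixels, dtype=float)
    if np.ptp(pixels) == 0:
        return np.zeros(pixels.shape, dtype=bool)
    return pixels > threshold_otsu(pixels)


def _roi_sort_key(region) -> tuple[int, int, tuple[int, int]]:
    r0, c0, _, _ = region.bbox
    first_pixel = min((int(a), int(b)) for a, b in region.coords)
    return (c0, r0, first_pixel)


def find_puncta(
    mask: np.ndarray,
    min_size: float,
    pixel_size: float | None = None,
    connectivity: int = 8,
) -> list[PunctumROI]:
    """Connected components of a mask, filtered by minimum area.

    Components with area (µm² when a pixel size is given, else px²) below
    ``min_size`` are dropped.  Survivors are numbered 1..n left-to-right by
    bounding-box left edge (ties: top edge, then first pixel row-major).
    """
    mask = np.asarray(mask, dtype=bool)
    labelled = label(mask, connectivity=2 if connectivity == 8 else 1)
    px_area = pixel_size * pixel_size if pixel_size is not None else 1.0
    units = "um^2" if pixel_size is not None else "px^2"
    regions = [reg for reg in regionprops(labelled) if reg.num_pixels * px_area >= min_size]
    regions.sort(key=_roi_sort_key)
    rois = []
    for i, reg in enumerate(regions, start=1):
        r0, c0, r1, c1 = reg.bbox
        rois.append(
            PunctumROI(
                roi_id=i,
                pixel_set=frozenset((int(a), int(b)) for a, b in reg.coords),
                bbox=(r0, c0, r1 - r0, c1 - c0),
                area=reg.num_pixels * px_area,
                area_units=units,
            )
        )
    return rois


def detect(img: StraightenedImage, params: DetectionParams) -> list[PunctumROI]:
    """Blur, threshold, and extract punctum ROIs from a straightened image."""
    blurred = gaussian_blur(img, params.sigma)
    if params.method == "phansalkar":
        mask = phansalkar_threshold(
            blurred,
            radius=params.radius,
            k=params.phansalkar_k,
            r=params.phansalkar_r,
            p=params.phansalkar_p,
            q=params.phansalkar_q,
        )
    else:
        mask = otsu_threshold(blurred)
    return find_puncta(
        mask,
        min_size=params.min_size,
        pixel_size=img.pixel_size,
        connectivity=params.connectivity,
    )


def detection_mask(img: StraightenedImage, params: DetectionParams) -> np.ndarray:
    """The binary mask the detection chain thresholds ROIs from."""
    blurred = gaussian_blur(img, params.sigma)
    if params.method == "phansalkar":
        return phansalkar_threshold(
            blurred,
            radius=params.radius,
            k=params.phansalkar_k,
            r=params.phansalkar_r,
            p=params.phansalkar_p,
            q=params.phansalkar_q,
        )
    return otsu_threshold(blurred)


def preview_settings(
    img: StraightenedImage, grid: list[DetectionParams]
) -> list[dict]:
    """Evaluate several parameter sets on one image for visual tuning.

    Returns one entry per parameter set with the binary mask and the ROI
    count after size filtering, in grid order.
    """
    if not grid:
        raise ValueError("parameter grid must be nonempty")
    out = []
    for params in grid:
        mask = detection_mask(img, params)
        rois = find_puncta(
            mask,
            min_size=params.min_size,
            pixel_size=img.pixel_size,
            connectivity=params.connectivity,
        )
        out.append({"params": params, "mask": mask, "n_rois": len(rois)})
    return out
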