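"""Image input/output: TIFF reading, maximum-intensity projection, quality crops.

Only baseline grayscale TIFF (single- or multi-page, 8/16-bit or float) is
supported; proprietary microscope formats must be exported to TIFF upstream.
Coordinates are 0-based, row-major; rectangles are half-open.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from fractions import Fraction
from pathlib import Path

import numpy as np
import tifffile

__all__ = [
    "ImageStack",
    "ProjectedImage",
    "CropSpec",
    "Excluded",
    "read_image",
    "max_project",
    "write_projected",
    "apply_crop",
]

#: sentinel bit depth for floating-point images
FLOAT_DEPTH = "float"

_DTYPE_TO_DEPTH = {np.uint8: 8, np.uint16: 16}


def depth_max(bit_depth) -> float:
    """Largest representable intensity for a bit depth (1.0 for float data)."""
    if bit_depth == FLOAT_DEPTH:
        return 1.0
    return float(2 ** int(bit_depth) - 1)


def _validate_pixels(pixels: np.ndarray, bit_depth) -> None:
    if np.any(np.asarray(pixels) < 0):
        raise ValueError("intensities must be non-negative")
    if bit_depth != FLOAT_DEPTH and np.any(pixels > depth_max(bit_depth)):
        raise ValueError(f"intensities exceed 2^{bit_depth} - 1")


@dataclass(frozen=True)
class ImageStack:
    """A z-stack: ``pixels`` has shape (planes, rows, cols)."""

    pixels: np.ndarray
    bit_depth: int | str = 16
    pixel_size: float | None = None  # µm per pixel
    source_id: str = ""

    def __post_init__(self):
        px = np.asarray(self.pixels)
        if px.ndim != 3 or min(px.shape) < 1:
            raise ValueError("stack must be 3D with planes, rows, cols >= 1")
        object.__setattr__(self, "pixels", px)
        _validate_pixels(px, self.bit_depth)
        if self.pixel_size is not None and self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0")

    @property
    def n_planes(self) -> int:
        return self.pixels.shape[0]


@dataclass(frozen=True)
class ProjectedImage:
    """A 2D image, typically the max projection of an :class:`ImageStack`."""

    pixels: np.ndarray
    bit_depth: int | str = 16
    pixel_size: float | None = None
    source_id: str = ""

    def __post_init__(self):
        px = np.asarray(self.pixels)
        if px.ndim != 2 or min(px.shape) < 1:
            raise ValueError("image must be 2D with rows, cols >= 1")
        object.__setattr__(self, "pixels", px)
        _validate_pixels(px, self.bit_depth)
        if self.pixel_size is not None and self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass(frozen=True)
class CropSpec:
    """Quality-control decision for one image: keep (optionally cropped) or exclude.

    ``rectangle`` is (row0, col0, height, width), 0-based half-open.
    ``keep=False`` excludes the image from all downstream tables.
    """

    image_id: str
    rectangle: tuple[int, int, int, int] | None = None
    keep: bool = True


class Excluded:
    """Marker returned by :func:`apply_crop` for images dropped by QC."""

    def __init__(self, image_id: str):
        self.image_id = image_id

    def __repr__(self):
        return f"Excluded({self.image_id!r})"


def max_project(stack: ImageStack) -> ProjectedImage:
    """Maximum-intensity projection over planes.

    A single-plane stack is returned unchanged (its one plane).
    """
    if stack.n_planes < 1:
        raise ValueError("no planes")
    return ProjectedImage(
        pixels=stack.pixels.max(axis=0),
        bit_depth=stack.bit_depth,
        pixel_size=stack.pixel_size,
        source_id=stack.source_id,
    )


def _pixel_size_from_tags(page) -> float | None:
    """µm/px from XResolution + ResolutionUnit, when present and sane."""
    tags = page.tags
    xres = tags.get("XResolution")
    if xres is None:
        return None
    num, den = xres.value
    if num == 0 or den == 0:
        return None
    res = Fraction(int(num), int(den))  # pixels per unit
    unit = tags.get("ResolutionUnit")
    unit_val = unit.value if unit is not None else 2
    unit_val = getattr(unit_val, "value", unit_val)
    # 1 = none (treat as µm, our writer's convention), 2 = inch, 3 = cm
    scale_to_um = {1: 1.0, 2: 25_400.0, 3: 10_000.0}.get(int(unit_val))
    if scale_to_um is None:
        return None
    um_per_px = scale_to_um / float(res)
    return um_per_px if um_per_px > 0 else None


def read_image(path: str | Path) -> ImageStack:
    """Read a single- or multi-page grayscale TIFF as an :class:`ImageStack`."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"{path}: no such file")
    try:
        with tifffile.TiffFile(path) as tif:
            page = tif.pages[0]
            if page.samplesperpixel != 1:
                raise ValueError("RGB/multi-sample images are not supported")
            arr = tif.asarray()
            pixel_size = _pixel_size_from_tags(page)
    except Exception as exc:  # noqa: BLE001 - rewrap with file name
        raise ValueError(f"{path}: cannot be read as TIFF ({exc})") from exc
    if arr.ndim == 2:
        arr = arr[None, :, :]
    if arr.ndim != 3:
        raise ValueError(f"{path}: expected grayscale pages, got shape {arr.shape}")
    dtype = arr.dtype.type
    if dtype in _DTYPE_TO_DEPTH:
        bit_depth = _DTYPE_TO_DEPTH[dtype]
    elif np.issubdtype(arr.dtype, np.floating):
        bit_depth = FLOAT_DEPTH
    else:
        raise ValueError(f"{path}: unsupported dtype {arr.dtype} (8/16-bit or float grayscale only)")
    return ImageStack(pixels=arr, bit_depth=bit_depth, pixel_size=pixel_size, source_id=path.name)


def write_projected(img: ProjectedImage, path: str | Path) -> Path:
    """Write a single-page TIFF preserving bit depth and pixel-size metadata."""
    path = Path(path)
    if not path.parent.exists():
        raise IOError(f"{path.parent}: parent directory does not exist")
    if img.bit_depth == FLOAT_DEPTH:
        data = img.pixels.astype(np.float32)
    else:
        data = img.pixels.astype(np.uint8 if img.bit_depth == 8 else np.uint16)
    kwargs = {}
    if img.pixel_size is not None:
        res = Fraction(1.0 / img.pixel_size).limit_denominator(10**9)
        kwargs["resolution"] = (
            (res.numerator, res.denominator),
            (res.numerator, res.denominator),
        )
        kwargs["resolutionunit"] = 1  # unit "none": pixels per µm by convention
    tifffile.imwrite(path, data, photometric="minisblack", **kwargs)
    return path


def apply_crop(img: ProjectedImage, spec: CropSpec) -> ProjectedImage | Excluded:
    """Apply a QC decision: exclude the image or crop it to a rectangle."""
    if spec.image_id != img.source_id:
        raise ValueError(f"crop spec for {spec.image_id!r} applied to {img.source_id!r}")
    if not spec.keep:
        return Excluded(spec.image_id)
    if spec.rectangle is None:
        return img
    r0, c0, h, w = spec.rectangle
    rows, cols = img.shape
    if r0 < 0 or c0 < 0 or h < 1 or w < 1 or r0 + h > rows or c0 + w > cols:
        raise ValueError(
            f"{spec.image_id}: rectangle {spec.rectangle} outside image of shape {img.shape}"
        )
    return replace(img, pixels=img.pixels[r0 : r0 + h, c0 : c0 + w])
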