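"""Polyline straightening: resample an image along a traced path.

Column ``j`` of the straightened image is the perpendicular cross-section
of the source at arc length ``j`` (pixels) along the polyline, ``width_px``
samples centered on the path, bilinear interpolation.  Sampling step is
exactly 1 px, so the output width is ``round(total arc length)``.

An axis-aligned path with width 1 therefore reproduces the underlying
pixel row/column bit-exactly (no interpolation error), and straightening
a constant image yields that constant.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.ndimage import map_coordinates

from punctaline.image_io import ProjectedImage

__all__ = ["LinePath", "StraightenedImage", "straighten", "path_length_um", "load_paths"]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class LinePath:
    """Ordered polyline tracing a linear structure, with a sampling width.

    ``vertices`` are (row, col) pixel coordinates, fractional allowed.
    ``width_px`` is the perpendicular extent sampled; it must be odd so the
    sampling is symmetric about the path.
    """

    image_id: str
    vertices: tuple[tuple[float, float], ...]
    width_px: int = 1

    def __post_init__(self):
        verts = tuple((float(r), float(c)) for r, c in self.vertices)
        object.__setattr__(self, "vertices", verts)
        if len(verts) < 2:
            raise ValueError("path needs at least 2 vertices")
        for a, b in zip(verts, verts[1:]):
            if a == b:
                raise ValueError("consecutive vertices must be distinct")
        if self.total_length() <= 0:
            raise ValueError("path has zero arc length")
        if self.width_px < 1 or self.width_px % 2 == 0:
            raise ValueError("width_px must be an odd positive integer")

    def segment_lengths(self) -> np.ndarray:
        v = np.asarray(self.vertices)
        return np.hypot(*(v[1:] - v[:-1]).T)

    def total_length(self) -> float:
        v = np.asarray(self.vertices)
        return float(np.hypot(*(v[1:] - v[:-1]).T).sum())

    def reversed(self) -> "LinePath":
        return LinePath(self.image_id, self.vertices[::-1], self.width_px)


@dataclass(frozen=True)
class StraightenedImage:
    """2D image whose horizontal axis is arc length along a traced path."""

    pixels: np.ndarray
    image_id: str = ""
    pixel_size: float | None = None
    bit_depth: int | str = 16

    def __post_init__(self):
        px = np.asarray(self.pixels, dtype=float)
        if px.ndim != 2 or min(px.shape) < 1:
            raise ValueError("straightened image must be 2D and nonempty")
        object.__setattr__(self, "pixels", px)

    @property
    def length_px(self) -> int:
        return self.pixels.shape[1]

    @property
    def width_px(self) -> int:
        return self.pixels.shape[0]


def _sample_points(path: LinePath, arc_positions: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Centers and unit normals at given arc-length positions.

    Within a segment the normal is the segment normal; exactly at an interior
    vertex it is the normalized bisector of the adjacent segment normals.
    """
    v = np.asarray(path.vertices)
    seg = v[1:] - v[:-1]
    seg_len = np.hypot(seg[:, 0], seg[:, 1])
    cum = np.concatenate([[0.0], np.cumsum(seg_len)])
    # segment index for each arc position (last position may equal total length)
    idx = np.searchsorted(cum, arc_positions, side="right") - 1
    idx = np.clip(idx, 0, len(seg) - 1)
    frac = (arc_positions - cum[idx]) / seg_len[idx]
    centers = v[idx] + frac[:, None] * seg[idx]
    tangents = seg / seg_len[:, None]
    # perpendicular = tangent rotated clockwise in (row, col) space, so a
    # left-to-right path keeps "up" up: output row order matches the source
    normals = np.stack([tangents[:, 1], -tangents[:, 0]], axis=1)
    out_normals = normals[idx].copy()
    # bisector at interior vertices hit exactly
    at_vertex = np.isclose(arc_positions[:, None], cum[None, 1:-1], atol=1e-9)
    for i, k in zip(*np.nonzero(at_vertex)):
        bis = normals[k] + normals[k + 1]
        norm = np.hypot(*bis)
        if norm > 1e-12:
            out_normals[i] = bis / norm
    return centers, out_normals


def straighten(img: ProjectedImage, path: LinePath) -> StraightenedImage:
    """Resample ``img`` along ``path`` into a straightened image.

    Out-of-bounds samples are zero-filled with a logged warning.
    """
    total = path.total_length()
    n_cols = int(round(total))
    if n_cols < 1:
        raise ValueError("path too short to produce any columns")
    arc = np.arange(n_cols, dtype=float)
    centers, normals = _sample_points(path, arc)
    half = (path.width_px - 1) // 2
    offsets = np.arange(-half, half + 1, dtype=float)
    # rows × cols sample grid: row k offset along the normal
    rr = centers[None, :, 0] + offsets[:, None] * normals[None, :, 0]
    cc = centers[None, :, 1] + offsets[:, None] * normals[None, :, 1]
    src = np.asarray(img.pixels, dtype=float)
    nrows, ncols = src.shape
    inside = (rr >= 0) & (rr <= nrows - 1) & (cc >= 0) & (cc <= ncols - 1)
    if not inside.any():
        raise ValueError(f"{path.image_id}: path lies entirely outside the image")
    if not inside.all():
        log.warning(
            "%s: %d straightening samples fall outside the image; zero-filled",
            path.image_id,
            int((~inside).sum()),
        )
    out = map_coordinates(src, [rr, cc], order=1, mode="constant", cval=0.0)
    return StraightenedImage(
        pixels=out,
        image_id=path.image_id,
        pixel_size=img.pixel_size,
        bit_depth=img.bit_depth,
    )


def path_length_um(path: LinePath, pixel_size: float | None) -> tuple[float, str]:
    """Total polyline length with units: µm if calibrated, else px."""
    length_px = path.total_length()
    if pixel_size is None:
        return length_px, "px"
    if pixel_size <= 0:
        raise ValueError("pixel_size must be > 0")
    return length_px * pixel_size, "um"


def load_paths(path_file: str | Path) -> dict[str, LinePath]:
    """Load traced paths from CSV or JSON, keyed by image_id.

    CSV columns: ``image_id, vertex_index, row, col, width_px`` (width
    repeated on every row of an image).  JSON:
    ``{image_id: {"vertices": [[row, col], ...], "width_px": w}}``.
    """
    path_file = Path(path_file)
    if path_file.suffix.lower() == ".json":
        spec = json.loads(path_file.read_text())
        return {
            image_id: LinePath(
                image_id=image_id,
                vertices=tuple((float(r), float(c)) for r, c in entry["vertices"]),
                width_px=int(entry.get("width_px", 1)),
            )
            for image_id, entry in spec.items()
        }
    rows: dict[str, list[tuple[int, float, float, int]]] = {}
    with open(path_file, newline="") as fh:
        for rec in csv.DictReader(fh):
            rows.setdefault(rec["image_id"], []).append(
                (
                    int(rec["vertex_index"]),
                    float(rec["row"]),
                    float(rec["col"]),
                    int(rec.get("width_px", 1) or 1),
                )
            )
    out = {}
    for image_id, verts in rows.items():
        verts.sort(key=lambda t: t[0])
        out[image_id] = LinePath(
            image_id=image_id,
            vertices=tuple((r, c) for _, r, c, _ in verts),
            width_px=verts[0][3],
        )
    return out


def straightened_length(path: LinePath) -> int:
    """Number of columns the straightened image will have."""
    return int(round(path.total_length()))
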