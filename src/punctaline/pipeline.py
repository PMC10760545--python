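"""Batch pipeline: project → straighten → [crop] → detect → measure → density.

Processes a folder of TIFFs deterministically (sorted by file name), isolating
per-image failures: a bad image is logged and skipped, never aborts the run.
All tabular outputs are plain CSV with floats at 6 significant digits, so two
runs over identical inputs produce byte-identical files.
"""

from __future__ import annotations

import csv
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

from punctaline import image_io
from punctaline.density import compute_density
from punctaline.detect import PRESETS, DetectionParams, detect, detection_mask
from punctaline.image_io import CropSpec, Excluded, apply_crop, max_project, read_image
from punctaline.measure import PunctumRecord, measure_puncta
from punctaline.straighten import LinePath, load_paths, straighten

__all__ = ["RunConfig", "PipelineResult", "run_pipeline", "aggregate_by_image"]

log = logging.getLogger(__name__)

PUNCTA_HEADER = [
    "image_id",
    "roi_id",
    "roi_width",
    "max_intensity",
    "fwhm",
    "discard",
    "fwhm_replaced",
    "units",
]
ROI_HEADER = ["image_id", "roi_id", "row0", "col0", "height", "width", "area", "area_units"]
DENSITY_HEADER = ["image_id", "n_puncta", "length", "density", "units"]


def _fmt(x: float) -> str:
    """Floats at 6 significant digits, integers untouched."""
    if isinstance(x, float):
        return format(x, ".6g")
    return str(x)


@dataclass(frozen=True)
class RunConfig:
    input_dir: Path
    output_dir: Path
    path_file: Path
    params: DetectionParams | str = "nuIs24"
    crop_file: Path | None = None
    straighten_width: int | None = None  # overrides per-path width when set
    replace_discarded: bool = False
    include_discarded_in_density: bool = True
    log_level: str = "INFO"

    def resolved_params(self) -> DetectionParams:
        if isinstance(self.params, DetectionParams):
            return self.params
        try:
            return PRESETS[self.params]
        except KeyError:
            raise ValueError(
                f"unknown preset {self.params!r}; available: {sorted(PRESETS)}"
            ) from None


@dataclass
class PipelineResult:
    puncta_csv: Path
    density_csv: Path
    summary_csv: Path
    manifest: Path
    n_processed: int = 0
    n_failed: int = 0
    n_excluded: int = 0
    statuses: dict[str, str] = field(default_factory=dict)


def load_crop_specs(crop_file: Path) -> dict[str, CropSpec]:
    """CSV columns: image_id, keep, row0, col0, height, width (rect optional)."""
    out = {}
    with open(crop_file, newline="") as fh:
        for rec in csv.DictReader(fh):
            keep = str(rec.get("keep", "1")).strip().lower() not in ("0", "false", "no")
            rect = None
            if rec.get("row0", "") not in ("", None):
                rect = (int(rec["row0"]), int(rec["col0"]), int(rec["height"]), int(rec["width"]))
            out[rec["image_id"]] = CropSpec(image_id=rec["image_id"], rectangle=rect, keep=keep)
    return out


def _write_csv(path: Path, header: list[str], rows: list[list]) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(header)
        writer.writerows([[_fmt(v) for v in row] for row in rows])


def _puncta_rows(records: list[PunctumRecord]) -> list[list]:
    return [
        [
            r.image_id,
            r.roi_id,
            r.roi_width,
            r.max_intensity,
            r.fwhm,
            r.discard,
            int(r.fwhm_replaced),
            r.units,
        ]
        for r in records
    ]


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Run the full macro sequence over a folder of projected/stack TIFFs."""
    params = config.resolved_params()
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = load_paths(config.path_file)
    crops = load_crop_specs(config.crop_file) if config.crop_file else {}

    tiffs = sorted(
        p for p in Path(config.input_dir).iterdir() if p.suffix.lower() in (".tif", ".tiff")
    )
    if not tiffs:
        log.warning("no TIFF images found in %s", config.input_dir)

    all_records: list[PunctumRecord] = []
    lengths: dict[str, tuple[float, str]] = {}
    roi_rows: list[list] = []
    result = PipelineResult(
        puncta_csv=out_dir / "puncta.csv",
        density_csv=out_dir / "density.csv",
        summary_csv=out_dir / "summary.csv",
        manifest=out_dir / "manifest.json",
    )

    for tif in tiffs:
        image_id = tif.name
        try:
            stack = read_image(tif)
            img = max_project(stack)
            if image_id in crops:
                cropped = apply_crop(img, crops[image_id])
                if isinstance(cropped, Excluded):
                    result.statuses[image_id] = "excluded"
                    result.n_excluded += 1
                    continue
                img = cropped
            if image_id not in paths:
                raise ValueError(f"no traced path for image {image_id!r}")
            path = paths[image_id]
            if config.straighten_width is not None:
                path = LinePath(path.image_id, path.vertices, config.straighten_width)
            straight = straighten(img, path)
            image_io.write_projected(
                image_io.ProjectedImage(
                    pixels=np.clip(straight.pixels, 0, image_io.depth_max(straight.bit_depth)),
                    bit_depth=straight.bit_depth,
                    pixel_size=straight.pixel_size,
                    source_id=image_id,
                ),
                out_dir / f"{tif.stem}_straight.tif",
            )
            rois = detect(straight, params)
            mask = detection_mask(straight, params)
            tifffile.imwrite(
                out_dir / f"{tif.stem}_mask.tif",
                (mask.astype(np.uint8) * 255),
                photometric="minisblack",
            )
            for roi in rois:
                r0, c0, h, w = roi.bbox
                roi_rows.append([image_id, roi.roi_id, r0, c0, h, w, roi.area, roi.area_units])
            records = measure_puncta(straight, rois, replace_discarded=config.replace_discarded)
            all_records.extend(records)
            if straight.pixel_size is not None:
                lengths[image_id] = (straight.length_px * straight.pixel_size, "um")
            else:
                lengths[image_id] = (float(straight.length_px), "px")
            result.statuses[image_id] = "ok"
            result.n_processed += 1
        except Exception as exc:  # noqa: BLE001 - per-image isolation
            log.error("%s: failed (%s)", image_id, exc)
            result.statuses[image_id] = f"failed: {exc}"
            result.n_failed += 1

    _write_csv(result.puncta_csv, PUNCTA_HEADER, _puncta_rows(all_records))
    _write_csv(out_dir / "rois.csv", ROI_HEADER, roi_rows)
    densities = compute_density(
        all_records, lengths, include_discarded=config.include_discarded_in_density
    )
    _write_csv(
        result.density_csv,
        DENSITY_HEADER,
        [[d.image_id, d.n_puncta, d.length, d.density, d.units] for d in densities],
    )
    summary_rows = aggregate_by_image(all_records)
    _write_csv(
        result.summary_csv,
        ["image_id", "n_puncta", "mean_intensity", "median_intensity", "median_fwhm"],
        summary_rows,
    )

    from punctaline import __version__

    manifest = {
        "version": __version__,
        "params": {
            "min_size": params.min_size,
            "sigma": params.sigma,
            "radius": params.radius,
            "method": params.method,
            "connectivity": params.connectivity,
        },
        "replace_discarded": config.replace_discarded,
        "include_discarded_in_density": config.include_discarded_in_density,
        "images": result.statuses,
        "n_processed": result.n_processed,
        "n_failed": result.n_failed,
        "n_excluded": result.n_excluded,
    }
    result.manifest.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return result


def aggregate_by_image(records: list[PunctumRecord]) -> list[list]:
    """Per-image summary rows: count, mean/median intensity, median FWHM.

    Discarded puncta count toward ``n_puncta`` and intensity statistics but
    are excluded from the FWHM summary (their fit is suspect by definition);
    an image with no usable FWHM gets an empty cell.
    """
    by_image: dict[str, list[PunctumRecord]] = {}
    for rec in records:
        by_image.setdefault(rec.image_id, []).append(rec)
    rows = []
    for image_id in sorted(by_image):
        recs = by_image[image_id]
        intensities = [r.max_intensity for r in recs]
        fwhms = [r.fwhm for r in recs if r.discard == 0 and math.isfinite(r.fwhm)]
        rows.append(
            [
                image_id,
                len(recs),
                float(np.mean(intensities)),
                float(np.median(intensities)),
                float(np.median(fwhms)) if fwhms else "",
            ]
        )
    return rows
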