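"""Per-image punctum density: ROI count divided by straightened-image length."""

from __future__ import annotations

from dataclasses import dataclass

from punctaline.measure import PunctumRecord

__all__ = ["DensityRecord", "compute_density"]


@dataclass(frozen=True)
class DensityRecord:
    image_id: str
    n_puncta: int
    length: float
    density: float  # puncta per µm (or per px when uncalibrated)
    units: str


def compute_density(
    records: list[PunctumRecord],
    lengths: dict[str, tuple[float, str]],
    include_discarded: bool = True,
) -> list[DensityRecord]:
    """Density per image = punctum count / straightened-image length.

    ``lengths`` maps image_id to (length, units).  By default discarded
    puncta still count — they are detected ROIs, only their FWHM is suspect
    — but ``include_discarded=False`` drops them first.  Images present in
    ``lengths`` but with no puncta get density 0.
    """
    by_image: dict[str, int] = {image_id: 0 for image_id in lengths}
    for rec in records:
        if rec.image_id not in lengths:
            raise ValueError(f"no straightened length provided for image {rec.image_id!r}")
        if include_discarded or rec.discard == 0:
            by_image[rec.image_id] += 1
    out = []
    for image_id in sorted(by_image):
        length, length_units = lengths[image_id]
        if length <= 0:
            raise ValueError(f"non-positive length for image {image_id!r}")
        out.append(
            DensityRecord(
                image_id=image_id,
                n_puncta=by_image[image_id],
                length=float(length),
                density=by_image[image_id] / float(length),
                units=f"per_{length_units}",
            )
        )
    return out
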