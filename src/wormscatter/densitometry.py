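"""Scattering density — the core fat-proxy metric — and its Oil Red O twin.

Scattering density is the sum of all pixel intensities inside a worm's
contour divided by the contour area in pixels (a.u. per pixel).  Oil Red O
absorption frames (510 nm bright field) are first inverted to
"pseudodark field" so that heavily stained (dark) regions become bright,
and then measured with the identical statistic.

Pipeline ordering is fixed: invert -> correct -> measure.  Inversion is
defined on the native integer scale and does not commute with the
multiplicative illumination correction, so inverting an already-corrected
frame (whose pixels may exceed full scale) is an error.
"""

from __future__ import annotations

from dataclasses import dataclass

from .illumination import GeometryError
from .image_io import Image
from .segmentation import WormMask


@dataclass
class DensityMeasurement:
    """Per-worm density: summed masked intensity / mask area (a.u. per pixel)."""

    worm_id: str
    density: float
    area_px: int
    modality: str  # darkfield | oro_pseudo
    corrected: bool
    condition: str = ""
    timepoint_hr: float | None = None

    def __post_init__(self) -> None:
        if self.density < 0:
            raise ValueError("density must be non-negative")
        if self.area_px < 1:
            raise ValueError("area_px must be >= 1")


def scattering_density(image: Image, mask: WormMask, worm_id: str = "",
                       condition: str | None = None,
                       timepoint_hr: float | None = None) -> DensityMeasurement:
    """Summed in-mask intensity divided by mask area."""
    if mask.mask.shape != image.shape:
        raise GeometryError(
            f"mask shape {mask.mask.shape} does not match image shape {image.shape}"
        )
    area = mask.area_px
    if area < 1:
        raise ValueError("mask must contain at least one pixel")
    total = float(image.pixels[mask.mask].sum())
    meta = image.meta
    tp = timepoint_hr
    if tp is None and meta.get("timepoint_hr"):
        tp = float(meta["timepoint_hr"])
    return DensityMeasurement(
        worm_id=worm_id or mask.label,
        density=total / area,
        area_px=area,
        modality="oro_pseudo" if image.modality == "oro_pseudo" else image.modality,
        corrected=meta.get("corrected") == "true",
        condition=condition if condition is not None else meta.get("condition", ""),
        timepoint_hr=tp,
    )


def invert_to_pseudodarkfield(image: Image) -> Image:
    """Invert a 510 nm bright-field frame: p -> (2^bit_depth - 1) - p.

    Stained regions absorb green light and appear dark in bright field;
    after inversion they are bright, so the density statistic increases
    with staining intensity just as scattering density increases with
    scatter.  Applying the function twice is the identity.
    """
    if image.modality == "oro_pseudo":
        # inversion is an involution; allow inverting back explicitly
        return image.with_pixels(image.scale_max - image.pixels,
                                 modality="brightfield510")
    if image.modality != "brightfield510":
        raise ValueError(
            f"pseudodark-field inversion applies to brightfield510 frames, got {image.modality}"
        )
    if image.pixels.max(initial=0) > image.scale_max:
        raise ValueError(
            "pixels exceed the native scale (frame already corrected?); "
            "invert before applying the illumination correction"
        )
    return image.with_pixels(image.scale_max - image.pixels, modality="oro_pseudo")


def staining_density(image510: Image, mask: WormMask, worm_id: str = "",
                     condition: str | None = None,
                     timepoint_hr: float | None = None) -> DensityMeasurement:
    """ORO staining density: scattering density of the inverted 510 nm frame."""
    return scattering_density(invert_to_pseudodarkfield(image510), mask,
                              worm_id=worm_id, condition=condition,
                              timepoint_hr=timepoint_hr)
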