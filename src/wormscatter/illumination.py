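"""Phantom-based lighting regulation and scalar intensity correction.

Dark-field intensities depend on the illumination geometry and brightness
of the session.  A stable scattering target (a BaSO4-in-PDMS phantom with a
surface scratch as a landmark) is imaged once per session; the mean
intensity in an annulus around the mark serves two purposes:

1. a live check that the lamp is within ~10% of a fixed target value, and
2. a post-hoc scalar correction: every experimental frame is multiplied by
   ``reference_mean / session_mean`` so that all sessions share the scale
   of one common reference phantom frame.

The correction is exactly multiplicative, so mask-restricted densities of
a scene scaled by any k > 0 are invariant once the matching phantom is
scaled by the same k — the guarantee the whole protocol rests on.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .image_io import Image


class GeometryError(ValueError):
    """Raised when an ROI or raster geometry is unusable."""


@dataclass
class PhantomRecord:
    """One phantom calibration frame with its annular measurement ROI.

    The annulus [roi_inner_px, roi_outer_px] around ``mark_center``
    excludes the scratch itself (a registration landmark, not
    representative scatter).  ``mean_intensity`` is computed on
    construction.
    """

    frame: Image
    mark_center: tuple[float, float]
    roi_inner_px: float = 5.0
    roi_outer_px: float = 25.0
    session_id: str = ""
    mean_intensity: float = field(init=False)

    def __post_init__(self) -> None:
        if not 0 < self.roi_inner_px < self.roi_outer_px:
            raise GeometryError("require 0 < roi_inner_px < roi_outer_px")
        self.mean_intensity = phantom_mean(
            self.frame, self.mark_center, self.roi_inner_px, self.roi_outer_px
        )


@dataclass
class CorrectionFactor:
    """Scalar by which a session's frames are multiplied onto the reference scale."""

    factor: float
    session_id: str = ""
    reference_id: str = ""

    def __post_init__(self) -> None:
        if not self.factor > 0:
            raise ValueError(f"correction factor must be positive, got {self.factor}")


@dataclass
class LightingCheck:
    """Outcome of the pre-acquisition lamp check (advisory, not blocking)."""

    passed: bool
    deviation: float  # signed relative deviation from the fixed target


def phantom_mean(frame: Image, mark_center: tuple[float, float],
                 roi_inner_px: float, roi_outer_px: float) -> float:
    """Mean intensity over pixels whose center lies in the annulus around the mark.

    A pixel (r, c) belongs to the ROI iff
    ``roi_inner_px <= dist((r, c), mark_center) <= roi_outer_px``.
    """
    if not 0 < roi_inner_px < roi_outer_px:
        raise GeometryError("require 0 < roi_inner_px < roi_outer_px")
    rows, cols = frame.shape
    rr, cc = np.ogrid[:rows, :cols]
    d = np.hypot(rr - mark_center[0], cc - mark_center[1])
    sel = (d >= roi_inner_px) & (d <= roi_outer_px)
    if not sel.any():
        raise GeometryError("annulus contains no pixels inside the frame")
    return float(frame.pixels[sel].mean())


def check_lighting(session_mean: float, fixed_target: float,
                   tol_frac: float = 0.10) -> LightingCheck:
    """Check that the session's phantom mean is within ``tol_frac`` of the target.

    The boundary is inclusive (a deviation of exactly 10% passes).  The
    result is advisory: residual drift is removed in software by
    :func:`apply_correction` regardless.
    """
    if fixed_target <= 0:
        raise ValueError("fixed_target must be positive")
    if tol_frac <= 0:
        raise ValueError("tol_frac must be positive")
    deviation = (session_mean - fixed_target) / fixed_target
    return LightingCheck(passed=abs(deviation) <= tol_frac, deviation=deviation)


def correction_factor(reference_mean: float, session_mean: float,
                      session_id: str = "", reference_id: str = "") -> CorrectionFactor:
    """Scalar correction = reference phantom mean / session phantom mean."""
    if reference_mean <= 0 or session_mean <= 0:
        raise ValueError("phantom means must be positive")
    return CorrectionFactor(factor=reference_mean / session_mean,
                            session_id=session_id, reference_id=reference_id)


def apply_correction(image: Image, cf: CorrectionFactor) -> Image:
    """Multiply every pixel by the correction factor (no clipping).

    Corrected values may exceed the source bit depth's full scale; that is
    intentional.  A metadata flag guards against accidental double
    correction, and the session is cross-checked when both the image and
    the factor carry a session id.
    """
    if image.meta.get("corrected") == "true":
        raise ValueError("image already corrected (metadata flag set); refusing to correct twice")
    img_session = image.meta.get("session_id", "")
    if img_session and cf.session_id and img_session != cf.session_id:
        raise ValueError(
            f"correction factor for session {cf.session_id!r} applied to "
            f"image from session {img_session!r}"
        )
    return image.with_pixels(
        image.pixels * cf.factor,
        meta_update={
            "corrected": "true",
            "correction_factor": repr(cf.factor),
            "correction_reference": cf.reference_id,
        },
    )
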