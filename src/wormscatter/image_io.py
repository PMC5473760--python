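"""Image and result I/O plus the raster/record types shared by all modules.

Conventions used throughout the package:

* pixel coordinates are 0-based ``(row, col)``, row-major;
* intensities are carried as floats on the native integer scale of the
  source file (no [0, 1] normalization) — the correction factor and the
  density metric are ratios, so the absolute scale is immaterial;
* ingest never rescales: an 8-bit and a 16-bit frame of the same scene
  differ only in ``bit_depth``.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import tifffile

MODALITIES = frozenset({"darkfield", "brightfield510", "fluor_red", "oro_pseudo"})

RESULT_COLUMNS = ("worm_id", "condition", "timepoint_hr", "density", "area_px", "modality")


class FormatError(ValueError):
    """Raised for rasters the pipeline cannot quantify (RGB, >2-D, bad dtype)."""


@dataclass
class Image:
    """A single-plane grayscale micrograph with acquisition metadata.

    ``pixels`` holds non-negative intensities in arbitrary units (a.u.) on
    the native integer scale recorded by ``bit_depth``.  Values may exceed
    ``2**bit_depth - 1`` after illumination correction; they may never be
    negative.
    """

    pixels: np.ndarray
    bit_depth: int
    modality: str
    pixel_size_um: float | None = None
    meta: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2 or self.pixels.shape[0] < 1 or self.pixels.shape[1] < 1:
            raise FormatError(f"expected a 2-D raster, got shape {self.pixels.shape}")
        if np.any(self.pixels < 0):
            raise ValueError("pixel intensities must be non-negative")
        if self.bit_depth not in (8, 16):
            raise ValueError(f"bit_depth must be 8 or 16, got {self.bit_depth}")
        if self.modality not in MODALITIES:
            raise ValueError(f"unknown modality {self.modality!r}; expected one of {sorted(MODALITIES)}")
        if self.pixel_size_um is not None and self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")

    @property
    def scale_max(self) -> int:
        """Full-scale value of the source integer format (255 or 65535)."""
        return 2 ** self.bit_depth - 1

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]

    def with_pixels(self, pixels: np.ndarray, *, modality: str | None = None,
                    meta_update: dict[str, str] | None = None) -> "Image":
        """Copy carrying new pixel data (and optionally modality/meta changes)."""
        meta = dict(self.meta)
        if meta_update:
            meta.update(meta_update)
        return Image(
            pixels=np.asarray(pixels, dtype=np.float64),
            bit_depth=self.bit_depth,
            modality=modality or self.modality,
            pixel_size_um=self.pixel_size_um,
            meta=meta,
        )


@dataclass
class ResultRow:
    """One per-worm measurement destined for a results CSV."""

    worm_id: str
    condition: str
    density: float
    area_px: int
    modality: str
    timepoint_hr: float | None = None

    def __post_init__(self) -> None:
        if self.density < 0:
            raise ValueError("density must be non-negative")
        if self.area_px < 1:
            raise ValueError("area_px must be >= 1")


def _infer_bit_depth(arr: np.ndarray, path: Path) -> int:
    if arr.dtype == np.uint8:
        return 8
    if arr.dtype == np.uint16:
        return 16
    if np.issubdtype(arr.dtype, np.integer):
        return 8 if arr.max(initial=0) <= 255 else 16
    if np.issubdtype(arr.dtype, np.floating):
        # float TIFFs written by this package carry the scale in their values
        return 8 if arr.max(initial=0) <= 255 else 16
    raise FormatError(f"{path}: unsupported pixel dtype {arr.dtype}")


def read_image(path: str | Path, modality: str, *, rgb: str = "reject",
               pixel_size_um: float | None = None,
               meta: dict[str, str] | None = None) -> Image:
    """Read a TIFF or PNG micrograph into an :class:`Image`.

    RGB frames are rejected by default: color rasters are not quantifiable
    without a channel decision.  Pass ``rgb="green"`` to extract the green
    channel explicitly (appropriate for 510 nm Oil Red O absorption frames,
    where the dye absorbs green light).
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"image file not found: {path}")
    try:
        if path.suffix.lower() in (".tif", ".tiff"):
            arr = tifffile.imread(path)
        else:
            arr = iio.imread(path)
    except Exception as exc:  # pragma: no cover - backend specific
        raise IOError(f"could not read image {path}: {exc}") from exc
    arr = np.asarray(arr)
    if arr.ndim == 3:
        if arr.shape[-1] in (3, 4):
            if rgb == "green":
                arr = arr[..., 1]
            else:
                raise FormatError(
                    f"{path}: RGB frame; pass rgb='green' to quantify the green channel"
                )
        else:
            raise FormatError(f"{path}: >2 spatial dimensions (shape {arr.shape})")
    elif arr.ndim != 2:
        raise FormatError(f"{path}: expected 2-D raster, got shape {arr.shape}")
    bit_depth = _infer_bit_depth(arr, path)
    img = Image(pixels=arr, bit_depth=bit_depth, modality=modality,
                pixel_size_um=pixel_size_um, meta=dict(meta or {}))
    if img.pixels.max(initial=0) > img.scale_max:
        raise FormatError(f"{path}: pixel values exceed 2^{bit_depth}-1 on ingest")
    return img


def write_image(image: Image, path: str | Path) -> None:
    """Write an :class:`Image` to TIFF (or 8-bit PNG).

    Integer-valued rasters within the bit-depth scale round-trip bit-exactly
    through the matching unsigned dtype; anything else (e.g. corrected
    frames exceeding full scale) is written as float32 TIFF.
    """
    path = Path(path)
    px = image.pixels
    integral = np.all(px == np.round(px)) and px.max(initial=0) <= image.scale_max
    if integral:
        arr = px.astype(np.uint8 if image.bit_depth == 8 else np.uint16)
    else:
        arr = px.astype(np.float32)
    try:
        if path.suffix.lower() in (".tif", ".tiff"):
            tifffile.imwrite(path, arr)
        elif path.suffix.lower() == ".png":
            if arr.dtype not in (np.uint8, np.uint16):
                raise FormatError("PNG output requires integer intensities within scale")
            iio.imwrite(path, arr)
        else:
            raise FormatError(f"unsupported output format: {path.suffix}")
    except OSError as exc:
        raise IOError(f"could not write image {path}: {exc}") from exc


def write_results(rows: list[ResultRow], path: str | Path,
                  header_comment: str | None = None) -> None:
    """Write per-worm measurements as RFC-4180 CSV.

    Missing timepoints become empty fields (never the text "NaN").  An
    optional ``header_comment`` line (prefixed ``#``) records provenance.
    """
    if not rows:
        raise ValueError("rows must be non-empty")
    path = Path(path)
    try:
        with open(path, "w", newline="") as fh:
            if header_comment:
                fh.write(f"# {header_comment}\n")
            writer = csv.writer(fh)
            writer.writerow(RESULT_COLUMNS)
            for r in rows:
                tp = "" if r.timepoint_hr is None else repr(float(r.timepoint_hr))
                writer.writerow([r.worm_id, r.condition, tp, repr(float(r.density)),
                                 int(r.area_px), r.modality])
    except OSError as exc:
        raise IOError(f"could not write results {path}: {exc}") from exc


def read_results(path: str | Path) -> list[ResultRow]:
    """Parse a results CSV written by :func:`write_results` back into rows."""
    path = Path(path)
    if not path.exists():
        raise IOError(f"results file not found: {path}")
    rows: list[ResultRow] = []
    with open(path, newline="") as fh:
        lines = [ln for ln in fh if not ln.startswith("#")]
    reader = csv.DictReader(lines)
    for rec in reader:
        tp = rec["timepoint_hr"]
        rows.append(ResultRow(
            worm_id=rec["worm_id"],
            condition=rec["condition"],
            timepoint_hr=None if tp == "" else float(tp),
            density=float(rec["density"]),
            area_px=int(rec["area_px"]),
            modality=rec["modality"],
        ))
    return rows
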