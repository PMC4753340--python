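"""Image input/output, calibration metadata and region-of-interest cropping.

Coordinate convention (project-wide): pixels are addressed as (x, y) with x
the column and y the row, 0-based, origin at the top-left corner, y growing
downward.  Arrays are stored row-major, i.e. ``pixels[y, x]``.  Regions of
interest are half-open boxes ``[x0, x1) x [y0, y1)``.

Physical calibration is carried as centimetres per pixel, one value per axis
``(sx, sy)``.  DICOM ``PixelSpacing`` stores (row spacing, column spacing) in
millimetres; it is converted on read.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image

from ._util import round_half_up
from .errors import BoundsError, FormatError

log = logging.getLogger(__name__)

#: ITU-R BT.601 luma weights used when collapsing RGB input to grayscale.
LUMA_WEIGHTS = (0.299, 0.587, 0.114)


@dataclass
class GrayImage:
    """An 8-bit grayscale raster with optional physical pixel spacing.

    Parameters
    ----------
    pixels : ndarray of uint8, shape (height, width)
        Intensity values in [0, 255].
    spacing_cm : (float, float), optional
        Physical size of one pixel in centimetres, as ``(sx, sy)`` for the
        x (column) and y (row) axes.  ``None`` when uncalibrated.
    """

    pixels: np.ndarray
    spacing_cm: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        arr = np.asarray(self.pixels)
        if arr.ndim != 2 or arr.size == 0:
            raise ValueError("GrayImage requires a non-empty 2-D array")
        if arr.dtype != np.uint8:
            if arr.min() < 0 or arr.max() > 255:
                raise ValueError("intensities must lie in [0, 255]")
            arr = arr.astype(np.uint8)
        self.pixels = arr
        if self.spacing_cm is not None:
            sx, sy = self.spacing_cm
            if not (sx > 0 and sy > 0):
                raise ValueError("spacing_cm must be strictly positive")
            self.spacing_cm = (float(sx), float(sy))

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def height(self) -> int:
        return self.pixels.shape[0]


@dataclass(frozen=True)
class ROISpec:
    """A half-open rectangular region of interest ``[x0, x1) x [y0, y1)``."""

    x0: int
    y0: int
    x1: int
    y1: int

    def __post_init__(self) -> None:
        if not (self.x0 < self.x1 and self.y0 < self.y1):
            raise BoundsError(f"degenerate ROI {self}")
        if self.x0 < 0 or self.y0 < 0:
            raise BoundsError(f"negative ROI origin {self}")

    @property
    def width(self) -> int:
        return self.x1 - self.x0

    @property
    def height(self) -> int:
        return self.y1 - self.y0

    def validate_for(self, img: GrayImage) -> None:
        if self.x1 > img.width or self.y1 > img.height:
            raise BoundsError(
                f"ROI {self} exceeds image bounds {img.width}x{img.height}"
            )


def read_dicom(path: str | Path) -> GrayImage:
    """Read a single-frame grayscale DICOM file as an 8-bit image.

    Pixel data of any bit depth is rescaled to [0, 255] by a min-max affine
    map with round-half-up.  ``PixelSpacing`` (mm) is converted to cm when
    present.

    Raises
    ------
    FileNotFoundError
        If *path* does not exist.
    FormatError
        For DICOM files without pixel data, with multiple frames, or with
        color (multi-sample) pixels.
    """
    import pydicom

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    ds = pydicom.dcmread(str(path))
    if "PixelData" not in ds:
        raise FormatError(f"{path}: DICOM file has no pixel data")
    if int(getattr(ds, "NumberOfFrames", 1)) > 1:
        raise FormatError(f"{path}: multi-frame DICOM is not supported")
    if int(getattr(ds, "SamplesPerPixel", 1)) != 1:
        raise FormatError(f"{path}: color DICOM (SamplesPerPixel > 1) is not supported")
    raw = ds.pixel_array
    if raw.ndim != 2:
        raise FormatError(f"{path}: expected a single 2-D frame, got shape {raw.shape}")
    pixels = _rescale_to_uint8(raw)
    spacing = None
    ps = getattr(ds, "PixelSpacing", None)
    if ps is not None:
        # PixelSpacing is (row, column) in mm -> (sx, sy) in cm.
        sy_mm, sx_mm = float(ps[0]), float(ps[1])
        spacing = (sx_mm / 10.0, sy_mm / 10.0)
    return GrayImage(pixels, spacing)


def _rescale_to_uint8(raw: np.ndarray) -> np.ndarray:
    raw = raw.astype(np.float64)
    lo, hi = raw.min(), raw.max()
    if hi == lo:
        return np.zeros(raw.shape, dtype=np.uint8)
    return round_half_up(255.0 * (raw - lo) / (hi - lo)).astype(np.uint8)


def read_image(path: str | Path, spacing_cm: tuple[float, float] | None = None) -> GrayImage:
    """Read a PNG/TIFF image as 8-bit grayscale.

    RGB input is converted with the BT.601 luma weights (:data:`LUMA_WEIGHTS`)
    and round-half-up.  ``spacing_cm`` may be supplied by the caller since
    these formats carry no physical calibration.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    try:
        im = Image.open(path)
        im.load()
    except Exception as exc:  # Pillow raises UnidentifiedImageError subclassing OSError
        raise FormatError(f"{path}: unsupported or corrupt image ({exc})") from exc
    arr = np.asarray(im)
    if arr.ndim == 3:
        rgb = arr[..., :3].astype(np.float64)
        arr = round_half_up(rgb @ np.array(LUMA_WEIGHTS)).astype(np.uint8)
    elif arr.dtype != np.uint8:
        arr = _rescale_to_uint8(arr)
    return GrayImage(arr, spacing_cm)


def write_image(img: GrayImage, path: str | Path) -> None:
    """Write *img* losslessly as an 8-bit grayscale PNG/TIFF."""
    path = Path(path)
    if not path.parent.exists():
        raise FileNotFoundError(f"directory {path.parent} does not exist")
    Image.fromarray(img.pixels, mode="L").save(path)


def crop_roi(img: GrayImage, roi: ROISpec) -> GrayImage:
    """Return the sub-image covered by *roi*; pixel spacing is preserved."""
    roi.validate_for(img)
    sub = img.pixels[roi.y0 : roi.y1, roi.x0 : roi.x1].copy()
    return GrayImage(sub, img.spacing_cm)
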