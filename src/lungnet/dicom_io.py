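"""Reading CT slices, Hounsfield rescale, and fixed-size cropping.

A CT scanner stores pixel values as raw integers ("pixel gradients"); the
DICOM header carries an affine rescale (slope, intercept) that maps them onto
the Hounsfield unit (HU) scale, on which distilled water is 0 HU and air is
about -1000 HU. This module reads a single-frame slice, applies the rescale,
and cuts square crops sized to contain one secondary pulmonary lobule — the
smallest anatomic unit of lung parenchyma, 1-2.5 cm across, which at typical
HRCT pixel spacing (~0.74 mm/px) fits comfortably inside a 65x65-pixel window.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pydicom
from PIL import Image

from .errors import (
    CropOutOfBoundsError,
    DomainError,
    InvalidMetadataError,
    MissingMetadataError,
)

# 12-bit CT convention: representable HU range after rescale.
HU_MIN = -1024
HU_MAX = 3071

DEFAULT_CROP_SIZE = 65


@dataclass(frozen=True)
class SliceImage:
    """One single-frame CT slice with the metadata needed downstream.

    ``pixels`` holds the raw stored values (not HU); ``rescale_slope`` and
    ``rescale_intercept`` define the affine map onto the HU scale;
    ``pixel_spacing_mm`` is the in-plane spacing in mm/pixel (isotropic).
    """

    pixels: np.ndarray
    rescale_slope: float
    rescale_intercept: float
    pixel_spacing_mm: float
    source_id: str = ""

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2 or px.size == 0:
            raise InvalidMetadataError("pixel array must be 2-D and non-empty")
        if self.rescale_slope == 0:
            raise InvalidMetadataError("rescale slope must be non-zero")
        if self.pixel_spacing_mm <= 0:
            raise InvalidMetadataError("pixel spacing must be positive")
        object.__setattr__(self, "pixels", px)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass(frozen=True)
class CropSample:
    """A square HU-valued crop taken from a slice.

    ``hu`` is ``size_px`` x ``size_px``, values clamped to [-1024, 3071];
    ``origin`` is the (row, col) of the crop's top-left corner in the source
    slice, 0-based.
    """

    hu: np.ndarray
    size_px: int
    origin: tuple[int, int]
    pixel_spacing_mm: float
    source_id: str = ""

    def __post_init__(self) -> None:
        hu = np.asarray(self.hu, dtype=float)
        if hu.shape != (self.size_px, self.size_px):
            raise DomainError(
                f"hu grid shape {hu.shape} does not match size_px={self.size_px}"
            )
        object.__setattr__(self, "hu", hu)


def to_hounsfield(raw, slope: float, intercept: float):
    """Affine map from raw stored values to Hounsfield units.

    HU = slope * raw + intercept. Scalar or array-valued ``raw``.
    """
    if slope == 0:
        raise InvalidMetadataError("rescale slope must be non-zero")
    return slope * raw + intercept


def clamp_hu(hu: np.ndarray) -> np.ndarray:
    """Clamp HU values into the representable 12-bit CT range."""
    return np.clip(hu, HU_MIN, HU_MAX)


def read_slice(path: str | Path) -> SliceImage:
    """Read a single-frame DICOM CT slice.

    Raises :class:`MissingMetadataError` if pixel data, rescale tags, or pixel
    spacing are absent, and :class:`InvalidMetadataError` for multi-frame
    files or a zero slope. Pixel spacing must be (near-)isotropic; the row
    spacing is used.
    """
    path = Path(path)
    ds = pydicom.dcmread(str(path), force=True)

    if "PixelData" not in ds:
        raise MissingMetadataError(f"{path.name}: no PixelData element")
    if int(getattr(ds, "NumberOfFrames", 1)) != 1:
        raise InvalidMetadataError(f"{path.name}: multi-frame DICOM not supported")
    for tag in ("RescaleSlope", "RescaleIntercept"):
        if tag not in ds:
            raise MissingMetadataError(f"{path.name}: missing {tag}")
    if "PixelSpacing" not in ds:
        raise MissingMetadataError(f"{path.name}: missing PixelSpacing")

    pixels = ds.pixel_array
    if pixels.ndim != 2:
        raise InvalidMetadataError(f"{path.name}: expected a 2-D pixel array")

    spacing = [float(v) for v in ds.PixelSpacing]
    return SliceImage(
        pixels=pixels.astype(np.int64),
        rescale_slope=float(ds.RescaleSlope),
        rescale_intercept=float(ds.RescaleIntercept),
        pixel_spacing_mm=spacing[0],
        source_id=str(getattr(ds, "SOPInstanceUID", path.name)),
    )


def crop(
    slice_image: SliceImage,
    origin: tuple[int, int],
    size_px: int = DEFAULT_CROP_SIZE,
) -> CropSample:
    """Cut a ``size_px`` square at ``origin`` (row, col) and rescale to HU.

    The window is origin-inclusive, size-exclusive. Raises
    :class:`CropOutOfBoundsError` if the window does not fit.
    """
    r0, c0 = origin
    n_rows, n_cols = slice_image.shape
    if size_px <= 0:
        raise DomainError("crop size must be positive")
    if r0 < 0 or c0 < 0 or r0 + size_px > n_rows or c0 + size_px > n_cols:
        raise CropOutOfBoundsError(
            f"crop window {size_px}px at ({r0},{c0}) exceeds slice {n_rows}x{n_cols}"
        )
    block = slice_image.pixels[r0 : r0 + size_px, c0 : c0 + size_px]
    hu = clamp_hu(
        slice_image.rescale_slope * block.astype(float)
        + slice_image.rescale_intercept
    )
    return CropSample(
        hu=hu,
        size_px=size_px,
        origin=(r0, c0),
        pixel_spacing_mm=slice_image.pixel_spacing_mm,
        source_id=slice_image.source_id,
    )


def min_sample_side(lobule_side_mm: float, pixel_spacing_mm: float) -> float:
    """Smallest crop side, in pixels, that spans one secondary lobule.

    Dividing the lobule side (mm) by the pixel spacing (mm/px) gives the
    minimum sample side; e.g. a 25 mm lobule at 0.74 mm/px needs ~33.78
    pixels, which motivates the near-double 65-pixel default crop.
    """
    if lobule_side_mm <= 0 or pixel_spacing_mm <= 0:
        raise DomainError("lobule side and pixel spacing must be positive")
    return lobule_side_mm / pixel_spacing_mm


def write_crop_csv(sample: CropSample, path: str | Path) -> None:
    """Write the HU grid as a headerless CSV of integers-or-floats."""
    np.savetxt(path, sample.hu, fmt="%.10g", delimiter=",")


def read_crop_csv(
    path: str | Path,
    pixel_spacing_mm: float = 0.74,
    origin: tuple[int, int] = (0, 0),
) -> CropSample:
    """Read a square HU grid written by :func:`write_crop_csv`."""
    hu = np.atleast_2d(np.loadtxt(path, delimiter=","))
    if hu.shape[0] != hu.shape[1]:
        raise DomainError(f"crop CSV must be square, got {hu.shape}")
    return CropSample(
        hu=hu,
        size_px=hu.shape[0],
        origin=origin,
        pixel_spacing_mm=pixel_spacing_mm,
        source_id=str(path),
    )


def write_crop_png(sample: CropSample, path: str | Path) -> None:
    """Write a lossless 16-bit grayscale PNG of the crop.

    HU values are offset by +1024 so the whole clamped range maps onto
    unsigned 16-bit; the inverse is ``value - 1024``.
    """
    offset = (sample.hu - HU_MIN).astype(np.uint16)
    Image.fromarray(offset).save(str(path))
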