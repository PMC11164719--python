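"""Greyscale face images, rectangular face crops and face resolution.

Face resolution is quantified as the *face-to-image pixel proportion*
(FIPP): the pixel area of the rectangle enclosing the face, head and neck
divided by the total pixel area of the original frame.  The crop is a plain
bounding box — images are cropped "down to the last visible pixel" of the
face region and nothing else about the raster (depth, density, values) is
altered.

Conventions: pixel coordinates are 0-based with the origin at the top-left;
crop boxes are half-open extents (``left <= x < left + width``).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Union

import numpy as np
from PIL import Image, UnidentifiedImageError

from .exceptions import BoundsError, InvalidInputError, UnsupportedFormatError

__all__ = [
    "GreyImage",
    "FaceCropBox",
    "FippResult",
    "load_grey",
    "crop",
    "compute_fipp",
]

#: Pillow modes with more than 8 bits per channel → rejected, not silently rescaled.
_DEEP_MODES = {"I": 32, "I;16": 16, "I;16B": 16, "I;16L": 16, "I;16N": 16, "F": 32}


def _round_half_up(x: np.ndarray) -> np.ndarray:
    """Round to nearest integer with halves away from zero (towards +inf here)."""
    return np.floor(x + 0.5)


@dataclass(frozen=True, eq=False)
class GreyImage:
    """An 8-bit intensity raster, row-major, origin at the top-left.

    Parameters
    ----------
    values
        2-D integer array of shape ``(height, width)`` with entries in
        [0, 255].  Stored as ``uint8``.
    """

    values: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.values)
        if arr.ndim != 2:
            raise InvalidInputError(f"image array must be 2-D, got {arr.ndim}-D")
        if arr.size == 0:
            raise InvalidInputError("image must have width >= 1 and height >= 1")
        if not np.issubdtype(arr.dtype, np.integer):
            if not np.all(arr == np.floor(arr)):
                raise InvalidInputError("image values must be integers")
            arr = arr.astype(np.int64)
        if arr.min() < 0 or arr.max() > 255:
            raise InvalidInputError("image values must lie in [0, 255]")
        object.__setattr__(self, "values", arr.astype(np.uint8))

    @property
    def width(self) -> int:
        return self.values.shape[1]

    @property
    def height(self) -> int:
        return self.values.shape[0]

    @property
    def pixel_count(self) -> int:
        return self.values.size

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GreyImage):
            return NotImplemented
        return self.values.shape == other.values.shape and bool(
            np.array_equal(self.values, other.values)
        )

    def save(self, path: Union[str, Path]) -> None:
        """Write the raster as an 8-bit greyscale PNG (used for fixtures)."""
        Image.fromarray(self.values, mode="L").save(path, format="PNG")


@dataclass(frozen=True)
class FaceCropBox:
    """Half-open rectangle locating the face/head/neck region in a frame."""

    left: int
    top: int
    width: int
    height: int

    def __post_init__(self) -> None:
        if self.left < 0 or self.top < 0:
            raise InvalidInputError(
                f"box offsets must be non-negative, got ({self.left}, {self.top})"
            )
        if self.width < 1 or self.height < 1:
            raise InvalidInputError(
                f"box extent must be at least 1x1, got {self.width}x{self.height}"
            )

    @property
    def area(self) -> int:
        return self.width * self.height

    def fits_within(self, image: GreyImage) -> bool:
        return (
            self.left + self.width <= image.width
            and self.top + self.height <= image.height
        )


@dataclass(frozen=True)
class FippResult:
    """Face-to-image pixel proportion with the raw pixel counts behind it."""

    face_pixels: int
    image_pixels: int

    def __post_init__(self) -> None:
        if self.face_pixels < 1:
            raise InvalidInputError("face region must contain at least one pixel")
        if self.face_pixels > self.image_pixels:
            raise InvalidInputError(
                f"face pixel count {self.face_pixels} exceeds image total "
                f"{self.image_pixels}"
            )

    @property
    def proportion(self) -> float:
        return self.face_pixels / self.image_pixels


def load_grey(path: Union[str, Path], conversion: str = "unweighted") -> GreyImage:
    """Read an image file and return an 8-bit greyscale raster.

    RGB input is collapsed per ``conversion``:

    ``"unweighted"``
        round((R + G + B) / 3) — the plain channel mean, matching the
        default greyscale conversion of the histogram tooling the pipeline
        reproduces.
    ``"luma"``
        round(0.299 R + 0.587 G + 0.114 B) — the Rec. 601 luma weighting.

    Greyscale input passes through unchanged; palette images are expanded
    to RGB first; an alpha channel, if present, is discarded.

    Raises
    ------
    UnsupportedFormatError
        For bit depths above 8 per channel.
    InvalidInputError
        For an unreadable or undecodable file.
    """
    if conversion not in ("unweighted", "luma"):
        raise InvalidInputError(f"unknown conversion {conversion!r}")
    try:
        with Image.open(path) as im:
            if im.mode in _DEEP_MODES:
                raise UnsupportedFormatError(
                    f"{path}: {_DEEP_MODES[im.mode]}-bit samples are not supported; "
                    "only 8 bits per channel"
                )
            if im.mode == "P":
                im = im.convert("RGB")
            if im.mode == "L":
                return GreyImage(np.asarray(im))
            if im.mode in ("RGB", "RGBA", "LA"):
                rgb = np.asarray(im.convert("RGB"), dtype=np.float64)
            else:
                raise UnsupportedFormatError(
                    f"{path}: unsupported image mode {im.mode!r}"
                )
    except UnidentifiedImageError as exc:
        raise InvalidInputError(f"cannot decode image file {path}") from exc
    except FileNotFoundError as exc:
        raise InvalidInputError(f"no such file: {path}") from exc

    if conversion == "unweighted":
        grey = _round_half_up(rgb.sum(axis=2) / 3.0)
    else:
        grey = _round_half_up(
            0.299 * rgb[..., 0] + 0.587 * rgb[..., 1] + 0.114 * rgb[..., 2]
        )
    return GreyImage(grey.astype(np.int64))


def crop(image: GreyImage, box: FaceCropBox) -> GreyImage:
    """Extract the sub-raster under ``box``; values are copied unchanged."""
    if not box.fits_within(image):
        raise BoundsError(
            f"box (left={box.left}, top={box.top}, width={box.width}, "
            f"height={box.height}) exceeds image bounds "
            f"{image.width}x{image.height}"
        )
    sub = image.values[box.top : box.top + box.height, box.left : box.left + box.width]
    return GreyImage(sub.copy())


def compute_fipp(
    face: Union[FaceCropBox, GreyImage], original: GreyImage
) -> FippResult:
    """Face-to-image pixel proportion of a face crop within its original frame.

    ``face`` may be the crop box itself or the already-cropped image; either
    way the proportion is computed on bounding-box pixel areas, not on a
    segmentation mask.
    """
    if isinstance(face, FaceCropBox):
        face_pixels = face.area
    elif isinstance(face, GreyImage):
        face_pixels = face.pixel_count
    else:
        raise InvalidInputError(
            f"face must be a FaceCropBox or GreyImage, got {type(face).__name__}"
        )
    return FippResult(face_pixels=face_pixels, image_pixels=original.pixel_count)
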