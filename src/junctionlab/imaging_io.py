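"""Grayscale channel images: loading, bit-depth conversion, thresholding.

Every downstream measurement in this package operates on single-channel
fluorescence micrographs (one junction protein, or the avidin leak tracer,
per image).  This module defines the in-memory container for such a channel
and the two primitive raster operations the analysis relies on:

* conversion of 16-bit acquisitions to 8-bit (min-max linear rescale), so
  that intensity thresholds stated on the 0-255 scale apply uniformly;
* inclusive intensity thresholding, producing the binary masks from which
  junction pieces and permeated regions are extracted.

Conventions: pixel coordinates are ``(row, col)``, 0-based, origin at the
top-left; image bounds are half-open.  Pixel calibration defaults to
0.18 um/px (60x oil objective; 15 px is approximately 2.7 um).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile
from PIL import Image as _PILImage

from .errors import FormatError, ParameterError

#: Default pixel calibration in micrometres per pixel (60x oil objective).
DEFAULT_PIXEL_SIZE_UM = 0.18


@dataclass(frozen=True)
class IntensityImage:
    """A single grayscale fluorescence channel.

    Parameters
    ----------
    pixels
        2-D array of non-negative integer intensities.
    bit_depth
        8 or 16; all intensities must lie in ``[0, 2**bit_depth - 1]``.
    pixel_size
        Calibration in micrometres per pixel (> 0).
    channel_label
        Free-text name of the stained protein or tracer, e.g. ``"ZO-1"``.
        Used to look up default junction thresholds.
    """

    pixels: np.ndarray
    bit_depth: int
    pixel_size: float = DEFAULT_PIXEL_SIZE_UM
    channel_label: str = ""

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2 or px.shape[0] < 1 or px.shape[1] < 1:
            raise FormatError(f"expected a 2-D image, got shape {px.shape}")
        if self.bit_depth not in (8, 16):
            raise ParameterError(f"bit_depth must be 8 or 16, got {self.bit_depth}")
        if px.size and (px.min() < 0 or px.max() > self.max_value):
            raise ParameterError(
                f"intensities outside [0, {self.max_value}] for bit depth {self.bit_depth}"
            )
        if not self.pixel_size > 0:
            raise ParameterError(f"pixel_size must be > 0, got {self.pixel_size}")
        object.__setattr__(self, "pixels", px)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]

    @property
    def max_value(self) -> int:
        """Largest representable intensity for this bit depth."""
        return (1 << self.bit_depth) - 1


@dataclass(frozen=True)
class BinaryMask:
    """A boolean raster, same shape as the image it was derived from."""

    pixels: np.ndarray

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2:
            raise FormatError(f"expected a 2-D mask, got shape {px.shape}")
        if px.dtype != bool:
            raise FormatError(f"mask must be boolean, got dtype {px.dtype}")
        object.__setattr__(self, "pixels", px)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]

    def count(self) -> int:
        """Number of true pixels."""
        return int(self.pixels.sum())


def load_channel(
    path: str | Path,
    pixel_size: float = DEFAULT_PIXEL_SIZE_UM,
    label: str = "",
) -> IntensityImage:
    """Read a single-channel grayscale TIFF or PNG.

    Multi-channel/multi-plane files are rejected: the caller must split
    channels before analysis (calibration and labels live in the project
    config, not in image metadata).

    Raises
    ------
    OSError
        If the file cannot be read or decoded.
    FormatError
        If the decoded array is not 2-D uint8/uint16.
    """
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        arr = tifffile.imread(path)
    else:
        with _PILImage.open(path) as im:
            arr = np.asarray(im)
    arr = np.asarray(arr)
    if arr.ndim != 2:
        raise FormatError(
            f"{path.name}: expected single-channel grayscale, got shape {arr.shape}"
        )
    if arr.dtype == np.uint8:
        depth = 8
    elif arr.dtype == np.uint16:
        depth = 16
    elif arr.dtype == np.int32 and arr.min() >= 0 and arr.max() <= 65535:
        # PIL reads 16-bit PNG as mode "I" (int32)
        arr = arr.astype(np.uint16)
        depth = 16
    else:
        raise FormatError(f"{path.name}: unsupported dtype {arr.dtype}")
    return IntensityImage(arr, bit_depth=depth, pixel_size=pixel_size, channel_label=label)


def write_channel(image: IntensityImage, path: str | Path) -> None:
    """Write an IntensityImage as TIFF (any depth) or PNG (8-bit only)."""
    path = Path(path)
    dtype = np.uint8 if image.bit_depth == 8 else np.uint16
    arr = image.pixels.astype(dtype)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, arr)
    elif path.suffix.lower() == ".png":
        if image.bit_depth != 8:
            raise FormatError("PNG output supported for 8-bit images only; use TIFF")
        _PILImage.fromarray(arr, mode="L").save(path)
    else:
        raise FormatError(f"unsupported output format: {path.suffix}")


def to_uint8(image: IntensityImage) -> IntensityImage:
    """Convert to 8-bit by linear min-max rescaling.

    8-bit input is returned unchanged.  For 16-bit input the observed
    minimum maps to 0 and the observed maximum to 255, rounding half-up;
    a constant image maps to all zeros.  The operation is idempotent.
    """
    if image.bit_depth == 8:
        return image
    px = image.pixels.astype(np.float64)
    lo, hi = px.min(), px.max()
    if hi == lo:
        out = np.zeros(image.shape, dtype=np.uint8)
    else:
        out = np.floor((px - lo) * 255.0 / (hi - lo) + 0.5).astype(np.uint8)
    return IntensityImage(out, bit_depth=8, pixel_size=image.pixel_size,
                          channel_label=image.channel_label)


def apply_threshold(image: IntensityImage, threshold: float) -> BinaryMask:
    """Binarize: mask is true exactly where intensity >= threshold.

    The lower bound is inclusive, matching the convention of interactive
    threshold tools where the selected value is part of the foreground.

    Raises
    ------
    ParameterError
        If the threshold lies outside the image's representable range.
    """
    if not (0 <= threshold <= image.max_value):
        raise ParameterError(
            f"threshold {threshold} outside [0, {image.max_value}] "
            f"for bit depth {image.bit_depth}"
        )
    return BinaryMask(image.pixels >= threshold)
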