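"""Image loading, 8-bit grayscale conversion and spatial calibration.

All downstream measurements are made in pixel units and converted to
micrometers by multiplying with ``um_per_px`` (lengths) or ``um_per_px**2``
(areas).  Calibration never resamples the image.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np

__all__ = [
    "CalibratedImage",
    "InputError",
    "load_image",
    "to_8bit_gray",
    "calibrate_from_scale_bar",
    "load_calibrated",
]

#: ITU-R BT.601 luminance weights, offered as an alternative to the
#: unweighted channel mean used by default.
LUMA_WEIGHTS = (0.299, 0.587, 0.114)


class InputError(ValueError):
    """Raised for unreadable, empty or otherwise invalid user input."""


@dataclass(frozen=True)
class CalibratedImage:
    """A 2-D 8-bit intensity raster with micrometer-per-pixel calibration.

    Parameters
    ----------
    pixels
        2-D array with values in ``[0, 255]``.  Stored as float64 so that
        intermediate filters do not lose precision; values always remain
        inside the 8-bit range.
    um_per_px
        Positive scalar calibration factor (micrometers per pixel).
    """

    pixels: np.ndarray
    um_per_px: float

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=np.float64)
        if px.ndim != 2 or px.size == 0:
            raise InputError("pixels must be a non-empty 2-D array")
        if px.min() < 0 or px.max() > 255:
            raise InputError("pixel intensities must lie in [0, 255]")
        if not (self.um_per_px > 0):
            raise InputError("um_per_px must be > 0")
        object.__setattr__(self, "pixels", px)

    @property
    def height_px(self) -> int:
        return int(self.pixels.shape[0])

    @property
    def width_px(self) -> int:
        return int(self.pixels.shape[1])

    @property
    def area_um2(self) -> float:
        """Full-field area in square micrometers."""
        return self.width_px * self.height_px * self.um_per_px**2

    def with_pixels(self, pixels: np.ndarray) -> "CalibratedImage":
        """Return a copy carrying the same calibration but new pixel data."""
        return CalibratedImage(pixels=pixels, um_per_px=self.um_per_px)


def load_image(path: str | Path) -> np.ndarray:
    """Read a TIFF/PNG/JPG image, preserving its native bit depth.

    Returns the raw raster (2-D grayscale or 3-D with a trailing channel
    axis).  Raises :class:`InputError` for unreadable or zero-size files.
    """
    path = Path(path)
    if not path.is_file():
        raise InputError(f"image file not found: {path}")
    try:
        raster = iio.imread(path)
    except Exception as exc:  # decoder errors vary by plugin
        raise InputError(f"could not decode image file: {path}") from exc
    raster = np.asarray(raster)
    if raster.size == 0:
        raise InputError(f"zero-size image: {path}")
    return raster


def to_8bit_gray(raster: np.ndarray, *, luminance: bool = False) -> np.ndarray:
    """Collapse a raster to a single 8-bit grayscale channel.

    RGB(A) images are collapsed with the unweighted channel mean
    ``(R+G+B)/3`` rounded to the nearest integer (alpha is ignored); pass
    ``luminance=True`` for BT.601 weights instead.  Integer dtypes deeper
    than 8 bits are rescaled linearly so the dtype range maps onto
    ``[0, 255]``.
    """
    raster = np.asarray(raster)
    if raster.size == 0:
        raise InputError("empty raster")
    if raster.ndim == 3:
        if raster.shape[2] > 4:
            raise InputError(f"unsupported channel count: {raster.shape[2]}")
        rgb = raster[..., :3].astype(np.float64)
        if luminance:
            gray = rgb @ np.asarray(LUMA_WEIGHTS)
        else:
            gray = rgb.mean(axis=2)
    elif raster.ndim == 2:
        gray = raster.astype(np.float64)
    else:
        raise InputError(f"expected a 2-D or 3-D raster, got ndim={raster.ndim}")

    if np.issubdtype(raster.dtype, np.integer):
        info = np.iinfo(raster.dtype)
        if info.max > 255:
            gray = gray * (255.0 / info.max)
    elif np.issubdtype(raster.dtype, np.floating):
        # float images are assumed to be in [0, 1] unless already 8-bit range
        if gray.max() <= 1.0:
            gray = gray * 255.0
    return np.clip(np.rint(gray), 0, 255)


def calibrate_from_scale_bar(line_length_px: float, known_distance_um: float) -> float:
    """Micrometers per pixel from a line drawn over the image scale bar."""
    if not (line_length_px > 0):
        raise InputError("line_length_px must be > 0")
    if not (known_distance_um > 0):
        raise InputError("known_distance_um must be > 0")
    return known_distance_um / line_length_px


def load_calibrated(
    path: str | Path, um_per_px: float, *, luminance: bool = False
) -> CalibratedImage:
    """Convenience: load + convert + attach calibration in one call."""
    return CalibratedImage(
        pixels=to_8bit_gray(load_image(path), luminance=luminance),
        um_per_px=um_per_px,
    )
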