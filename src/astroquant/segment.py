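"""Maximum-entropy thresholding and binary mask cleanup.

The mask convention throughout the package is foreground = stained
structures = 1, background = 0, regardless of display polarity.  With DAB
staining the structures are dark, so the default thresholding keeps
pixels at or below the threshold.

The cleanup chain after thresholding is fixed:
threshold -> despeckle -> close -> remove_outliers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi

from .io import CalibratedImage
from .preprocess import PreprocessParams, preprocess_image

__all__ = [
    "BinaryMask",
    "CleanupParams",
    "DegenerateHistogramError",
    "intensity_histogram",
    "max_entropy_threshold",
    "apply_threshold",
    "binary_close",
    "remove_outliers",
    "disk_footprint",
    "segment_image",
]

_SQUARE3 = np.ones((3, 3), dtype=bool)


class DegenerateHistogramError(ValueError):
    """Histogram carries all its mass in a single bin; no threshold exists."""


@dataclass(frozen=True)
class BinaryMask:
    """Strictly binary foreground mask with calibration."""

    pixels: np.ndarray
    um_per_px: float

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2 or px.size == 0:
            raise ValueError("mask must be a non-empty 2-D array")
        if px.dtype != bool:
            vals = np.unique(px)
            if not np.isin(vals, (0, 1)).all():
                raise ValueError("mask must be binary")
            px = px.astype(bool)
        if not (self.um_per_px > 0):
            raise ValueError("um_per_px must be > 0")
        object.__setattr__(self, "pixels", px)

    def with_pixels(self, pixels: np.ndarray) -> "BinaryMask":
        return BinaryMask(pixels=pixels, um_per_px=self.um_per_px)

    @property
    def area_um2(self) -> float:
        h, w = self.pixels.shape
        return h * w * self.um_per_px**2


@dataclass(frozen=True)
class CleanupParams:
    """Mask cleanup parameters (defaults follow the published protocol)."""

    outlier_radius_px: float = 2.0
    outlier_threshold: float = 50.0
    outlier_polarity: str = "bright"
    close_iterations: int = 1

    def __post_init__(self) -> None:
        if self.outlier_radius_px < 1:
            raise ValueError("outlier_radius_px must be >= 1")
        if self.outlier_threshold < 0:
            raise ValueError("outlier_threshold must be >= 0")
        if self.outlier_polarity not in ("bright", "dark"):
            raise ValueError("outlier_polarity must be 'bright' or 'dark'")
        if self.close_iterations < 1:
            raise ValueError("close_iterations must be >= 1")


def intensity_histogram(image: CalibratedImage) -> np.ndarray:
    """256-bin histogram of the rounded 8-bit intensities."""
    levels = np.clip(np.rint(image.pixels), 0, 255).astype(np.int64)
    return np.bincount(levels.ravel(), minlength=256)


def max_entropy_threshold(hist: np.ndarray) -> int:
    """Kapur-Sahoo-Wong maximum-entropy threshold of a 256-bin histogram.

    Returns the level ``t`` maximizing the sum of the Shannon entropies of
    the two classes ``{0..t}`` and ``{t+1..255}``, each normalized by its
    own probability mass.  Only splits with nonzero mass on both sides are
    candidates; ties are broken toward the smallest ``t``.
    """
    hist = np.asarray(hist, dtype=np.float64)
    if hist.shape != (256,):
        raise ValueError("histogram must have exactly 256 bins")
    if (hist < 0).any():
        raise ValueError("histogram counts must be non-negative")
    nonzero = np.flatnonzero(hist)
    if nonzero.size < 2:
        raise DegenerateHistogramError(
            "histogram needs at least two distinct nonzero bins"
        )
    p = hist / hist.sum()
    # plogp[i] = p_i * ln(p_i), with 0 ln 0 = 0
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(p > 0, p * np.log(np.where(p > 0, p, 1.0)), 0.0)
    cum_p = np.cumsum(p)
    cum_plogp = np.cumsum(plogp)
    total_plogp = cum_plogp[-1]

    best_t, best_h = -1, -np.inf
    for t in range(int(nonzero[0]), int(nonzero[-1])):
        p_low = cum_p[t]
        p_high = 1.0 - p_low
        if p_low <= 0 or p_high <= 0:
            continue
        # H_class = ln(P) - (sum p ln p over class) / P
        h_low = np.log(p_low) - cum_plogp[t] / p_low
        h_high = np.log(p_high) - (total_plogp - cum_plogp[t]) / p_high
        h = h_low + h_high
        if h > best_h + 1e-12:
            best_h, best_t = h, t
    return best_t


def apply_threshold(
    image: CalibratedImage, t: int, dark_foreground: bool = True
) -> BinaryMask:
    """Binarize: with ``dark_foreground`` pixels <= t become foreground."""
    levels = np.clip(np.rint(image.pixels), 0, 255)
    fg = levels <= t if dark_foreground else levels > t
    return BinaryMask(pixels=fg, um_per_px=image.um_per_px)


def binary_close(mask: BinaryMask, iterations: int = 1) -> BinaryMask:
    """Morphological closing with a 3x3 square: n dilations then n erosions.

    The erosion treats the region outside the image as foreground, which
    keeps closing extensive (input is a subset of the output) up to the
    image border.
    """
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    dilated = ndi.binary_dilation(
        mask.pixels, structure=_SQUARE3, iterations=iterations, border_value=0
    )
    closed = ndi.binary_erosion(
        dilated, structure=_SQUARE3, iterations=iterations, border_value=1
    )
    return mask.with_pixels(closed)


def disk_footprint(radius: float) -> np.ndarray:
    """Pixels whose center distance from the origin is <= radius."""
    r = int(np.floor(radius))
    yy, xx = np.mgrid[-r : r + 1, -r : r + 1]
    return (yy**2 + xx**2) <= radius**2


def remove_outliers(
    raster: np.ndarray,
    params: CleanupParams = CleanupParams(),
) -> np.ndarray:
    """Replace pixels deviating from their disk-neighborhood median.

    For each pixel the median over the disk of ``outlier_radius_px``
    (center included, edge replication at borders) is computed; with
    ``bright`` polarity a pixel is replaced by that median when
    ``pixel - median > outlier_threshold`` (``dark``: ``median - pixel``).
    """
    raster = np.asarray(raster, dtype=np.float64)
    footprint = disk_footprint(params.outlier_radius_px)
    med = ndi.median_filter(raster, footprint=footprint, mode="nearest")
    if params.outlier_polarity == "bright":
        outliers = raster - med > params.outlier_threshold
    else:
        outliers = med - raster > params.outlier_threshold
    return np.where(outliers, med, raster)


def _mask_remove_outliers(mask: BinaryMask, params: CleanupParams) -> BinaryMask:
    # the protocol runs the outlier filter on the 0/255 mask rendering
    cleaned = remove_outliers(mask.pixels.astype(np.float64) * 255.0, params)
    return mask.with_pixels(cleaned > 127.5)


def segment_image(
    image: CalibratedImage,
    cleanup: CleanupParams = CleanupParams(),
    *,
    dark_foreground: bool = True,
) -> BinaryMask:
    """Threshold (max entropy) then clean: despeckle -> close -> outliers."""
    t = max_entropy_threshold(intensity_histogram(image))
    mask = apply_threshold(image, t, dark_foreground=dark_foreground)
    # despeckle on the binary mask = 3x3 boolean median
    despeckled = ndi.median_filter(mask.pixels, size=3, mode="nearest")
    mask = mask.with_pixels(despeckled)
    mask = binary_close(mask, cleanup.close_iterations)
    return _mask_remove_outliers(mask, cleanup)


def segment_preprocessed(
    image: CalibratedImage,
    pre: PreprocessParams = PreprocessParams(),
    cleanup: CleanupParams = CleanupParams(),
    *,
    dark_foreground: bool = True,
) -> BinaryMask:
    """Preprocess then segment (the full image-to-mask front end)."""
    return segment_image(preprocess_image(image, pre), cleanup, dark_foreground=dark_foreground)
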