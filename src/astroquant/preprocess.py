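"""Grayscale preprocessing chain: FFT bandpass, unsharp mask, despeckle.

The bandpass transfer function is a difference of two Gaussian low-pass
filters in the frequency domain,

    B(u) = exp(-(pi * small_px * |u|)**2) - exp(-(pi * large_px * |u|)**2)

with ``|u|`` in cycles/pixel, so spatial structures larger than
``large_px`` (including the DC level) and smaller than ``small_px`` are
attenuated while the band in between passes.  Images are padded to a
square power-of-two size by mirror (symmetric) replication before the
transform and cropped afterwards, which suppresses both wraparound and
border-step artifacts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi

from .io import CalibratedImage, InputError

__all__ = [
    "PreprocessParams",
    "bandpass_transfer",
    "fft_bandpass",
    "unsharp_mask",
    "despeckle",
    "preprocess_image",
]


@dataclass(frozen=True)
class PreprocessParams:
    """Parameters of the preprocessing chain (reference-tool defaults)."""

    bandpass_large_px: float = 40.0
    bandpass_small_px: float = 3.0
    # NB: the reference tool's "5%" bandpass setting is a stripe-direction
    # tolerance, not a saturation fraction; clipping 5% of pixels destroys
    # sparse signals, so the autoscale default saturates only 0.35%.
    bandpass_saturate_pct: float = 0.35
    bandpass_autoscale: bool = True
    unsharp_radius_px: float = 1.0
    unsharp_weight: float = 0.6

    def __post_init__(self) -> None:
        if not (self.bandpass_large_px > self.bandpass_small_px >= 0):
            raise ValueError("require bandpass_large_px > bandpass_small_px >= 0")
        if not (0 < self.unsharp_weight < 1):
            raise ValueError("unsharp_weight must be in (0, 1)")


def _next_pow2(n: int) -> int:
    p = 1
    while p < n:
        p *= 2
    return p


def bandpass_transfer(n: int, small_px: float, large_px: float) -> np.ndarray:
    """The n-by-n frequency-domain band transfer function B(u)."""
    f = np.fft.fftfreq(n)  # cycles per pixel
    fy, fx = np.meshgrid(f, f, indexing="ij")
    r2 = fy**2 + fx**2
    return np.exp(-((np.pi * small_px) ** 2) * r2) - np.exp(
        -((np.pi * large_px) ** 2) * r2
    )


def _pad_to_square_pow2(pixels: np.ndarray) -> tuple[np.ndarray, tuple[int, int]]:
    h, w = pixels.shape
    n = _next_pow2(int(np.ceil(1.5 * max(h, w))))
    top = (n - h) // 2
    left = (n - w) // 2
    # mirror padding: edge replication turns the noisy border row/column
    # into long constant stripes whose band response bleeds back into the
    # cropped image as spurious dark rims
    padded = np.pad(
        pixels, ((top, n - h - top), (left, n - w - left)), mode="symmetric"
    )
    return padded, (top, left)


def _autoscale(band: np.ndarray, saturate_pct: float) -> np.ndarray:
    # clip saturate_pct of pixels symmetrically, then map linearly to [0,255]
    lo = np.percentile(band, saturate_pct / 2.0)
    hi = np.percentile(band, 100.0 - saturate_pct / 2.0)
    if hi <= lo:
        return np.full_like(band, 127.5)
    out = (band - lo) * (255.0 / (hi - lo))
    return np.clip(out, 0, 255)


def fft_bandpass(
    image: CalibratedImage, params: PreprocessParams = PreprocessParams()
) -> CalibratedImage:
    """Frequency-domain bandpass retaining structures between the two scales.

    With ``bandpass_autoscale`` the filtered image is rescaled linearly to
    [0, 255] with ``bandpass_saturate_pct`` of pixels clipped symmetrically
    at both tails; otherwise the input mean is restored and the result
    clipped to [0, 255].
    """
    if image.pixels.size == 0:
        raise InputError("empty image")
    padded, (top, left) = _pad_to_square_pow2(image.pixels)
    n = padded.shape[0]
    transfer = bandpass_transfer(
        n, params.bandpass_small_px, params.bandpass_large_px
    )
    band = np.fft.ifft2(np.fft.fft2(padded) * transfer).real
    h, w = image.pixels.shape
    band = band[top : top + h, left : left + w]
    if params.bandpass_autoscale:
        out = _autoscale(band, params.bandpass_saturate_pct)
    else:
        out = np.clip(band + image.pixels.mean(), 0, 255)
    return image.with_pixels(out)


def unsharp_mask(
    image: CalibratedImage, radius_px: float = 1.0, weight: float = 0.6
) -> CalibratedImage:
    """Gaussian unsharp mask: ``(I - w*G_sigma(I)) / (1 - w)``, clipped.

    ``radius_px`` is the Gaussian sigma; ``weight`` must be in (0, 1).
    """
    if not (0 < weight < 1):
        raise ValueError("weight must be in (0, 1)")
    blurred = ndi.gaussian_filter(image.pixels, sigma=radius_px, mode="nearest")
    sharp = (image.pixels - weight * blurred) / (1.0 - weight)
    return image.with_pixels(np.clip(sharp, 0, 255))


def despeckle(image: CalibratedImage) -> CalibratedImage:
    """3x3 median filter; border pixels use edge replication."""
    if image.pixels.size == 0:
        raise InputError("empty image")
    return image.with_pixels(ndi.median_filter(image.pixels, size=3, mode="nearest"))


def preprocess_image(
    image: CalibratedImage, params: PreprocessParams = PreprocessParams()
) -> CalibratedImage:
    """Full chain: bandpass -> unsharp mask -> despeckle."""
    out = fft_bandpass(image, params)
    out = unsharp_mask(out, params.unsharp_radius_px, params.unsharp_weight)
    return despeckle(out)
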