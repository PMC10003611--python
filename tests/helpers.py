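"""Independent oracles used by the test suite.

Everything here is deliberately written as a naive, brute-force
re-derivation (explicit loops, direct DFT matrices, scan-and-accumulate)
so it shares no code path with the package implementation it checks.
"""

from __future__ import annotations

import numpy as np


def kapur_threshold_bruteforce(hist: np.ndarray) -> int:
    """Exhaustive evaluation of the two-class maximum-entropy criterion.

    Scans every level t in 0..254; splits with an empty class are invalid.
    Ties break toward the smallest t.
    """
    hist = np.asarray(hist, dtype=float)
    p = hist / hist.sum()
    best_t, best_h = -1, -np.inf
    for t in range(255):
        p_low = p[: t + 1].sum()
        p_high = p[t + 1 :].sum()
        if p_low == 0 or p_high == 0:
            continue
        h = 0.0
        for q in p[: t + 1]:
            if q > 0:
                h -= (q / p_low) * np.log(q / p_low)
        for q in p[t + 1 :]:
            if q > 0:
                h -= (q / p_high) * np.log(q / p_high)
        if h > best_h + 1e-12:
            best_h, best_t = h, t
    return best_t


def dft_matrix(n: int) -> np.ndarray:
    j = np.arange(n)
    return np.exp(-2j * np.pi * np.outer(j, j) / n)


def bandpass_oracle(
    pixels: np.ndarray, small_px: float, large_px: float
) -> np.ndarray:
    """Direct-DFT application of the documented band transfer function.

    Pads exactly like the implementation (mirror replication to the
    power-of-two square) but performs the transform with explicit DFT
    matrices and builds the transfer function with explicit loops.
    Returns the *pre-autoscale* band image (input mean restored, clipped),
    matching ``fft_bandpass`` with autoscale off.
    """
    h, w = pixels.shape
    n = 1
    while n < int(np.ceil(1.5 * max(h, w))):
        n *= 2
    top = (n - h) // 2
    left = (n - w) // 2
    padded = np.pad(
        pixels, ((top, n - h - top), (left, n - w - left)), mode="symmetric"
    ).astype(float)

    freqs = np.fft.fftfreq(n)
    transfer = np.empty((n, n))
    for i in range(n):
        for j in range(n):
            r2 = freqs[i] ** 2 + freqs[j] ** 2
            transfer[i, j] = np.exp(-((np.pi * small_px) ** 2) * r2) - np.exp(
                -((np.pi * large_px) ** 2) * r2
            )

    W = dft_matrix(n)
    Winv = np.conj(W) / n
    spectrum = W @ padded @ W.T
    band = (Winv @ (spectrum * transfer) @ Winv.T).real
    band = band[top : top + h, left : left + w]
    return np.clip(band + pixels.mean(), 0, 255)


def median3x3_bruteforce(pixels: np.ndarray) -> np.ndarray:
    """3x3 median with edge replication, computed pixel by pixel."""
    h, w = pixels.shape
    out = np.empty_like(pixels, dtype=float)
    for y in range(h):
        for x in range(w):
            vals = []
            for dy in (-1, 0, 1):
                for dx in (-1, 0, 1):
                    ny = min(max(y + dy, 0), h - 1)
                    nx = min(max(x + dx, 0), w - 1)
                    vals.append(pixels[ny, nx])
            out[y, x] = np.median(vals)
    return out


def disk_median_bruteforce(pixels: np.ndarray, radius: float) -> np.ndarray:
    """Median over the disk of given radius (center included), edge-replicated."""
    h, w = pixels.shape
    r = int(np.floor(radius))
    offsets = [
        (dy, dx)
        for dy in range(-r, r + 1)
        for dx in range(-r, r + 1)
        if dy * dy + dx * dx <= radius * radius
    ]
    out = np.empty_like(pixels, dtype=float)
    for y in range(h):
        for x in range(w):
            vals = []
            for dy, dx in offsets:
                ny = min(max(y + dy, 0), h - 1)
                nx = min(max(x + dx, 0), w - 1)
                vals.append(pixels[ny, nx])
            out[y, x] = np.median(vals)
    return out


def spreadsheet_oracle(records):
    """COUNTIF/SUMIF + duplicate-filter semantics, scan-and-accumulate.

    ``records`` is a sequence of (skeleton_id, branch_length) pairs.
    Returns (filtered_pairs, {id: (count, total_length)}).
    """
    occurrences = {}
    for sid, _ in records:
        occurrences[sid] = occurrences.get(sid, 0) + 1
    filtered = [(sid, ln) for sid, ln in records if occurrences[sid] > 1]
    table = {}
    for sid, _ in filtered:
        if sid not in table:
            count = 0
            total = 0.0
            for sid2, ln2 in filtered:
                if sid2 == sid:
                    count += 1
                    total += ln2
            table[sid] = (count, total)
    return filtered, table


def random_blob_mask(rng: np.random.Generator, shape=(64, 64)) -> np.ndarray:
    """Smoothed-noise blob mask, the standard random shape for topology tests."""
    from scipy.ndimage import gaussian_filter

    noise = gaussian_filter(rng.normal(size=shape), 3.0)
    return noise > np.quantile(noise, 0.8)
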