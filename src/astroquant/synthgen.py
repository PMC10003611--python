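"""Synthetic DAB-like photomicrograph generator with exact ground truth.

Renders star-shaped dark cells (disk soma + straight arms) on a bright
noisy background, plus isolated short bars ("singleton fragments") that a
correct pipeline must discard.  Arm lengths are recorded from the soma
boundary to the tip, matching what skeletonization can recover.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SynthSpec",
    "CellTruth",
    "GroundTruth",
    "GenerationError",
    "generate",
    "match_recovered_cells",
]


class GenerationError(ValueError):
    """Requested layout does not fit on the canvas."""


@dataclass(frozen=True)
class SynthSpec:
    width_px: int = 1024
    height_px: int = 1024
    um_per_px: float = 0.5
    n_cells: int = 10
    branches_min: int = 3
    branches_max: int = 6
    branch_length_um_min: float = 10.0
    branch_length_um_max: float = 30.0
    branch_thickness_px: int = 3
    soma_radius_px: int = 5
    background_level: int = 200
    foreground_level: int = 60
    noise_sd: float = 8.0
    n_singleton_fragments: int = 5
    fragment_length_um: float = 6.0
    min_arm_gap_deg: float = 55.0
    allow_overlap: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.branch_thickness_px < 2:
            raise ValueError("branch_thickness_px must be >= 2")
        if self.foreground_level >= self.background_level:
            raise ValueError("foreground must be darker than background")
        if not (0 < self.branches_min <= self.branches_max):
            raise ValueError("invalid branch count range")
        if not (0 < self.branch_length_um_min <= self.branch_length_um_max):
            raise ValueError("invalid branch length range")


@dataclass(frozen=True)
class CellTruth:
    center: tuple[int, int]  # (row, col)
    branch_lengths_um: tuple[float, ...]

    @property
    def branch_count(self) -> int:
        return len(self.branch_lengths_um)

    @property
    def total_branch_length_um(self) -> float:
        return float(sum(self.branch_lengths_um))


@dataclass(frozen=True)
class GroundTruth:
    cells: tuple[CellTruth, ...]
    n_singleton_fragments: int
    spec: SynthSpec = field(repr=False, default=None)

    @property
    def n_cells(self) -> int:
        return len(self.cells)


def _draw_disk(canvas: np.ndarray, cy: float, cx: float, radius: float) -> None:
    h, w = canvas.shape
    y0, y1 = max(0, int(cy - radius) - 1), min(h, int(cy + radius) + 2)
    x0, x1 = max(0, int(cx - radius) - 1), min(w, int(cx + radius) + 2)
    yy, xx = np.mgrid[y0:y1, x0:x1]
    canvas[y0:y1, x0:x1] |= (yy - cy) ** 2 + (xx - cx) ** 2 <= radius**2


def _draw_bar(
    canvas: np.ndarray,
    p0: tuple[float, float],
    p1: tuple[float, float],
    thickness_px: float,
) -> None:
    """Solid bar: stamp disks of diameter `thickness_px` along the segment."""
    length = float(np.hypot(p1[0] - p0[0], p1[1] - p0[1]))
    n_steps = max(2, int(np.ceil(length * 2)) + 1)
    r = thickness_px / 2.0
    for t in np.linspace(0.0, 1.0, n_steps):
        _draw_disk(canvas, p0[0] + t * (p1[0] - p0[0]), p0[1] + t * (p1[1] - p0[1]), r)


def _place_centers(
    rng: np.random.Generator, spec: SynthSpec, n: int, margin: float, min_sep: float
) -> list[tuple[float, float]]:
    """Rejection-sample `n` points with pairwise distance >= min_sep."""
    centers: list[tuple[float, float]] = []
    lo_y, hi_y = margin, spec.height_px - margin
    lo_x, hi_x = margin, spec.width_px - margin
    if hi_y <= lo_y or hi_x <= lo_x:
        raise GenerationError("canvas too small for the requested geometry")
    for _ in range(20000):
        if len(centers) == n:
            return centers
        cy = rng.uniform(lo_y, hi_y)
        cx = rng.uniform(lo_x, hi_x)
        if all(np.hypot(cy - y, cx - x) >= min_sep for y, x in centers):
            centers.append((cy, cx))
    raise GenerationError(
        f"could not place {n} objects with separation {min_sep:.0f}px "
        f"on a {spec.height_px}x{spec.width_px} canvas"
    )


def _arm_angles(rng: np.random.Generator, k: int, min_gap_rad: float) -> np.ndarray:
    """k angles: evenly spaced with jitter, keeping a minimum angular gap."""
    base = np.linspace(0.0, 2 * np.pi, k, endpoint=False)
    spacing = 2 * np.pi / k
    jitter = rng.uniform(-0.5, 0.5, size=k) * max(0.0, spacing - min_gap_rad)
    return base + rng.uniform(0, 2 * np.pi) + jitter


def generate(spec: SynthSpec) -> tuple[np.ndarray, GroundTruth]:
    """Render one synthetic image; deterministic given ``spec.seed``.

    Returns (uint8 image, ground truth).
    """
    rng = np.random.default_rng(spec.seed)
    max_len_px = spec.branch_length_um_max / spec.um_per_px
    reach = spec.soma_radius_px + max_len_px + spec.branch_thickness_px
    margin = reach + 4
    min_sep = 0.0 if spec.allow_overlap else 2.0 * max_len_px

    fg = np.zeros((spec.height_px, spec.width_px), dtype=bool)
    cells: list[CellTruth] = []

    n_objects = spec.n_cells + spec.n_singleton_fragments
    centers = (
        _place_centers(rng, spec, n_objects, margin, min_sep) if n_objects else []
    )

    min_gap = np.deg2rad(spec.min_arm_gap_deg)
    for cy, cx in centers[: spec.n_cells]:
        k = int(rng.integers(spec.branches_min, spec.branches_max + 1))
        angles = _arm_angles(rng, k, min_gap)
        lengths_um = rng.uniform(
            spec.branch_length_um_min, spec.branch_length_um_max, size=k
        )
        _draw_disk(fg, cy, cx, spec.soma_radius_px)
        for ang, lum in zip(angles, lengths_um):
            lpx = lum / spec.um_per_px
            d = (np.sin(ang), np.cos(ang))
            p0 = (cy + spec.soma_radius_px * d[0], cx + spec.soma_radius_px * d[1])
            p1 = (
                cy + (spec.soma_radius_px + lpx) * d[0],
                cx + (spec.soma_radius_px + lpx) * d[1],
            )
            _draw_bar(fg, p0, p1, spec.branch_thickness_px)
        cells.append(
            CellTruth(center=(int(round(cy)), int(round(cx))),
                      branch_lengths_um=tuple(float(v) for v in lengths_um))
        )

    frag_len_px = spec.fragment_length_um / spec.um_per_px
    for cy, cx in centers[spec.n_cells :]:
        ang = rng.uniform(0, 2 * np.pi)
        d = (np.sin(ang), np.cos(ang))
        half = frag_len_px / 2.0
        _draw_bar(
            fg,
            (cy - half * d[0], cx - half * d[1]),
            (cy + half * d[0], cx + half * d[1]),
            spec.branch_thickness_px,
        )

    img = np.full(fg.shape, float(spec.background_level))
    img[fg] = float(spec.foreground_level)
    if spec.noise_sd > 0:
        img += rng.normal(0.0, spec.noise_sd, size=fg.shape)
    img = np.clip(np.rint(img), 0, 255).astype(np.uint8)

    truth = GroundTruth(
        cells=tuple(cells),
        n_singleton_fragments=spec.n_singleton_fragments,
        spec=spec,
    )
    return img, truth


def match_recovered_cells(
    truth: GroundTruth,
    skeleton_px: np.ndarray,
    summaries,
    max_dist_px: float = 40.0,
):
    """Match ground-truth cells to recovered skeleton components by centroid.

    ``summaries`` is the post-filter list of per-skeleton summaries;
    component labels follow the branch-table convention (8-connected,
    raster-scan order).  Returns a list of
    ``(CellTruth, SkeletonSummary | None)`` pairs, one per true cell.
    """
    from scipy import ndimage as ndi

    labels, n = ndi.label(np.asarray(skeleton_px, bool), structure=np.ones((3, 3)))
    by_id = {s.skeleton_id: s for s in summaries}
    ids = sorted(by_id)
    if ids:
        centroids = ndi.center_of_mass(np.ones_like(labels), labels, ids)
    else:
        centroids = []
    pairs = []
    taken: set[int] = set()
    for cell in truth.cells:
        best, best_d = None, max_dist_px
        for sid, (cy, cx) in zip(ids, centroids):
            if sid in taken:
                continue
            d = float(np.hypot(cy - cell.center[0], cx - cell.center[1]))
            if d < best_d:
                best, best_d = sid, d
        if best is None:
            pairs.append((cell, None))
        else:
            taken.add(best)
            pairs.append((cell, by_id[best]))
    return pairs
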