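"""Spreadsheet-equivalent data trimming and aggregation.

Reproduces the datasheet post-processing applied to the branch table:
singleton removal (a skeleton with exactly one branch is not counted as a
cell), per-skeleton count/sum aggregation, per-image summaries with a
cell-normalized branch-length histogram, zone-level pooling, and the
per-group ratio metrics.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from .skeleton import BranchRecord

__all__ = [
    "SkeletonSummary",
    "ImageSummary",
    "GroupRow",
    "DEFAULT_BIN_EDGES_UM",
    "filter_singletons",
    "summarize_skeletons",
    "summarize_image",
    "summarize_zone",
    "group_metrics",
    "virtual_cell_points",
]

#: Default branch-length interval edges (µm).  The final bin is open-ended.
DEFAULT_BIN_EDGES_UM: tuple[float, ...] = (0.0, 5.0, 10.0, 15.0, 20.0, 30.0, 50.0, np.inf)


@dataclass(frozen=True)
class SkeletonSummary:
    """Per-cell record: branch count and summed branch length."""

    skeleton_id: int
    branch_count: int
    total_branch_length_um: float


@dataclass(frozen=True)
class ImageSummary:
    """Per-image aggregate ('Key' table row).

    ``bin_counts`` holds the raw branch counts per length interval;
    ``binned_mode`` is the same histogram divided by ``n_cells`` (all
    zeros, with ``empty`` set, when the image has no cells).
    """

    image_id: str
    n_cells: int
    n_branches: int
    total_length_um: float
    bin_edges_um: tuple[float, ...]
    bin_counts: tuple[int, ...]
    area_um2: float
    empty: bool = field(default=False)

    @property
    def binned_mode(self) -> np.ndarray:
        counts = np.asarray(self.bin_counts, dtype=np.float64)
        if self.n_cells == 0:
            return np.zeros_like(counts)
        return counts / self.n_cells

    @property
    def modal_bin(self) -> int | None:
        """Index of the most populated length interval (None if empty)."""
        if self.n_branches == 0:
            return None
        return int(np.argmax(self.bin_counts))


@dataclass(frozen=True)
class GroupRow:
    """Per-zone/animal/group metrics row.

    Ratio semantics: branches_per_cell = n_branches / n_cells,
    cells_per_area = n_cells / area_um2 (cells per µm²),
    length_per_cell_um = total_length_um / n_cells.
    """

    group_id: str
    animal_id: str
    zone_id: str
    area_um2: float
    n_cells: int
    n_branches: int
    total_length_um: float
    branches_per_cell: float
    cells_per_area: float
    length_per_cell_um: float


def filter_singletons(records: list[BranchRecord]) -> list[BranchRecord]:
    """Drop every record whose skeleton_id occurs exactly once.

    This is the duplicate-entry filter on the raw branch table: a skeleton
    with a single branch is not considered an astrocyte.  Order of the
    surviving records is preserved; idempotent.
    """
    counts = Counter(r.skeleton_id for r in records)
    return [r for r in records if counts[r.skeleton_id] > 1]


def summarize_skeletons(records: list[BranchRecord]) -> list[SkeletonSummary]:
    """Per-skeleton branch count and total length (COUNTIF/SUMIF analog).

    Input must already be singleton-filtered; a skeleton_id with a single
    record raises ``ValueError``.
    """
    counts: dict[int, int] = {}
    sums: dict[int, float] = {}
    order: list[int] = []
    for r in records:
        if r.skeleton_id not in counts:
            counts[r.skeleton_id] = 0
            sums[r.skeleton_id] = 0.0
            order.append(r.skeleton_id)
        counts[r.skeleton_id] += 1
        sums[r.skeleton_id] += r.branch_length_um
    bad = [sid for sid in order if counts[sid] == 1]
    if bad:
        raise ValueError(
            f"skeleton ids with a single branch reached summarize_skeletons: {bad}"
        )
    return [
        SkeletonSummary(sid, counts[sid], sums[sid]) for sid in order
    ]


def _bin_lengths(lengths: np.ndarray, edges: np.ndarray) -> np.ndarray:
    """Histogram with half-open bins [e_k, e_{k+1}); final bin right-closed."""
    idx = np.searchsorted(edges, lengths, side="right") - 1
    nbins = len(edges) - 1
    idx = np.where((lengths == edges[-1]), nbins - 1, idx)
    valid = (idx >= 0) & (idx < nbins)
    return np.bincount(idx[valid], minlength=nbins)[:nbins]


def summarize_image(
    summaries: list[SkeletonSummary],
    branch_lengths_um,
    bin_edges_um=DEFAULT_BIN_EDGES_UM,
    area_um2: float = np.nan,
    image_id: str = "",
) -> ImageSummary:
    """Per-image 'Key' row: cell count, totals, binned length distribution."""
    edges = np.asarray(bin_edges_um, dtype=np.float64)
    if edges.ndim != 1 or len(edges) < 2 or not np.all(np.diff(edges) > 0):
        raise ValueError("bin_edges_um must be strictly ascending with >= 2 edges")
    lengths = np.asarray(list(branch_lengths_um), dtype=np.float64)
    n_cells = len(summaries)
    counts = _bin_lengths(lengths, edges) if lengths.size else np.zeros(len(edges) - 1, int)
    total = float(sum(s.total_branch_length_um for s in summaries))
    n_branches = int(sum(s.branch_count for s in summaries))
    return ImageSummary(
        image_id=image_id,
        n_cells=n_cells,
        n_branches=n_branches,
        total_length_um=total,
        bin_edges_um=tuple(edges),
        bin_counts=tuple(int(c) for c in counts),
        area_um2=float(area_um2),
        empty=(n_cells == 0),
    )


def summarize_zone(images: list[ImageSummary], zone_id: str = "") -> ImageSummary:
    """Pool image summaries into one zone summary.

    Cell counts, branch counts, lengths, areas and raw bin counts are
    summed; the normalized histogram is recomputed from the pooled counts
    (never averaged across images).
    """
    if not images:
        raise ValueError("summarize_zone requires at least one image summary")
    edges = images[0].bin_edges_um
    for im in images[1:]:
        if im.bin_edges_um != edges:
            raise ValueError("all images in a zone must share bin edges")
    n_cells = sum(im.n_cells for im in images)
    counts = tuple(int(s) for s in np.sum([im.bin_counts for im in images], axis=0))
    return ImageSummary(
        image_id=zone_id,
        n_cells=n_cells,
        n_branches=sum(im.n_branches for im in images),
        total_length_um=float(sum(im.total_length_um for im in images)),
        bin_edges_um=edges,
        bin_counts=counts,
        area_um2=float(sum(im.area_um2 for im in images)),
        empty=(n_cells == 0),
    )


def group_metrics(
    zone: ImageSummary,
    group_id: str = "",
    animal_id: str = "",
    zone_id: str = "",
) -> GroupRow:
    """The three ratio metrics for one zone; NaN (with a warning) if no cells."""
    if zone.n_cells == 0:
        warnings.warn(
            f"zone '{zone.image_id}' has no cells; ratio metrics are undefined",
            stacklevel=2,
        )
        bpc = cpa = lpc = float("nan")
    else:
        bpc = zone.n_branches / zone.n_cells
        cpa = zone.n_cells / zone.area_um2 if zone.area_um2 > 0 else float("nan")
        lpc = zone.total_length_um / zone.n_cells
    return GroupRow(
        group_id=group_id,
        animal_id=animal_id,
        zone_id=zone_id or zone.image_id,
        area_um2=zone.area_um2,
        n_cells=zone.n_cells,
        n_branches=zone.n_branches,
        total_length_um=zone.total_length_um,
        branches_per_cell=bpc,
        cells_per_area=cpa,
        length_per_cell_um=lpc,
    )


def virtual_cell_points(
    summaries: list[SkeletonSummary],
) -> list[tuple[int, float]]:
    """One (branch_count, total_branch_length_um) point per cell."""
    return [(s.branch_count, s.total_branch_length_um) for s in summaries]
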