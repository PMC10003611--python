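"""Batch pipeline: per-image processing and zone/group roll-up.

The analysis path is fully deterministic; all randomness lives in the
synthetic generator.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .io import CalibratedImage, load_calibrated
from .preprocess import PreprocessParams, preprocess_image
from .quantify import (
    DEFAULT_BIN_EDGES_UM,
    GroupRow,
    ImageSummary,
    SkeletonSummary,
    filter_singletons,
    group_metrics,
    summarize_image,
    summarize_skeletons,
    summarize_zone,
    virtual_cell_points,
)
from .segment import BinaryMask, CleanupParams, segment_image
from .skeleton import BranchRecord, build_branch_table, skeletonize

log = logging.getLogger("astroquant")

__all__ = ["PipelineConfig", "ImageResult", "process_image", "run_pipeline"]


@dataclass(frozen=True)
class PipelineConfig:
    """Every knob of the analysis path, serializable to/from YAML."""

    um_per_px: float = 1.0
    luminance_gray: bool = False
    dark_foreground: bool = True
    preprocess: PreprocessParams = field(default_factory=PreprocessParams)
    cleanup: CleanupParams = field(default_factory=CleanupParams)
    bin_edges_um: tuple[float, ...] = DEFAULT_BIN_EDGES_UM
    save_intermediates: bool = False

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["bin_edges_um"] = [
            "inf" if np.isinf(e) else float(e) for e in self.bin_edges_um
        ]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "preprocess" in d:
            d["preprocess"] = PreprocessParams(**d["preprocess"])
        if "cleanup" in d:
            d["cleanup"] = CleanupParams(**d["cleanup"])
        if "bin_edges_um" in d:
            d["bin_edges_um"] = tuple(
                np.inf if e in ("inf", ".inf") else float(e) for e in d["bin_edges_um"]
            )
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})


@dataclass(frozen=True)
class ImageResult:
    """Everything the pipeline extracts from one image."""

    image_id: str
    records: list[BranchRecord]
    filtered: list[BranchRecord]
    summaries: list[SkeletonSummary]
    summary: ImageSummary
    mask: BinaryMask
    skeleton: np.ndarray


def process_image(
    image: CalibratedImage,
    config: PipelineConfig,
    image_id: str = "",
    area_um2: float | None = None,
) -> ImageResult:
    """Run preprocess -> segment -> skeletonize -> branch analysis -> trim."""
    pre = preprocess_image(image, config.preprocess)
    mask = segment_image(pre, config.cleanup, dark_foreground=config.dark_foreground)
    skel = skeletonize(mask)
    records = build_branch_table(skel)
    filtered = filter_singletons(records)
    summaries = summarize_skeletons(filtered)
    summary = summarize_image(
        summaries,
        [r.branch_length_um for r in filtered],
        config.bin_edges_um,
        area_um2=image.area_um2 if area_um2 is None else area_um2,
        image_id=image_id,
    )
    return ImageResult(
        image_id=image_id,
        records=records,
        filtered=filtered,
        summaries=summaries,
        summary=summary,
        mask=mask,
        skeleton=skel.pixels,
    )


def _edges_header(edges: tuple[float, ...]) -> list[str]:
    labels = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        hi_s = "inf" if np.isinf(hi) else f"{hi:g}"
        labels.append(f"branches_per_cell_len_{lo:g}_{hi_s}_um")
    return labels


def _summary_frame(rows: list[ImageSummary], id_col: str) -> pd.DataFrame:
    edges = rows[0].bin_edges_um
    data = []
    for s in rows:
        row = {
            id_col: s.image_id,
            "n_cells": s.n_cells,
            "n_branches": s.n_branches,
            "total_length_um": s.total_length_um,
            "area_um2": s.area_um2,
            "modal_bin": s.modal_bin if s.modal_bin is not None else "",
        }
        for name, v in zip(_edges_header(edges), s.binned_mode):
            row[name] = v
        data.append(row)
    return pd.DataFrame(data)


def run_pipeline(
    manifest_path: str | Path,
    config: PipelineConfig,
    outdir: str | Path,
) -> int:
    """Process every image in the manifest and write all output tables.

    Manifest CSV columns: ``image,animal,zone,group[,area_um2]``.  Returns
    0 on full success, 3 if some images failed (they are logged and
    skipped).  Raises on an empty or unreadable manifest.
    """
    manifest_path = Path(manifest_path)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = pd.read_csv(manifest_path)
    required = {"image", "animal", "zone", "group"}
    if manifest.empty:
        raise ValueError(f"manifest has no rows: {manifest_path}")
    if not required.issubset(manifest.columns):
        raise ValueError(f"manifest must have columns {sorted(required)}")

    config.to_yaml(outdir / "config_snapshot.yaml")

    per_image: list[tuple[pd.Series, ImageResult]] = []
    n_failed = 0
    for _, row in manifest.iterrows():
        img_path = Path(row["image"])
        if not img_path.is_absolute():
            img_path = manifest_path.parent / img_path
        image_id = img_path.stem
        try:
            image = load_calibrated(
                img_path, config.um_per_px, luminance=config.luminance_gray
            )
            area = row.get("area_um2", np.nan)
            area = None if pd.isna(area) else float(area)
            result = process_image(image, config, image_id=image_id, area_um2=area)
        except Exception:
            log.exception("failed to process %s; skipping", img_path)
            n_failed += 1
            continue
        per_image.append((row, result))
        _write_image_outputs(outdir, result, config)

    if not per_image:
        raise ValueError("no image in the manifest could be processed")

    _write_aggregates(outdir, per_image)
    log.info(
        "processed %d image(s), %d failed; outputs in %s",
        len(per_image), n_failed, outdir,
    )
    return 3 if n_failed else 0


def _write_image_outputs(
    outdir: Path, result: ImageResult, config: PipelineConfig
) -> None:
    stem = result.image_id
    pd.DataFrame(
        [
            {"image": stem, "skeleton_id": r.skeleton_id,
             "branch_length_um": r.branch_length_um}
            for r in result.records
        ]
    ).to_csv(outdir / f"{stem}_branches.csv", index=False)
    pd.DataFrame(
        [
            {"skeleton_id": s.skeleton_id, "branch_count": s.branch_count,
             "total_branch_length_um": s.total_branch_length_um}
            for s in result.summaries
        ]
    ).to_csv(outdir / f"{stem}_cells.csv", index=False)
    if config.save_intermediates:
        import imageio.v3 as iio

        iio.imwrite(
            outdir / f"{stem}_mask.png",
            (result.mask.pixels.astype(np.uint8) * 255),
        )
        iio.imwrite(
            outdir / f"{stem}_skeleton.png",
            (result.skeleton.astype(np.uint8) * 255),
        )


def _write_aggregates(outdir: Path, per_image) -> None:
    _summary_frame([res.summary for _, res in per_image], "image").to_csv(
        outdir / "image_summaries.csv", index=False
    )

    zones: dict[tuple, list] = {}
    for row, res in per_image:
        key = (str(row["group"]), str(row["animal"]), str(row["zone"]))
        zones.setdefault(key, []).append(res)

    zone_rows: list[ImageSummary] = []
    group_rows: list[GroupRow] = []
    scatter = []
    for (group, animal, zone), results in sorted(zones.items()):
        zid = f"{group}/{animal}/{zone}"
        zsum = summarize_zone([r.summary for r in results], zone_id=zid)
        zone_rows.append(zsum)
        group_rows.append(
            group_metrics(zsum, group_id=group, animal_id=animal, zone_id=zone)
        )
        for res in results:
            for bc, tl in virtual_cell_points(res.summaries):
                scatter.append(
                    {"group": group, "animal": animal, "zone": zone,
                     "image": res.image_id, "branch_count": bc,
                     "total_branch_length_um": tl}
                )

    _summary_frame(zone_rows, "zone").to_csv(outdir / "zone_summaries.csv", index=False)
    pd.DataFrame([dataclasses.asdict(g) for g in group_rows]).to_csv(
        outdir / "group_metrics.csv", index=False
    )
    pd.DataFrame(
        scatter,
        columns=["group", "animal", "zone", "image", "branch_count",
                 "total_branch_length_um"],
    ).to_csv(outdir / "virtual_cell_scatter.csv", index=False)
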