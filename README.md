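# astroquant

Semi-automatic quantification of astrocyte number, branching and branch
length in DAB-stained GFAP brightfield photomicrographs (≈20×
magnification), as a native Python library and CLI.

The pipeline mirrors a well-established ImageJ + spreadsheet workflow,
re-implemented end to end:

1. **io** — image loading (TIFF/PNG/JPG), 8-bit grayscale conversion,
   µm/pixel calibration from a scale bar.
2. **preprocess** — FFT bandpass (difference-of-Gaussians transfer,
   mirror-padded to a power-of-two square), Gaussian unsharp mask,
   3×3 median despeckle.
3. **segment** — Kapur maximum-entropy thresholding (dark foreground for
   DAB), then the fixed cleanup chain despeckle → 3×3 binary closing →
   disk-median outlier removal (radius 2, threshold 50).
4. **skeleton** — topology-preserving thinning (Guo–Hall two-subiteration,
   plus a verified cleanup of residual 2×2 blocks) and skeleton-graph
   branch analysis: endpoints / slabs / junctions by 8-neighbor count,
   adjacent junction pixels merged into one node, branch length as the
   calibrated chain length (1 per orthogonal step, √2 per diagonal).
5. **quantify** — spreadsheet-equivalent trimming and aggregation:
   skeletons with a single branch are discarded (not astrocytes),
   per-skeleton COUNTIF/SUMIF summaries, per-image "Key" rows with a
   cell-normalized branch-length histogram, zone pooling (summed, never
   averaged) and group ratio metrics (branches/cell, cells/area,
   length/cell), plus the virtual-cell-size scatter table.
6. **synthgen** — synthetic star-shaped cells with exact ground truth
   (branch counts and lengths) for end-to-end validation.
7. **cli / pipeline** — deterministic batch driver with config snapshots.

## CLI

```bash
# µm/px from a scale bar (100 px line over a 50 µm bar)
astroquant calibrate --scale-bar-px 100 --scale-bar-um 50

# generate a synthetic test image + ground truth + manifest row
astroquant simulate --out scene.png --seed 1 --n-cells 10

# run the full pipeline over a manifest (CSV: image,animal,zone,group[,area_um2])
astroquant process --manifest manifest.csv --outdir out/ --um-per-px 0.5 \
    --save-intermediates

# re-bin existing branch tables without re-segmenting
astroquant summarize --branches out/img0_branches.csv --out rebinned.csv \
    --bin-edges-um 0,10,20,inf
```

`process` writes, per image, the branch table
(`image,skeleton_id,branch_length_um`) and per-cell summary
(`skeleton_id,branch_count,total_branch_length_um`), plus
`image_summaries.csv`, `zone_summaries.csv`, `group_metrics.csv`,
`virtual_cell_scatter.csv`, a `config_snapshot.yaml` that reproduces the
run, and a log. Failed images are logged and skipped (exit status 3
signals partial failure). The analysis path is fully deterministic; all
randomness lives in the generator.

All lengths are measured in pixels and scaled by µm/px (areas by
µm/px²); calibration never resamples images. Histogram bin edges default
to 0, 5, 10, 15, 20, 30, 50, ∞ µm and are fully configurable.

## Tests

```bash
python -m pytest -q tests/
```

The suite checks each stage against independent brute-force oracles
(exhaustive Kapur scan, direct DFT-matrix filtering, pixelwise medians,
scan-and-accumulate spreadsheet semantics) and includes
`tests/test_acceptance.py`, one test per acceptance criterion — including
end-to-end recovery of known cell counts, branch counts and branch
lengths from 40 synthetic 1024×1024 scenes.

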