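import numpy as np
import pytest
from hypothesis import given, strategies as st

from astroquant.quantify import (
    DEFAULT_BIN_EDGES_UM,
    filter_singletons,
    group_metrics,
    summarize_image,
    summarize_skeletons,
    summarize_zone,
    virtual_cell_points,
)
from astroquant.skeleton import BranchRecord
from helpers import spreadsheet_oracle


def recs(*pairs):
    return [BranchRecord(sid, ln) for sid, ln in pairs]


class TestFilterSingletons:
    def test_removes_single_occurrence_ids(self):
        records = recs((1, 1.0), (1, 2.0), (2, 3.0), (3, 1.0), (3, 2.0), (3, 3.0))
        out = filter_singletons(records)
        assert [r.skeleton_id for r in out] == [1, 1, 3, 3, 3]

    def test_all_unique_gives_empty(self):
        assert filter_singletons(recs((1, 1.0), (2, 2.0), (3, 3.0))) == []

    def test_empty_input(self):
        assert filter_singletons([]) == []

    @given(st.lists(st.integers(min_value=1, max_value=20), max_size=60))
    def test_idempotent(self, ids):
        records = [BranchRecord(i, float(i)) for i in ids]
        once = filter_singletons(records)
        assert filter_singletons(once) == once


class TestSummarizeSkeletons:
    def test_countif_sumif_example(self):
        records = recs((1, 2.0), (1, 3.0), (3, 1.5), (3, 2.5), (3, 4.0))
        out = summarize_skeletons(records)
        assert [(s.skeleton_id, s.branch_count, s.total_branch_length_um) for s in out] == [
            (1, 2, 5.0),
            (3, 3, 8.0),
        ]

    def test_identical_lengths_stay_independent(self):
        out = summarize_skeletons(recs((1, 2.0), (1, 2.0), (2, 2.0), (2, 2.0)))
        assert len(out) == 2
        assert all(s.total_branch_length_um == 4.0 for s in out)

    def test_singleton_reaching_summary_is_contract_error(self):
        with pytest.raises(ValueError):
            summarize_skeletons(recs((1, 2.0), (1, 3.0), (2, 9.0)))

    def test_matches_groupby_oracle_on_random_records(self, rng):
        ids = rng.integers(1, 120, size=1000)
        lengths = rng.uniform(0, 50, size=1000)
        records = [BranchRecord(int(i), float(ln)) for i, ln in zip(ids, lengths)]
        filtered = filter_singletons(records)
        out = summarize_skeletons(filtered)
        _, oracle = spreadsheet_oracle([(int(i), float(ln)) for i, ln in zip(ids, lengths)])
        assert {s.skeleton_id: (s.branch_count, s.total_branch_length_um) for s in out} == {
            sid: (c, pytest.approx(t, abs=1e-9)) for sid, (c, t) in oracle.items()
        }

    def test_conservation(self, rng):
        ids = rng.integers(1, 40, size=300)
        records = [BranchRecord(int(i), float(i)) for i in ids]
        filtered = filter_singletons(records)
        out = summarize_skeletons(filtered)
        assert sum(s.branch_count for s in out) == len(filtered)
        assert sum(s.total_branch_length_um for s in out) == pytest.approx(
            sum(r.branch_length_um for r in filtered), abs=1e-9 * max(1, len(filtered))
        )


class TestSummarizeImage:
    def _cells(self, *counts_and_lengths):
        from astroquant.quantify import SkeletonSummary

        return [
            SkeletonSummary(i + 1, c, ln)
            for i, (c, ln) in enumerate(counts_and_lengths)
        ]

    def test_binned_mode_example(self):
        cells = self._cells((2, 4.4), (1, 7.5))  # n_cells = 2
        out = summarize_image(cells, [2.1, 2.3, 7.5], [0, 5, 10], area_um2=100.0)
        assert out.binned_mode == pytest.approx([1.0, 0.5])

    def test_no_cells_flagged(self):
        out = summarize_image([], [], [0, 5, 10], area_um2=100.0)
        assert out.empty
        assert out.n_cells == 0
        assert out.binned_mode == pytest.approx([0.0, 0.0])
        assert out.modal_bin is None

    def test_single_catchall_bin_equals_branches_per_cell(self):
        cells = self._cells((2, 3.0), (3, 9.0))
        out = summarize_image(cells, [1, 2, 3, 4, 5], [0, np.inf], area_um2=1.0)
        assert out.binned_mode[0] == pytest.approx(5 / 2)

    def test_unsorted_edges_rejected(self):
        with pytest.raises(ValueError):
            summarize_image([], [], [0, 10, 5])

    def test_final_bin_right_closed(self):
        cells = self._cells((2, 30.0))
        out = summarize_image(cells, [10.0, 20.0], [0, 10, 20], area_um2=1.0)
        assert tuple(out.bin_counts) == (0, 2)  # 10 in [10,20), 20 in closed end

    def test_default_edges_cover_everything(self):
        cells = self._cells((2, 1e6))
        out = summarize_image(cells, [0.1, 999999.9], DEFAULT_BIN_EDGES_UM, area_um2=1.0)
        assert sum(out.bin_counts) == 2


class TestSummarizeZone:
    def _image(self, n_cells, lengths, edges=(0, 5, 10), area=100.0):
        from astroquant.quantify import SkeletonSummary

        cells = [SkeletonSummary(i + 1, 2, 1.0) for i in range(n_cells)]
        return summarize_image(cells, lengths, edges, area_um2=area)

    def test_single_image_identity(self):
        im = self._image(3, [1.0, 2.0, 7.0])
        zone = summarize_zone([im])
        assert zone.n_cells == im.n_cells
        assert zone.bin_counts == im.bin_counts
        assert zone.total_length_um == im.total_length_um

    def test_cell_counts_sum(self):
        zone = summarize_zone([self._image(3, [1.0]), self._image(7, [6.0])])
        assert zone.n_cells == 10

    def test_pooling_equals_pooled_recompute(self, rng):
        edges = (0.0, 5.0, 10.0, 20.0, np.inf)
        all_lengths = []
        images = []
        for _ in range(4):
            lengths = rng.uniform(0, 30, size=rng.integers(5, 30)).tolist()
            all_lengths += lengths
            images.append(self._image(rng.integers(1, 5), lengths, edges))
        zone = summarize_zone(images)
        pooled = self._image(zone.n_cells, all_lengths, edges)
        assert zone.bin_counts == pooled.bin_counts
        assert zone.binned_mode == pytest.approx(pooled.binned_mode)

    def test_mismatched_edges_rejected(self):
        with pytest.raises(ValueError):
            summarize_zone([self._image(1, [], (0, 5)), self._image(1, [], (0, 9))])

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            summarize_zone([])


class TestGroupMetrics:
    def _zone(self, n_cells, n_branches, total_len, area):
        from astroquant.quantify import ImageSummary

        return ImageSummary(
            image_id="z", n_cells=n_cells, n_branches=n_branches,
            total_length_um=total_len, bin_edges_um=(0.0, np.inf),
            bin_counts=(n_branches,), area_um2=area, empty=(n_cells == 0),
        )

    def test_cells_per_area(self):
        row = group_metrics(self._zone(50, 150, 1200.0, 250000.0))
        assert row.cells_per_area == pytest.approx(2e-4)

    def test_branches_per_cell(self):
        row = group_metrics(self._zone(50, 150, 1200.0, 250000.0))
        assert row.branches_per_cell == pytest.approx(3.0)

    def test_length_per_cell(self):
        row = group_metrics(self._zone(50, 150, 1200.0, 250000.0))
        assert row.length_per_cell_um == pytest.approx(24.0)

    def test_zero_cells_yields_nan_with_warning(self):
        with pytest.warns(UserWarning):
            row = group_metrics(self._zone(0, 0, 0.0, 100.0))
        assert np.isnan(row.branches_per_cell)
        assert np.isnan(row.cells_per_area)
        assert np.isnan(row.length_per_cell_um)

    def test_scale_consistency(self):
        one = group_metrics(self._zone(10, 30, 200.0, 1000.0))
        two = group_metrics(self._zone(20, 60, 400.0, 2000.0))
        assert two.branches_per_cell == pytest.approx(one.branches_per_cell)
        assert two.length_per_cell_um == pytest.approx(one.length_per_cell_um)
        assert two.cells_per_area == pytest.approx(one.cells_per_area)


class TestVirtualCellPoints:
    def test_example(self):
        out = summarize_skeletons(
            recs((1, 2.0), (1, 3.0), (3, 1.5), (3, 2.5), (3, 4.0))
        )
        assert virtual_cell_points(out) == [(2, 5.0), (3, 8.0)]

    def test_empty(self):
        assert virtual_cell_points([]) == []

    def test_bijection_with_cells(self, rng):
        ids = np.repeat(rng.integers(1, 30, size=20), 2)
        records = [BranchRecord(int(i), 1.0) for i in ids]
        summaries = summarize_skeletons(filter_singletons(records))
        assert len(virtual_cell_points(summaries)) == len(summaries)
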