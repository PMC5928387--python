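"""Per-cell NCR computation, transfection gating and aggregation."""

import numpy as np
import pytest

from factpipe.ncr_quant import (
    CellRecord,
    WellNCR,
    compute_all_cells,
    compute_cell_ncr,
    condition_ncr,
    estimate_background,
    gate_transfected,
    well_ncr,
)
from factpipe.segmentation import LabelMaps, segment_well


def disk_maps(ncr_value=2.0, cyto_level=100.0, size=64):
    """One synthetic cell with exact compartment intensities."""
    rr, cc = np.mgrid[:size, :size]
    d2 = (rr - size // 2) ** 2 + (cc - size // 2) ** 2
    cell = (d2 <= 20**2).astype(np.int32)
    nucleus = (d2 <= 10**2).astype(np.int32)
    reporter = np.zeros((size, size))
    reporter[(cell == 1) & (nucleus == 0)] = cyto_level
    reporter[nucleus == 1] = cyto_level * ncr_value
    return LabelMaps(cell, nucleus), reporter


def record(ncr, transfected=True, total=100.0):
    return CellRecord("w", 1, ncr * 10, 10.0, ncr, total, transfected=transfected)


class TestComputeCellNCR:
    def test_uniform_reporter_gives_unity(self):
        maps, reporter = disk_maps(ncr_value=1.0)
        cell = compute_cell_ncr(maps, reporter, 1)
        assert cell.ncr == pytest.approx(1.0)

    def test_direct_ratio(self):
        maps, reporter = disk_maps(ncr_value=2.0, cyto_level=100.0)
        cell = compute_cell_ncr(maps, reporter, 1)
        assert cell.nuclear_mean == pytest.approx(200.0)
        assert cell.cytoplasm_mean == pytest.approx(100.0)
        assert cell.ncr == pytest.approx(2.0)

    def test_dark_cytoplasm_excluded_not_infinite(self):
        maps, reporter = disk_maps(ncr_value=2.0, cyto_level=0.0)
        cell = compute_cell_ncr(maps, reporter, 1)
        assert cell.ncr is None
        assert cell.excluded_reason == "cytoplasm_below_epsilon"

    def test_missing_label_rejected(self):
        maps, reporter = disk_maps()
        with pytest.raises(ValueError, match="label 7"):
            compute_cell_ncr(maps, reporter, 7)

    def test_scale_invariance_of_ncr(self):
        maps, reporter = disk_maps(ncr_value=2.5)
        a = compute_cell_ncr(maps, reporter, 1)
        b = compute_cell_ncr(maps, reporter * 37.0, 1)
        assert a.ncr == pytest.approx(b.ncr)

    def test_simulated_cell_ncr_within_two_percent(self, clean_sparse_plate):
        """No noise/blur: measured NCR matches sampled truth to rasterization."""
        config, images, truth = clean_sparse_plate
        image = images[0]
        maps, _, reporter = segment_well(
            image.channels["nuclear_stain"], image.channels["reporter"], seed=1
        )
        cells = compute_all_cells(maps, reporter, well_id=image.well_id)
        from factpipe.segmentation import object_table

        centroids = object_table(maps)[["centroid_row", "centroid_col"]].to_numpy()
        checked = 0
        for cell_truth in truth:
            d = np.hypot(
                centroids[:, 0] - cell_truth.center[0],
                centroids[:, 1] - cell_truth.center[1],
            )
            idx = int(np.argmin(d))
            if d[idx] > 3.0:
                continue
            measured = cells[idx].ncr
            if measured is None:
                continue
            assert measured == pytest.approx(cell_truth.true_ncr, rel=0.05)
            checked += 1
        assert checked >= 40


class TestGate:
    def test_gated_fraction_matches_transfection_rate(self, small_plate):
        config, images, truth = small_plate
        image = images[0]
        maps, _, reporter = segment_well(
            image.channels["nuclear_stain"], image.channels["reporter"], seed=0
        )
        cells = compute_all_cells(maps, reporter, well_id=image.well_id)
        bg_mean, bg_sd = estimate_background(reporter, maps.cell_labels)
        passed = gate_transfected(cells, background_mean=bg_mean, background_sd=bg_sd)
        true_fraction = np.mean([c.transfected for c in truth if c.well_id == image.well_id])
        assert abs(len(passed) / len(cells) - true_fraction) <= 0.10

    def test_all_below_gate(self):
        cells = [record(1.0, total=5.0), record(2.0, total=4.0)]
        assert gate_transfected(cells, background_mean=10.0, background_sd=1.0) == []

    def test_zero_gate_passes_all(self):
        cells = [record(1.0, total=5.0), record(2.0, total=4.0)]
        assert len(gate_transfected(cells, background_mean=0.0, background_sd=0.0)) == 2


class TestWellAggregation:
    def test_odd_count_median(self):
        cells = [record(v) for v in (1.0, 2.0, 3.0)]
        assert well_ncr(cells, min_cells=1).median_ncr == 2.0

    def test_even_count_median_averages_central_pair(self):
        cells = [record(v) for v in (1.0, 2.0, 3.0, 10.0)]
        assert well_ncr(cells, min_cells=1).median_ncr == 2.5

    def test_median_over_transfected_subset_only(self):
        cells = [record(v) for v in (1.0, 2.0, 3.0)] + [
            record(50.0, transfected=False)
        ]
        assert well_ncr(cells, min_cells=1).median_ncr == 2.0

    def test_underpopulated_well_flagged_invalid(self):
        cells = [record(1.0)]
        well = well_ncr(cells, min_cells=50, well_id="B02")
        assert not well.valid
        assert well.median_ncr is None


class TestConditionAggregation:
    def _wells(self, medians, condition="C"):
        return [
            WellNCR(f"A{i:02d}", condition, m, 100) for i, m in enumerate(medians, 1)
        ]

    def test_constant_wells(self):
        result = condition_ncr(self._wells([2.0] * 6))
        assert result.mean_ncr == 2.0
        assert result.sd_ncr == 0.0

    def test_mean_of_well_medians(self):
        result = condition_ncr(self._wells([1, 2, 3, 4, 5, 6]))
        assert result.mean_ncr == pytest.approx(3.5)

    def test_two_wells_is_an_error(self):
        with pytest.raises(ValueError, match="valid wells"):
            condition_ncr(self._wells([1.0, 2.0]))

    def test_mixed_conditions_rejected(self):
        wells = self._wells([1.0] * 3) + self._wells([2.0] * 3, condition="D")
        with pytest.raises(ValueError, match="multiple conditions"):
            condition_ncr(wells)

    def test_order_invariance(self):
        wells = self._wells([1.0, 2.5, 3.0, 0.5, 2.0, 1.5])
        forward = condition_ncr(wells)
        backward = condition_ncr(wells[::-1])
        assert forward.mean_ncr == backward.mean_ncr
        assert sorted(forward.well_medians) == sorted(backward.well_medians)
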