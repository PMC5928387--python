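"""Synthetic plate generator: determinism, geometry and signal contracts."""

import numpy as np
import pytest

from factpipe.synthetic_imaging import (
    CHANNELS,
    ConditionSpec,
    ConfigError,
    GroundTruthCell,
    SimulationConfig,
    generate_plate,
    read_plate,
    render_cell,
    well_names,
    write_plate,
)


def tiny_config(**overrides):
    defaults = dict(
        conditions={"C": ConditionSpec(2.0)},
        image_size=(256, 256),
        cells_per_well=30,
        wells_per_condition=2,
        seed=1,
    )
    defaults.update(overrides)
    return SimulationConfig(**defaults)


class TestConfig:
    def test_nucleus_fraction_must_be_below_one(self):
        config = tiny_config(nucleus_radius_fraction=1.0)
        with pytest.raises(ConfigError, match="nucleus_radius_fraction"):
            config.validate()

    def test_well_names_follow_plate_layout(self):
        assert well_names(3) == ["A01", "A02", "A03"]
        assert well_names(13)[-1] == "B01"
        with pytest.raises(ConfigError):
            well_names(97)


class TestGeneratePlate:
    def test_zero_cells_gives_background_only(self):
        config = tiny_config(cells_per_well=0, noise_sd=0.0)
        images, truth = generate_plate(config)
        assert truth == []
        for image in images:
            for channel in CHANNELS:
                assert np.all(image.channels[channel] == config.background_level)

    def test_deterministic_given_seed(self):
        config = tiny_config()
        images_a, truth_a = generate_plate(config)
        images_b, truth_b = generate_plate(tiny_config())
        assert truth_a == truth_b
        for a, b in zip(images_a, images_b):
            for channel in CHANNELS:
                assert np.array_equal(a.channels[channel], b.channels[channel])

    def test_wells_per_condition(self):
        config = tiny_config(
            conditions={"A": ConditionSpec(1.0), "B": ConditionSpec(2.0)}
        )
        images, _ = generate_plate(config)
        assert len(images) == 4
        assert sorted({i.condition_id for i in images}) == ["A", "B"]

    def test_sampled_ncr_median_matches_configured(self):
        """Direct-sampling oracle: the configured log-normal median is recovered."""
        config = tiny_config(
            conditions={"C": ConditionSpec(2.0, ncr_sigma=0.1)},
            image_size=(1200, 1200),
            cells_per_well=500,
            wells_per_condition=1,
            transfection_fraction=1.0,
            noise_sd=0.0,
            seed=3,
        )
        _, truth = generate_plate(config)
        sample_median = np.median([c.true_ncr for c in truth])
        assert abs(sample_median - 2.0) / 2.0 < 0.05

    def test_configured_median_increase_raises_truth_median(self):
        medians = []
        for m in (1.0, 1.5, 2.0, 3.0):
            config = tiny_config(conditions={"C": ConditionSpec(m)}, seed=9)
            _, truth = generate_plate(config)
            medians.append(np.median([c.true_ncr for c in truth]))
        assert np.all(np.diff(medians) > 0)


class TestRenderCell:
    def _canvases(self, size=64):
        return {c: np.zeros((size, size)) for c in CHANNELS}

    def _cell(self, ncr, transfected=True):
        return GroundTruthCell("A01", (32.0, 32.0), 12.0, 6.0, ncr, transfected)

    def _masks(self, cell, shape):
        rr, cc = np.mgrid[: shape[0], : shape[1]]
        d2 = (rr - cell.center[0]) ** 2 + (cc - cell.center[1]) ** 2
        nucleus = d2 <= cell.nucleus_radius**2
        cytoplasm = (d2 <= cell.cell_radius**2) & ~nucleus
        return nucleus, cytoplasm

    @pytest.mark.parametrize("ncr", [1.0, 3.0])
    def test_compartment_means_encode_ncr(self, ncr):
        config = tiny_config(noise_sd=0.0, blur_sigma=0.0)
        canvases = self._canvases()
        cell = self._cell(ncr)
        render_cell(canvases, cell, config)
        nucleus, cytoplasm = self._masks(cell, canvases["reporter"].shape)
        measured = canvases["reporter"][nucleus].mean() / canvases["reporter"][cytoplasm].mean()
        assert measured == pytest.approx(ncr, rel=0.02)

    def test_untransfected_leaves_reporter_unchanged(self):
        config = tiny_config()
        canvases = self._canvases()
        render_cell(canvases, self._cell(2.0, transfected=False), config)
        assert np.all(canvases["reporter"] == 0)
        assert canvases["nuclear_stain"].max() > 0

    def test_overlapping_cells_sum_additively(self):
        config = tiny_config(noise_sd=0.0, blur_sigma=0.0)
        single = self._canvases()
        render_cell(single, self._cell(2.0), config)
        double = self._canvases()
        render_cell(double, self._cell(2.0), config)
        render_cell(double, self._cell(2.0), config)
        assert np.array_equal(double["reporter"], 2 * single["reporter"])


class TestGroundTruthRecovery:
    def test_noise_free_ncr_recovered_from_pixels(self, clean_sparse_plate):
        """With no noise/blur and non-touching cells, pixel means give true NCR."""
        config, images, truth = clean_sparse_plate
        image = images[0]
        reporter = image.channels["reporter"].astype(float) - config.background_level
        rr, cc = np.mgrid[: config.image_size[0], : config.image_size[1]]
        for cell in truth[:25]:
            d2 = (rr - cell.center[0]) ** 2 + (cc - cell.center[1]) ** 2
            nucleus = d2 <= (cell.nucleus_radius - 0.5) ** 2
            cytoplasm = (d2 <= (cell.cell_radius - 0.5) ** 2) & (
                d2 >= (cell.nucleus_radius + 0.5) ** 2
            )
            measured = reporter[nucleus].mean() / reporter[cytoplasm].mean()
            assert measured == pytest.approx(cell.true_ncr, rel=0.02)


class TestPlateIO:
    def test_write_read_round_trip(self, tmp_path):
        config = tiny_config()
        images, truth = generate_plate(config)
        write_plate(images, truth, tmp_path)
        loaded = read_plate(tmp_path)
        assert [i.well_id for i in loaded] == [i.well_id for i in images]
        for a, b in zip(images, loaded):
            for channel in CHANNELS:
                assert np.array_equal(a.channels[channel], b.channels[channel])
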