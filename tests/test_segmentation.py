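"""Enhancement, GMM foreground detection, watershed segmentation, refinement."""

import numpy as np
import pytest

from factpipe.segmentation import (
    LabelMaps,
    MorphologyRules,
    detect_foreground_gmm,
    enhance,
    refine,
    segment_cells,
    segment_well,
)
from factpipe.synthetic_imaging import (
    ConditionSpec,
    GroundTruthCell,
    SimulationConfig,
    generate_plate,
    render_cell,
)


def planted_disks(shape=(256, 256), n=12, radius=10, amp=900.0, bg=100.0, seed=0):
    """Non-touching bright disks on noisy background, with the true mask."""
    rng = np.random.default_rng(seed)
    image = rng.normal(bg, 5.0, shape)
    mask = np.zeros(shape, dtype=bool)
    rr, cc = np.mgrid[: shape[0], : shape[1]]
    placed = []
    while len(placed) < n:
        center = rng.uniform(radius + 2, shape[0] - radius - 2, 2)
        if all(np.hypot(*(center - p)) > 3 * radius for p in placed):
            placed.append(center)
            disk = (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius**2
            image[disk] += rng.normal(amp, 50.0, disk.sum())
            mask |= disk
    return image, mask


class TestEnhance:
    def test_constant_image_maps_to_zero(self):
        assert np.allclose(enhance(np.full((128, 128), 500.0)), 0.0)

    def test_disk_amplitude_preserved_after_subtraction(self):
        image = np.full((256, 256), 200.0)
        rr, cc = np.mgrid[:256, :256]
        disk = (rr - 128) ** 2 + (cc - 128) ** 2 <= 12**2
        image[disk] += 700.0
        out = enhance(image, smooth_sigma=0.0)
        assert out[disk].mean() == pytest.approx(700.0, rel=0.05)
        assert abs(out[~disk].mean()) < 5.0

    def test_output_never_negative(self):
        rng = np.random.default_rng(0)
        out = enhance(rng.normal(100, 20, (128, 128)))
        assert out.min() >= 0.0


class TestForegroundGMM:
    def test_planted_disks_recovered(self):
        image, mask = planted_disks()
        detected = detect_foreground_gmm([image], n_components=2, seed=0)
        assert detected[mask].mean() >= 0.95  # disk coverage
        assert detected[~mask].mean() <= 0.01  # background leakage
        fraction = detected.mean()
        planted = mask.mean()
        assert abs(fraction - planted) / planted < 0.10

    def test_constant_image_warns_and_returns_empty(self):
        with pytest.warns(UserWarning, match="degenerate"):
            mask = detect_foreground_gmm([np.full((64, 64), 7.0)], n_components=2)
        assert not mask.any()

    def test_deterministic_given_seed(self):
        image, _ = planted_disks(seed=4)
        a = detect_foreground_gmm([image], n_components=3, seed=9)
        b = detect_foreground_gmm([image], n_components=3, seed=9)
        assert np.array_equal(a, b)


class TestSegmentCells:
    def test_blank_images_give_zero_labels(self):
        blank = np.zeros((128, 128))
        maps = segment_cells(blank, blank, np.zeros((128, 128), dtype=bool))
        assert maps.n_objects == 0

    def test_two_touching_cells_split_by_seeds(self):
        """Overlapping disks with separated nuclei resolve into two cells."""
        config = SimulationConfig(noise_sd=0.0, blur_sigma=0.5)
        canvases = {c: np.zeros((128, 128)) for c in ("nuclear_stain", "reporter")}
        cells = [
            GroundTruthCell("w", (64.0, 50.0), 12.0, 6.0, 2.0, True),
            GroundTruthCell("w", (64.0, 68.0), 12.0, 6.0, 2.0, True),
        ]
        for cell in cells:
            render_cell(canvases, cell, config)
        mask = canvases["nuclear_stain"] > 10
        maps = segment_cells(
            canvases["nuclear_stain"], canvases["reporter"], mask, seed_min_distance=8
        )
        assert maps.n_objects == 2
        for cell, label in zip(cells, (1, 2)):
            nucleus = maps.nucleus_labels[int(cell.center[0]), int(cell.center[1])]
            enclosing = maps.cell_labels[int(cell.center[0]), int(cell.center[1])]
            assert nucleus == enclosing != 0

    def test_fifty_separated_cells_all_found(self, clean_sparse_plate):
        config, images, truth = clean_sparse_plate
        image = images[0]
        maps, _, _ = segment_well(
            image.channels["nuclear_stain"], image.channels["reporter"], seed=2
        )
        assert maps.n_objects == len(truth) == 50

    def test_nucleus_contained_in_cell(self, small_plate):
        _, images, _ = small_plate
        image = images[0]
        maps, _, _ = segment_well(
            image.channels["nuclear_stain"], image.channels["reporter"], seed=0
        )
        assert maps.n_objects > 0
        mismatch = (maps.nucleus_labels != 0) & (
            maps.nucleus_labels != maps.cell_labels
        )
        assert not mismatch.any()


class TestRefine:
    def _maps_with_speck(self):
        cell = np.zeros((64, 64), dtype=np.int32)
        nucleus = np.zeros_like(cell)
        rr, cc = np.mgrid[:64, :64]
        big = (rr - 20) ** 2 + (cc - 20) ** 2 <= 12**2
        cell[big] = 1
        nucleus[(rr - 20) ** 2 + (cc - 20) ** 2 <= 6**2] = 1
        speck = (rr - 50) ** 2 + (cc - 50) ** 2 <= 3**2
        cell[speck] = 2
        nucleus[(rr - 50) ** 2 + (cc - 50) ** 2 <= 2**2] = 2
        return LabelMaps(cell, nucleus)

    def test_sub_threshold_object_removed(self):
        refined = refine(self._maps_with_speck(), MorphologyRules(min_cell_area=150))
        assert refined.n_objects == 1

    def test_within_bounds_is_noop_up_to_relabelling(self):
        maps = self._maps_with_speck()
        rules = MorphologyRules(min_cell_area=5.0, min_nucleus_area=2.0)
        refined = refine(maps, rules)
        assert refined.n_objects == 2
        assert np.array_equal(refined.cell_labels > 0, maps.cell_labels > 0)

    def test_labels_consecutive_after_refine(self):
        refined = refine(self._maps_with_speck(), MorphologyRules(min_cell_area=150))
        labels = np.unique(refined.cell_labels)
        assert labels.tolist() == [0, 1]

    def test_debris_specks_removed_on_simulated_plate(self):
        config = SimulationConfig(
            conditions={"C": ConditionSpec(2.0)},
            image_size=(384, 384),
            cells_per_well=40,
            wells_per_condition=1,
            debris_per_well=15,
            seed=21,
        )
        images, truth = generate_plate(config)
        maps, _, _ = segment_well(
            images[0].channels["nuclear_stain"], images[0].channels["reporter"], seed=3
        )
        assert abs(maps.n_objects - len(truth)) <= 2

    def test_inverted_rule_bounds_rejected(self):
        with pytest.raises(ValueError, match="inverted"):
            MorphologyRules(min_cell_area=100, max_cell_area=50)


class TestEndToEndRecovery:
    def test_count_and_centroid_recovery(self, small_plate):
        """Detected count within 5% of planted; centroids match within a radius."""
        config, images, truth = small_plate
        total_planted = 0
        total_detected = 0
        matched = 0
        from factpipe.segmentation import object_table

        for image in images:
            maps, _, _ = segment_well(
                image.channels["nuclear_stain"], image.channels["reporter"], seed=0
            )
            gt = [c for c in truth if c.well_id == image.well_id]
            total_planted += len(gt)
            total_detected += maps.n_objects
            centroids = object_table(maps)[["centroid_row", "centroid_col"]].to_numpy()
            for cell in gt:
                d = np.hypot(
                    centroids[:, 0] - cell.center[0], centroids[:, 1] - cell.center[1]
                )
                if d.size and d.min() <= cell.cell_radius:
                    matched += 1
        assert abs(total_detected - total_planted) / total_planted <= 0.05
        assert matched / total_planted >= 0.95
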