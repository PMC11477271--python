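"""Soma/neurite splitting against generator ground truth."""

import numpy as np
import pytest

from nquant import (
    CellSpec,
    ImagingParams,
    generate_neuron_scene,
    measure_intensity,
    neurite_ratio_summary,
    segment_cells,
    split_soma_neurites,
)


def jaccard(a, b):
    return (a & b).sum() / (a | b).sum()


def three_cell_scene(noise_free=False, seed=21):
    specs = [
        CellSpec((60, 60), 10, neurites=[([(60, 70), (60, 130)], 3.0)]),
        CellSpec((160, 60), 12, neurites=[([(148, 60), (100, 60)], 3.0)]),
        CellSpec((160, 180), 11),
    ]
    params = ImagingParams(image_shape=(230, 230), seed=seed)
    if noise_free:
        params = params.noise_free()
    return generate_neuron_scene(specs, params)


class TestSegmentCells:
    def test_three_cells_recovered_with_high_overlap(self):
        scene = three_cell_scene()
        labels = segment_cells(scene.channels["actin"], min_cell_area=100)
        assert labels.max() == 3
        for truth_mask in scene.truth.cell_masks:
            best = max(jaccard(labels == k, truth_mask)
                       for k in range(1, labels.max() + 1))
            assert best >= 0.8

    def test_constant_image_has_no_foreground(self):
        with pytest.raises(ValueError, match="foreground"):
            segment_cells(np.full((64, 64), 7.0))

    def test_cell_below_min_area_filtered(self):
        scene = three_cell_scene(noise_free=True)
        labels = segment_cells(scene.channels["actin"], min_cell_area=10 ** 5,
                               smoothing_sigma=0)
        assert labels.max() == 0

    def test_noise_free_mask_recovery_is_exact(self):
        scene = three_cell_scene(noise_free=True)
        labels = segment_cells(scene.channels["actin"], min_cell_area=100,
                               smoothing_sigma=0)
        assert np.array_equal(labels > 0, scene.truth.cell_labels > 0)


class TestSplitSomaNeurites:
    def test_pure_disk_has_near_zero_ratio(self):
        from nquant.synthetic import disk_mask
        cell = disk_mask((80, 80), (40, 40), 15)
        m = split_soma_neurites(cell, soma_opening_radius=7)
        assert m.ratio_neurite_cell <= 0.05

    def test_ratio_close_to_truth_on_noisy_scene(self, one_cell_scene):
        truth = one_cell_scene.truth
        truth_ratio = truth.neurite_masks[0].sum() / truth.cell_masks[0].sum()
        labels = segment_cells(one_cell_scene.channels["actin"],
                               min_cell_area=100)
        m = split_soma_neurites(labels == 1, soma_opening_radius=7)
        assert abs(m.ratio_neurite_cell - truth_ratio) <= 0.05

    def test_thin_cell_has_no_soma(self):
        cell = np.zeros((60, 60), bool)
        cell[30, 5:55] = True
        cell[29, 5:55] = True
        with pytest.raises(ValueError, match="no soma"):
            split_soma_neurites(cell, soma_opening_radius=7)

    def test_partition_invariant_exact(self, one_cell_scene_noise_free):
        labels = segment_cells(one_cell_scene_noise_free.channels["actin"],
                               min_cell_area=100, smoothing_sigma=0)
        m = split_soma_neurites(labels == 1, soma_opening_radius=7)
        assert not (m.soma_mask & m.neurite_mask).any()
        assert np.array_equal(m.soma_mask | m.neurite_mask, m.cell_mask)
        assert 0 <= m.ratio_neurite_cell <= 1

    def test_matched_opening_radius_recovers_truth_exactly(
            self, one_cell_scene_noise_free):
        """A rasterized disk is exactly reconstructed by opening with its
        own radius, so the soma/neurite split is pixel-exact here."""
        scene = one_cell_scene_noise_free
        labels = segment_cells(scene.channels["actin"], min_cell_area=100,
                               smoothing_sigma=0)
        m = split_soma_neurites(labels == 1, soma_opening_radius=10)
        assert np.array_equal(m.soma_mask, scene.truth.soma_masks[0])
        assert np.array_equal(m.neurite_mask, scene.truth.neurite_masks[0])

    def test_longer_neurite_never_decreases_ratio(self):
        ratios = []
        for length in (20, 40, 60, 80):
            spec = CellSpec((100, 50), 10,
                            neurites=[([(100, 60), (100, 60 + length)], 3.0)])
            scene = generate_neuron_scene(
                [spec], ImagingParams((200, 200), seed=3).noise_free())
            labels = segment_cells(scene.channels["actin"], min_cell_area=50,
                                   smoothing_sigma=0)
            m = split_soma_neurites(labels == 1, soma_opening_radius=7)
            ratios.append(m.ratio_neurite_cell)
        assert all(b >= a for a, b in zip(ratios, ratios[1:]))

    def test_disconnected_mask_rejected(self):
        mask = np.zeros((50, 50), bool)
        mask[5:15, 5:15] = True
        mask[30:40, 30:40] = True
        with pytest.raises(ValueError, match="connected"):
            split_soma_neurites(mask)


class TestSummaryAndIntensity:
    def test_summary_single_cell_equals_its_ratio(self, one_cell_scene_noise_free):
        labels = segment_cells(one_cell_scene_noise_free.channels["actin"],
                               min_cell_area=100, smoothing_sigma=0)
        m = split_soma_neurites(labels == 1, soma_opening_radius=7)
        s = neurite_ratio_summary([m])
        assert s["n_cells"] == 1
        assert s["mean_ratio_neurite_cell"] == m.ratio_neurite_cell

    def test_summary_mean_of_two_cells(self):
        scene = three_cell_scene(noise_free=True)
        labels = segment_cells(scene.channels["actin"], min_cell_area=100,
                               smoothing_sigma=0)
        morphs = [split_soma_neurites(labels == k, 7, cell_id=k)
                  for k in (1, 2)]
        s = neurite_ratio_summary(morphs)
        expected = (morphs[0].ratio_neurite_cell + morphs[1].ratio_neurite_cell) / 2
        assert s["mean_ratio_neurite_cell"] == pytest.approx(expected)

    def test_summary_empty_list_raises(self):
        with pytest.raises(ValueError):
            neurite_ratio_summary([])

    def test_uniform_image_corrects_to_zero(self):
        img = np.full((40, 40), 9.0)
        mask = np.zeros((40, 40), bool)
        mask[10:20, 10:20] = True
        res = measure_intensity(img, mask, background_method="outside-mask-mean")
        assert res.corrected_mean == 0.0

    def test_empty_mask_raises(self):
        with pytest.raises(ValueError, match="mask"):
            measure_intensity(np.ones((10, 10)), np.zeros((10, 10), bool))

    def test_whole_image_mask_floored_at_zero(self):
        rng = np.random.default_rng(0)
        img = rng.normal(10, 1, (50, 50))
        res = measure_intensity(img, np.ones((50, 50), bool),
                                background_method="percentile")
        assert res.corrected_mean >= 0

    def test_integrated_intensity_matches_generator_amplitude(self):
        """Low-noise scene: background-corrected integrated intensity over
        the truth mask approximates signal amplitude x truth area."""
        spec = CellSpec((60, 60), 10, neurites=[([(60, 70), (60, 120)], 3.0)])
        params = ImagingParams((160, 160), seed=13, psf_sigma=0.0,
                               poisson_scale=50.0, read_noise_sigma=0.5)
        scene = generate_neuron_scene([spec], params)
        truth_mask = scene.truth.cell_masks[0]
        res = measure_intensity(scene.channels["actin"], truth_mask,
                                background_method="outside-mask-mean")
        expected = params.signal_level * truth_mask.sum()
        assert abs(res.corrected_integrated - expected) / expected < 0.05
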