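"""Colony detection, quantification and the three analysis modes."""

import numpy as np
import pytest
from scipy import ndimage

import phenoplate as pp
from phenoplate.exceptions import (
    DimensionMismatchError,
    EmptyMaskError,
    ImageModeError,
    NoBackgroundError,
)
from phenoplate.imaging import (
    REFLECTIVE_RGB,
    TRANSMISSION_GREY,
    PlateImage,
    SegmentationMask,
)
from phenoplate.synthetic import SimulationConfig, simulate_plate_image

from conftest import make_disk_image


class TestPlateImage:
    def test_rejects_tiny_and_out_of_range_images(self):
        with pytest.raises(ValueError):
            PlateImage(np.zeros((10, 10)), TRANSMISSION_GREY)
        with pytest.raises(ValueError):
            PlateImage(np.full((100, 100), 2.0), TRANSMISSION_GREY)

    def test_mode_must_match_dimensionality(self):
        with pytest.raises(ImageModeError):
            PlateImage(np.zeros((100, 100)), REFLECTIVE_RGB)
        with pytest.raises(ImageModeError):
            PlateImage(np.zeros((100, 100, 4)), REFLECTIVE_RGB)


class TestSegmentation:
    @pytest.mark.parametrize("k", [1, 7, 23, 48, 96])
    def test_count_matches_connected_component_oracle(self, k, grid96):
        """Detected position count equals an independent component count."""
        rng = np.random.default_rng(k)
        all_pos = [(r, c) for r in range(8) for c in range(12)]
        chosen = [all_pos[i] for i in rng.choice(96, size=k, replace=False)]
        image = make_disk_image(chosen)
        # independent oracle: simple global threshold + connected components
        _, n_oracle = ndimage.label(image.pixels < 0.5)
        assert n_oracle == k
        mask = pp.segment_plate(image, grid96)
        assert len(mask.position_map) == k

    def test_blank_image_raises(self, grid96):
        image = PlateImage(np.full((216, 312), 0.85), TRANSMISSION_GREY)
        with pytest.raises(EmptyMaskError):
            pp.segment_plate(image, grid96)

    def test_single_disk_maps_to_origin(self, grid96):
        image = make_disk_image([(0, 0)])
        mask = pp.segment_plate(image, grid96)
        assert list(mask.position_map.values()) == [(0, 0)]

    def test_scale_robustness(self, full_plate_image_96, grid96):
        """Half-scale segmentation yields areas within 10% of full scale."""
        (_, full), = pp.quantify_batch([full_plate_image_96], grid96, scale=1.0)
        (_, half), = pp.quantify_batch([full_plate_image_96], grid96, scale=0.5)
        a_full = np.array([r.area for r in full if r.found])
        a_half = np.array([r.area for r in half if r.found])
        assert len(a_full) == len(a_half) == 96
        assert abs(a_half.mean() / a_full.mean() - 1) <= 0.10


class TestQuantifyBatch:
    def test_disk_geometry(self, grid96, layout96_nogrid):
        """A radius-20 disk: area within 5% of pi r^2, circularity >= 0.9."""
        cfg = SimulationConfig(
            format=96, noise_cv=0, gradient_amplitude=0, seed=0,
            image_colony_radius=20.0, image_pitch=60, image_margin=40,
        )
        image = simulate_plate_image(cfg, layout96_nogrid, np.full((8, 12), 100.0), "grey")
        (_, records), = pp.quantify_batch([image], grid96)
        areas = np.array([r.area for r in records if r.found])
        assert np.all(np.abs(areas - np.pi * 400) / (np.pi * 400) <= 0.05)
        assert all(r.circularity >= 0.9 for r in records if r.found)

    def test_empty_position_not_found(self, grid96, layout96_nogrid):
        cfg = SimulationConfig(format=96, noise_cv=0, gradient_amplitude=0, seed=0)
        sizes = np.full((8, 12), 100.0)
        sizes[3, 5] = 0.0
        image = simulate_plate_image(cfg, layout96_nogrid, sizes, "grey")
        (_, records), = pp.quantify_batch([image], grid96)
        by_pos = {(r.row, r.col): r for r in records}
        assert not by_pos[(3, 5)].found and by_pos[(3, 5)].area == 0
        assert sum(r.found for r in records) == 95

    def test_area_accuracy_radius_8(self, full_plate_image_96, grid96):
        (_, records), = pp.quantify_batch([full_plate_image_96], grid96)
        areas = np.array([r.area for r in records if r.found])
        assert np.all(np.abs(areas - np.pi * 64) / (np.pi * 64) <= 0.05)

    def test_mixed_sizes_rejected(self, full_plate_image_96, grid96):
        other = PlateImage(np.full((100, 100), 0.5), TRANSMISSION_GREY)
        with pytest.raises(DimensionMismatchError):
            pp.quantify_batch([full_plate_image_96, other], grid96)

    def test_rgb_input_rejected(self, grid96):
        rgb = PlateImage(np.ones((100, 100, 3)) * 0.5, REFLECTIVE_RGB)
        with pytest.raises(ImageModeError):
            pp.quantify_batch([rgb], grid96)


def _colour_disk_image(colours, radius=15):
    """RGB image with one uniformly coloured disk per entry on white."""
    n = len(colours)
    img = np.ones((120, 80 * n + 40, 3))
    for i, col in enumerate(colours):
        cy, cx = 60, 60 + 80 * i
        yy, xx = np.mgrid[0:120, 0 : img.shape[1]]
        disk = np.hypot(yy - cy, xx - cx) < radius
        img[disk] = col
    return PlateImage(img, REFLECTIVE_RGB)


class TestQuantifyRedness:
    def test_chromaticity_of_uniform_disk(self):
        """(0.9, 0.3, 0.3) disk: redness = 0.9 / 1.5 = 0.6."""
        image = _colour_disk_image([(0.9, 0.3, 0.3)])
        records = pp.quantify_redness(image, pp.GridSpec(1, 1))
        (rec,) = [r for r in records if r.found]
        assert rec.redness == pytest.approx(0.6, abs=0.02)

    def test_grey_disk_scores_one_third(self):
        image = _colour_disk_image([(0.4, 0.4, 0.4)])
        records = pp.quantify_redness(image, pp.GridSpec(1, 1))
        (rec,) = [r for r in records if r.found]
        assert rec.redness == pytest.approx(1 / 3, abs=0.02)

    def test_red_disk_outscores_grey(self):
        image = _colour_disk_image([(0.8, 0.3, 0.3), (0.5, 0.5, 0.5)])
        records = pp.quantify_redness(image, pp.GridSpec(1, 2))
        by_col = {r.col: r for r in records if r.found}
        assert by_col[0].redness > by_col[1].redness

    def test_redness_in_unit_interval_and_greyscale_rejected(self, layout96_nogrid):
        cfg = SimulationConfig(format=96, seed=1)
        image = simulate_plate_image(cfg, layout96_nogrid, np.full((8, 12), 100.0), "rgb")
        records = pp.quantify_redness(image, pp.GridSpec(8, 12))
        assert all(0 <= r.redness <= 1 for r in records if r.found)
        grey = simulate_plate_image(cfg, layout96_nogrid, np.full((8, 12), 100.0), "grey")
        with pytest.raises(ImageModeError):
            pp.quantify_redness(grey, pp.GridSpec(8, 12))


def _growing_series(layout, radii, empty=()):
    cfg = SimulationConfig(
        format=96, noise_cv=0, gradient_amplitude=0, seed=0,
        image_colony_radius=20.0, image_pitch=60, image_margin=40,
    )
    series = []
    for i, radius in enumerate(radii):
        sizes = np.full((8, 12), 100.0 * (radius / 20.0) ** 2)
        for pos in empty:
            sizes[pos] = 0.0
        img = simulate_plate_image(cfg, layout, sizes, mode="grey")
        series.append(PlateImage(img.pixels, TRANSMISSION_GREY, timestamp=i * 3600.0))
    return series


class TestQuantifyTimecourse:
    def test_growing_disks_give_nondecreasing_series(self, grid96, layout96_nogrid):
        series = _growing_series(layout96_nogrid, np.linspace(2, 20, 8))
        table = pp.quantify_timecourse(series, grid96)
        assert table.data.shape == (8, 96)
        assert (np.diff(table.data.to_numpy(), axis=0) >= -1e-9).all()

    def test_always_empty_position_has_no_column(self, grid96, layout96_nogrid):
        series = _growing_series(layout96_nogrid, np.linspace(2, 20, 5), empty=[(0, 0)])
        table = pp.quantify_timecourse(series, grid96)
        assert "0-0" not in table.data.columns
        assert table.data.shape[1] == 95

    def test_uniform_background_offset_cancels(self, grid96, layout96_nogrid):
        series = _growing_series(layout96_nogrid, np.linspace(2, 20, 6))
        reference = pp.quantify_timecourse(series, grid96)
        raised = PlateImage(
            np.clip(series[3].pixels - 0.1, 0, 1), TRANSMISSION_GREY,
            timestamp=series[3].timestamp,
        )
        series[3] = raised
        shifted = pp.quantify_timecourse(series, grid96)
        rel = np.abs(shifted.data.iloc[3] - reference.data.iloc[3]) / reference.data.iloc[3]
        assert rel.max() <= 0.01

    def test_blank_final_image_raises(self, grid96, layout96_nogrid):
        series = _growing_series(layout96_nogrid, [5.0, 10.0])
        blank = PlateImage(
            np.full_like(series[-1].pixels, 0.85), TRANSMISSION_GREY, timestamp=7e4
        )
        with pytest.raises(EmptyMaskError):
            pp.quantify_timecourse([series[0], blank], grid96)

    def test_dimension_mismatch_raises(self, grid96, layout96_nogrid):
        series = _growing_series(layout96_nogrid, [5.0, 10.0])
        small = PlateImage(np.full((100, 100), 0.2), TRANSMISSION_GREY, timestamp=8e4)
        with pytest.raises(DimensionMismatchError):
            pp.quantify_timecourse(series + [small], grid96)


class TestEstimateBackground:
    def test_median_of_background(self, grid96, full_plate_image_96):
        mask = pp.segment_plate(full_plate_image_96, grid96)
        assert pp.estimate_background(full_plate_image_96, mask) == pytest.approx(0.85, abs=1e-6)

    def test_noisy_background(self, grid96):
        rng = np.random.default_rng(0)
        pixels = np.clip(rng.normal(0.2, 0.01, (216, 312)), 0, 1)
        image = PlateImage(pixels, TRANSMISSION_GREY)
        mask = SegmentationMask(np.zeros((216, 312), dtype=int), {})
        assert pp.estimate_background(image, mask) == pytest.approx(0.2, abs=0.005)

    def test_all_colony_mask_raises(self, full_plate_image_96):
        labels = np.ones(full_plate_image_96.pixels.shape, dtype=int)
        mask = SegmentationMask(labels, {1: (0, 0)})
        with pytest.raises(NoBackgroundError):
            pp.estimate_background(full_plate_image_96, mask)


def test_qc_overlay_written(tmp_path, grid96, full_plate_image_96):
    pp.quantify_batch([full_plate_image_96], grid96, qc_dir=tmp_path)
    assert list(tmp_path.glob("*_qc.png"))
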