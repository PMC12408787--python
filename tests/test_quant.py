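"""Quantification core: preprocessing, thresholding, segmentation."""

import numpy as np
import pytest
from scipy import ndimage as ndi
from skimage.morphology import disk

from conftest import flood_fill_count, small_frame
from hcbfquant.frames import Channel, ImageFrame
from hcbfquant.quant import (
    CELL_COUNT_HCBF,
    MYO_QUANT_HCBF,
    NUCLEI_HOECHST,
    AnalysisParams,
    background_floor,
    cell_count,
    cell_coverage,
    myo_quant,
    nuclei_count,
    preprocess,
    rolling_ball,
    segment,
    smooth,
)
from hcbfquant.simulate import (
    AcquisitionModel,
    CellSpot,
    Myotube,
    SceneTruth,
    random_scene,
    render_frame,
)


class TestRollingBall:
    def test_constant_image_subtracts_to_zero(self):
        img = np.full((40, 40), 500.0)
        bg, sub = rolling_ball(img, 10.0, um_per_px=1.0)
        np.testing.assert_allclose(sub, 0.0)
        np.testing.assert_allclose(bg, 500.0)

    def test_spike_preserved_plateau_removed(self):
        # oracle: grayscale opening with a flat disk removes a narrow
        # spike from the background estimate entirely
        img = np.full((32, 32), 200.0)
        img[14:17, 14:17] += 300.0
        bg, sub = rolling_ball(img, 8.0, um_per_px=1.0)
        opened = ndi.grey_opening(img, footprint=disk(8))
        assert sub[15, 15] == pytest.approx(300.0, rel=0.05)
        assert abs(bg - opened).max() <= 0.05 * 300.0
        assert sub[2, 2] == pytest.approx(0.0, abs=1e-9)

    def test_background_bounded_by_input(self):
        rng = np.random.default_rng(0)
        img = rng.uniform(100, 1000, (48, 48))
        bg, sub = rolling_ball(img, 5.0, um_per_px=1.0)
        assert (bg <= img + 1e-9).all()
        assert (sub >= -1e-9).all()

    def test_subpixel_radius_rejected(self):
        with pytest.raises(ValueError, match="resolution|radius"):
            rolling_ball(np.zeros((16, 16)), 0.5, um_per_px=1.0)


class TestSmooth:
    def test_setting_zero_is_identity(self):
        img = np.arange(64.0).reshape(8, 8)
        np.testing.assert_array_equal(smooth(img, 0), img)

    def test_impulse_response_is_box_filter(self):
        img = np.zeros((64, 64))
        img[32, 32] = 441.0
        out = smooth(img, 10)
        assert out.max() == pytest.approx(441.0 / 21**2)

    def test_global_mean_preserved(self):
        rng = np.random.default_rng(1)
        img = rng.uniform(0, 1000, (128, 128))
        assert smooth(img, 10).mean() == pytest.approx(img.mean(), abs=0.5)


class TestBackgroundFloor:
    def test_uniform_image_any_percent(self):
        img = np.full((20, 20), 77.0)
        for pct in (10, 60, 100):
            assert background_floor(img, pct) == 77.0

    def test_bimodal_half_lowest(self):
        img = np.concatenate([np.full(50, 100.0), np.full(50, 300.0)])
        assert background_floor(img.reshape(10, 10), 50) == 100.0

    def test_percent_100_is_global_mean(self):
        rng = np.random.default_rng(2)
        img = rng.uniform(0, 100, (30, 30))
        assert background_floor(img, 100) == pytest.approx(img.mean())

    def test_empty_roi_raises(self):
        with pytest.raises(ValueError, match="ROI"):
            background_floor(np.ones((8, 8)), 50, mask=np.zeros((8, 8), dtype=bool))


class TestSegment:
    def test_blank_frame_detects_nothing(self, clean_acq, wide_open_params):
        _, frame = small_frame([], acq=clean_acq)
        det = segment(frame, wide_open_params)
        assert det.count == 0 and det.total_area_um2 == 0.0

    def test_single_spot_in_band_counted(self, clean_acq):
        params = AnalysisParams(3000, 10, 80, True, smoothing=0, roi=None)
        _, frame = small_frame([(0.0, 0.0, 30.0)], acq=clean_acq)
        assert segment(frame, params).count == 1

    def test_spot_below_size_floor_rejected(self, clean_acq):
        params = AnalysisParams(3000, 10, 80, True, smoothing=0, roi=None)
        _, frame = small_frame([(0.0, 0.0, 5.0)], acq=clean_acq)
        assert segment(frame, params).count == 0

    def test_split_touching_separates_pair(self, clean_acq):
        cells = [(-10.0, 0.0, 18.0), (10.0, 0.0, 18.0)]
        _, frame = small_frame(cells, acq=clean_acq)
        on = AnalysisParams(3000, 10, 80, True, smoothing=0, roi=None)
        off = AnalysisParams(3000, 10, 80, False, smoothing=0, roi=None)
        assert segment(frame, on).count == 2
        assert segment(frame, off).count == 1

    @pytest.mark.parametrize("layout", ["separated", "corners", "dense"])
    def test_count_matches_flood_fill_oracle(self, clean_acq, wide_open_params, layout):
        coords = {
            "separated": [(-20.0, -15.0, 10.0), (18.0, 12.0, 12.0)],
            "corners": [(-22.0, -22.0, 9.0), (22.0, -22.0, 9.0), (0.0, 22.0, 9.0)],
            "dense": [(-8.0, 0.0, 12.0), (8.0, 0.0, 12.0), (0.0, 14.0, 12.0)],
        }[layout]
        _, frame = small_frame(coords, acq=clean_acq)
        pre = preprocess(frame, wide_open_params)
        mask = pre > wide_open_params.signal_threshold
        assert segment(frame, wide_open_params).count == flood_fill_count(mask)

    def test_widening_size_band_never_decreases_count(self, default_acq, roi384):
        truth = random_scene(
            60, np.random.default_rng(3), min_separation_um=40.0
        )
        frame = render_frame(truth, default_acq, rng=np.random.default_rng(4))
        narrow = CELL_COUNT_HCBF.with_roi(roi384)
        import dataclasses

        wide = dataclasses.replace(narrow, size_min_um=5.0, size_max_um=200.0)
        assert segment(frame, wide).count >= segment(frame, narrow).count

    def test_raising_threshold_never_increases_foreground(self, default_acq, roi384):
        truth = random_scene(40, np.random.default_rng(5), min_separation_um=40.0)
        frame = render_frame(truth, default_acq, rng=np.random.default_rng(6))
        import dataclasses

        lo = CELL_COUNT_HCBF.with_roi(roi384)
        hi = dataclasses.replace(lo, signal_threshold=6000.0)
        assert cell_coverage(frame, hi) <= cell_coverage(frame, lo)

    def test_translation_equivariance(self, roi384):
        acq = AcquisitionModel(shot_noise=False, read_noise_sd=0.0)
        truth = random_scene(
            30, np.random.default_rng(7), placement_diameter_um=2000.0,
            min_separation_um=80.0,
        )
        params = CELL_COUNT_HCBF.with_roi(roi384)
        n0 = cell_count(render_frame(truth, acq), params)
        shifted = truth.shifted(5 * acq.um_per_px, -3 * acq.um_per_px)
        n1 = cell_count(render_frame(shifted, acq), params)
        assert n0 == n1 == 30

    def test_pipeline_is_idempotent(self, default_acq, roi384):
        truth = random_scene(25, np.random.default_rng(8), min_separation_um=60.0)
        frame = render_frame(truth, default_acq, rng=np.random.default_rng(9))
        params = CELL_COUNT_HCBF.with_roi(roi384)
        a = segment(frame, params)
        b = segment(frame, params)
        np.testing.assert_array_equal(a.labels, b.labels)
        assert a.table.equals(b.table) and a.flags == b.flags

    def test_confluent_frame_flagged_not_raised(self):
        # wall-to-wall high-contrast texture: after background
        # subtraction and smoothing, essentially every pixel is
        # foreground -- the fully confluent failure mode
        yy, xx = np.mgrid[0:256, 0:256]
        checker = ((yy + xx) % 2).astype(np.uint16)
        frame = ImageFrame(
            pixels=8000 + 10000 * checker,
            um_per_px=1.6,
            channel=Channel.CELL_DEFOCUS,
        )
        params = AnalysisParams(
            3000, 10, 80, False, rolling_ball_um=20.0, smoothing=10, roi=None
        )
        det = segment(frame, params)
        assert "confluent/unreliable" in det.flags
        assert det.count == 0  # one wall-to-wall blob fails the size band


class TestCountsAndAreas:
    def test_fifty_disjoint_cells_counted_exactly(self, default_acq, roi384):
        truth = random_scene(
            50,
            np.random.default_rng(1),
            placement_diameter_um=2300.0,
            min_separation_um=90.0,
        )
        frame = render_frame(truth, default_acq, rng=np.random.default_rng(2))
        assert cell_count(frame, CELL_COUNT_HCBF.with_roi(roi384)) == 50

    def test_myo_ridge_area_matches_rasterized_truth(self, roi384):
        acq = AcquisitionModel(channel=Channel.MYO_DEFOCUS)
        tube = Myotube(np.array([[-400.0, 0.0], [400.0, 50.0]]), width_um=25.0)
        truth = SceneTruth(myotubes=[tube])
        frame = render_frame(truth, acq, rng=np.random.default_rng(3))
        measured = myo_quant(frame, MYO_QUANT_HCBF.with_roi(roi384))
        assert measured == pytest.approx(truth.true_myotube_area_um2, rel=0.15)

    def test_isolated_cells_contribute_no_myo_area(self, roi384):
        acq = AcquisitionModel(channel=Channel.MYO_DEFOCUS)
        truth = random_scene(
            40, np.random.default_rng(4), placement_diameter_um=2300.0,
            min_separation_um=90.0,
        )
        frame = render_frame(truth, acq, rng=np.random.default_rng(5))
        assert myo_quant(frame, MYO_QUANT_HCBF.with_roi(roi384)) == 0.0

    def test_coverage_tracks_truth_footprints(self, default_acq, roi384):
        truth = random_scene(
            50,
            np.random.default_rng(6),
            placement_diameter_um=2300.0,
            min_separation_um=90.0,
        )
        frame = render_frame(truth, default_acq, rng=np.random.default_rng(7))
        cov = cell_coverage(frame, CELL_COUNT_HCBF.with_roi(roi384))
        assert cov == pytest.approx(truth.analytic_cell_coverage_um2(), rel=0.15)

    def test_blank_coverage_is_zero(self, clean_acq, wide_open_params):
        _, frame = small_frame([], acq=clean_acq)
        assert cell_coverage(frame, wide_open_params) == 0.0

    def test_nuclei_counted_exactly_and_reproducibly(self, roi384):
        truth = random_scene(
            100,
            np.random.default_rng(8),
            placement_diameter_um=2300.0,
            min_separation_um=60.0,
        )
        acq = AcquisitionModel(channel=Channel.NUCLEI_FLUOR)
        frame = render_frame(truth, acq, rng=np.random.default_rng(9))
        params = NUCLEI_HOECHST.with_roi(roi384)
        n1 = nuclei_count(frame, params)
        n2 = nuclei_count(frame, params)
        assert n1 == n2 == 100
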