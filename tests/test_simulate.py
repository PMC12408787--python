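"""Synthetic imager: rendering contract, determinism, growth model."""

import numpy as np
import pytest

from hcbfquant.frames import Channel
from hcbfquant.kinetics import KineticSeries, fit_logistic
from hcbfquant.plate import P384
from hcbfquant.simulate import (
    AcquisitionModel,
    CellSpot,
    GrowthParams,
    SceneTruth,
    mean_cell_footprint_um2,
    random_scene,
    render_frame,
    seed_clonal_plate,
    simulate_timecourse,
    two_wave_params,
)


class TestRenderFrame:
    def test_empty_truth_without_noise_is_flat_background(self):
        acq = AcquisitionModel(
            shot_noise=False, read_noise_sd=0.0, vignette_strength=0.0,
            meniscus_ring=(0.9, 0.0),
        )
        frame = render_frame(SceneTruth(well_diameter_um=500.0), acq, image_px=128)
        assert np.unique(frame.pixels).tolist() == [8000]

    def test_single_center_cell_is_global_maximum(self):
        acq = AcquisitionModel(
            um_per_px=1.0, shot_noise=False, read_noise_sd=0.0,
            vignette_strength=0.0, meniscus_ring=(0.9, 0.0),
        )
        # (0.5, 0.5) µm puts the cell exactly on the center of pixel (64, 64)
        truth = SceneTruth(cells=[CellSpot(0.5, 0.5, 24.0)], well_diameter_um=128.0)
        frame = render_frame(truth, acq, image_px=128)
        iy, ix = np.unravel_index(np.argmax(frame.pixels), frame.shape)
        assert (iy, ix) == (64, 64)

    def test_identical_seed_gives_bit_identical_frames(self):
        truth = random_scene(20, np.random.default_rng(0), min_separation_um=50.0)
        acq = AcquisitionModel()
        f1 = render_frame(truth, acq, rng=np.random.default_rng(7))
        f2 = render_frame(truth, acq, rng=np.random.default_rng(7))
        np.testing.assert_array_equal(f1.pixels, f2.pixels)

    def test_background_pixels_within_four_sd(self):
        acq = AcquisitionModel(vignette_strength=0.0, meniscus_ring=(0.9, 0.0))
        frame = render_frame(
            SceneTruth(well_diameter_um=2000.0), acq, image_px=512,
            rng=np.random.default_rng(1),
        )
        sd = np.sqrt(acq.background_level + acq.read_noise_sd**2)
        frac = np.mean(
            np.abs(frame.pixels.astype(float) - acq.background_level) <= 4 * sd
        )
        assert frac >= 0.99

    def test_intensities_clipped_to_16bit(self):
        acq = AcquisitionModel(background_level=60000.0, meniscus_ring=(0.9, 20000.0))
        frame = render_frame(
            SceneTruth(well_diameter_um=1000.0), acq, image_px=320,
            rng=np.random.default_rng(2),
        )
        assert frame.pixels.max() <= 65535 and frame.pixels.min() >= 0

    def test_defocus_metadata_follows_format_and_channel(self):
        acq = AcquisitionModel().for_channel(Channel.MYO_DEFOCUS, P384)
        assert acq.defocus_z_um == 1580.0


class TestClonalSeeding:
    def test_lambda_zero_leaves_all_wells_empty(self):
        counts = seed_clonal_plate(0.0, rng_seed=0)
        assert (counts == 0).all() and len(counts) == 240

    def test_same_seed_is_identical(self):
        a = seed_clonal_plate(0.85, rng_seed=42)
        b = seed_clonal_plate(0.85, rng_seed=42)
        assert (a == b).all()

    def test_empty_fraction_approaches_poisson_zero_class(self):
        wells = [f"W{i}" for i in range(20000)]
        counts = seed_clonal_plate(0.85, rng_seed=3, wells=wells)
        assert (counts == 0).mean() == pytest.approx(np.exp(-0.85), abs=0.01)

    def test_negative_lambda_rejected(self):
        with pytest.raises(ValueError):
            seed_clonal_plate(-0.1)


class TestTimecourse:
    def test_fusion_off_follows_closed_form_logistic(self):
        gp = GrowthParams(
            n0=500, r=0.06, K=20000, lag_h=12, fusion_rate=0.0,
            duration_h=200, rng_seed=3,
        )
        pts = simulate_timecourse(gp)
        t = np.array([p.t_h for p in pts])
        n = np.array([p.n_cells for p in pts])
        tt = np.maximum(t - gp.lag_h, 0.0)
        expected = gp.K * gp.n0 * np.exp(gp.r * tt) / (
            gp.K + gp.n0 * (np.exp(gp.r * tt) - 1.0)
        )
        np.testing.assert_allclose(n, expected, rtol=1e-9)
        assert all(p.myo_area_um2 == 0.0 for p in pts)

    def test_no_detachment_keeps_area_non_decreasing(self):
        gp = GrowthParams(detachment_hazard=0.0, rng_seed=4, duration_h=300)
        a = np.array([p.myo_area_um2 for p in simulate_timecourse(gp)])
        assert np.all(np.diff(a) >= -1e-9)

    def test_fusion_conserves_area_in_cell_equivalents(self):
        gp = GrowthParams(detachment_hazard=0.0, rng_seed=7, duration_h=200)
        last = simulate_timecourse(gp)[-1]
        created = last.cum_fused_cells * mean_cell_footprint_um2()
        assert last.myo_area_um2 == pytest.approx(created, rel=0.10)

    def test_logistic_parameters_recovered_at_snr_20(self):
        gp = GrowthParams(
            n0=500, r=0.055, K=15000, lag_h=16, fusion_rate=0.0,
            duration_h=220, rng_seed=9,
        )
        pts = simulate_timecourse(gp)
        t = np.array([p.t_h for p in pts])
        v = np.array([p.n_cells for p in pts])
        # SNR 20 per measurement: counting error scales with the count
        rel = np.random.default_rng(42).normal(0.0, 1.0 / 20.0, size=v.shape)
        noisy = np.clip(v * (1.0 + rel), 0.0, None)
        fit = fit_logistic(
            KineticSeries("w", "count", t, noisy), relative_sigma=1.0 / 20.0
        )
        assert fit["r"] == pytest.approx(gp.r, rel=0.05)
        assert fit["K"] == pytest.approx(gp.K, rel=0.05)

    def test_reformation_scenario_has_two_area_maxima(self):
        pts = simulate_timecourse(two_wave_params(rng_seed=0))
        a = np.array([p.myo_area_um2 for p in pts])
        events = [p.t_h for p in pts if p.detachment_event]
        assert len(events) == 1
        # local maxima of the raw trace (interior or terminal)
        peaks = 0
        for i in range(1, len(a) - 1):
            if a[i] > a[i - 1] and a[i] >= a[i + 1]:
                peaks += 1
        if a[-1] > a[-2]:
            peaks += 1
        assert peaks >= 2

    def test_determinism_of_truth_series(self):
        gp = GrowthParams(rng_seed=11, duration_h=120)
        a = [p.n_cells for p in simulate_timecourse(gp)]
        b = [p.n_cells for p in simulate_timecourse(gp)]
        assert a == b

    def test_short_duration_yields_single_timepoint(self, caplog):
        gp = GrowthParams(duration_h=1.0, interval_h=4.0)
        pts = simulate_timecourse(gp)
        assert len(pts) == 1

    def test_rendered_channels_share_one_truth(self):
        gp = GrowthParams(
            n0=30, K=200, r=0.05, duration_h=8, rng_seed=5, fusion_rate=0.0
        )
        acq = AcquisitionModel(um_per_px=12.0)
        pts = simulate_timecourse(
            gp, acq, fmt=P384,
            render_channels=(Channel.CELL_DEFOCUS, Channel.MYO_DEFOCUS),
        )
        for p in pts:
            assert set(p.frames) == {Channel.CELL_DEFOCUS, Channel.MYO_DEFOCUS}
            assert p.truth.true_cell_count == len(p.truth.cells)


class TestGrowthParamsValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"n0": 0.0},
            {"n0": 50000.0},
            {"r": -0.1},
            {"diff_onset_density_fraction": 1.5},
            {"interval_h": 0.0},
        ],
    )
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(ValueError):
            GrowthParams(**kwargs)
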