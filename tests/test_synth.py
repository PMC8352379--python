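import numpy as np
import pytest

from pttherm.kinetics import first_order
from pttherm.roi import locate_roi, roi_trace
from pttherm.synth import (
    GNR,
    SALINE,
    CameraModel,
    SceneSpec,
    SimGroupParams,
    animal_seed,
    default_paper_params,
    sample_animal_params,
    simulate_design,
    simulate_stack,
    simulate_trace,
    tinf_from_tmax,
)


class TestDefaultParams:
    def test_full_design_eight_groups_of_four(self, paper_groups):
        assert len(paper_groups) == 8
        assert all(g.n_animals == 4 for g in paper_groups)
        assert {(g.wavelength, g.injection) for g in paper_groups} == {
            (wl, inj) for wl in (808, 940, 975, 1064) for inj in (GNR, SALINE)
        }

    def test_published_time_constants(self, paper_groups):
        by = {(g.wavelength, g.injection): g for g in paper_groups}
        assert by[(808, SALINE)].tau_mean == 67.8
        assert by[(808, SALINE)].tau_sd == 1.8
        assert by[(940, GNR)].tau_mean == 35.4
        assert by[(975, SALINE)].tau_mean == 38.3
        assert by[(1064, SALINE)].tau_mean == 66.9

    def test_derived_time_constants_from_printed_reductions(self, paper_groups):
        by = {(g.wavelength, g.injection): g for g in paper_groups}
        assert by[(808, GNR)].tau_mean == pytest.approx(67.8 - 33)
        assert by[(1064, GNR)].tau_mean == pytest.approx(66.9 - 33)
        assert by[(975, GNR)].tau_mean == pytest.approx(38.3 - 7)

    def test_provenance_tags_carried(self, paper_groups):
        by = {(g.wavelength, g.injection): g for g in paper_groups}
        assert by[(808, SALINE)].metadata["provenance"]["tau"] == "paper"
        assert by[(808, GNR)].metadata["provenance"]["tau"] == "derived"

    def test_steady_state_inversion_reproduces_printed_tmax(self, paper_groups):
        # the 90-s endpoint of the mean curve must hit the printed group Tmax
        for g in paper_groups:
            tmax = g.metadata["tmax_printed"]
            end = first_order(np.array([90.0]), g.t0_mean, g.tinf_mean, g.tau_mean)[0]
            assert end == pytest.approx(tmax, abs=1e-9)

    def test_tinf_from_tmax_closed_form(self):
        tinf = tinf_from_tmax(68.0, 29.0, 34.8)
        assert first_order(np.array([90.0]), 29.0, tinf, 34.8)[0] == pytest.approx(68.0)

    def test_invariant_validation(self):
        with pytest.raises(ValueError, match="tinf_mean"):
            SimGroupParams(808, GNR, t0_mean=30, t0_sd=1, tinf_mean=25, tinf_sd=1,
                           tau_mean=40, tau_sd=2)
        with pytest.raises(ValueError, match="tau_mean"):
            SimGroupParams(808, GNR, t0_mean=30, t0_sd=1, tinf_mean=70, tinf_sd=1,
                           tau_mean=-1, tau_sd=2)


class TestSimulateTrace:
    def test_noiseless_closed_form_at_tau(self, quiet_camera):
        g = SimGroupParams(808, GNR, t0_mean=30, t0_sd=0, tinf_mean=70, tinf_sd=0,
                           tau_mean=40, tau_sd=0)
        tr = simulate_trace(g, quiet_camera, seed=0)
        k = np.argmin(np.abs(tr.times - 40.0))
        assert tr.temp_mean[k] == pytest.approx(70 - 40 * np.exp(-1), abs=1e-9)  # 55.28 °C
        assert tr.temp_mean[0] == pytest.approx(30.0)

    def test_sampling_grid(self, quiet_camera):
        tr = simulate_trace(default_paper_params()[0], quiet_camera, exposure_s=90, seed=1)
        assert len(tr) == int(90 * 6) + 1
        assert tr.times[1] - tr.times[0] == pytest.approx(1 / 6)

    def test_same_seed_identical_traces(self, paper_groups):
        a = simulate_trace(paper_groups[2], seed=77)
        b = simulate_trace(paper_groups[2], seed=77)
        np.testing.assert_array_equal(a.temp_mean, b.temp_mean)
        assert a.meta["truth"] == b.meta["truth"]

    def test_noiseless_trace_strictly_increasing_and_bounded(self, quiet_camera, paper_groups):
        tr = simulate_trace(paper_groups[0], quiet_camera, seed=4)
        assert np.all(np.diff(tr.temp_mean) > 0)
        assert np.all(tr.temp_mean < tr.meta["truth"]["tinf"])

    def test_roi_pixel_equivalent_attenuates_noise(self, paper_groups):
        tr = simulate_trace(paper_groups[0], seed=5, roi_pixel_equivalent=49)
        assert tr.meta["noise_sd_mean_channel"] == pytest.approx(0.7 / 7)

    def test_nonphysical_group_exhausts_resampling(self):
        g = SimGroupParams(808, GNR, t0_mean=30, t0_sd=0, tinf_mean=70, tinf_sd=0,
                           tau_mean=1e-6, tau_sd=1e-9)
        with pytest.raises((RuntimeError, ValueError)):
            # tau_mean must be positive but far below the 1-s truncation bound:
            # every draw is rejected
            simulate_trace(g, seed=0)

    def test_truncation_keeps_draws_physical(self):
        # saline 940 nm has tau SD 12.3 s: unbounded normal draws can go below 1 s
        g = SimGroupParams(940, SALINE, t0_mean=31, t0_sd=1, tinf_mean=72.8, tinf_sd=3,
                           tau_mean=5, tau_sd=12.3)
        rng = np.random.default_rng(0)
        draws = [sample_animal_params(g, rng)[2] for _ in range(500)]
        assert min(draws) > 1.0


class TestEnsembleStatistics:
    def test_tau_moments_recovered_over_many_animals(self):
        g = SimGroupParams(808, SALINE, t0_mean=30, t0_sd=1, tinf_mean=60, tinf_sd=1,
                           tau_mean=67.8, tau_sd=1.8, n_animals=250)
        _, manifest = simulate_design([g], seed=21)
        taus = manifest["tau"].to_numpy()
        se_mean = 1.8 / np.sqrt(len(taus))
        assert abs(taus.mean() - 67.8) < 3 * se_mean
        se_sd = 1.8 / np.sqrt(2 * (len(taus) - 1))
        assert abs(taus.std(ddof=1) - 1.8) < 3 * se_sd


class TestSimulateStack:
    def test_null_heating_gives_constant_body_temp(self, quiet_camera):
        g = SimGroupParams(808, GNR, t0_mean=33, t0_sd=0, tinf_mean=33.001, tinf_sd=0,
                           tau_mean=40, tau_sd=0)
        stack = simulate_stack(g, quiet_camera, SceneSpec(exposure_s=10, pre_exposure_s=0), seed=0)
        inside = stack.frames[:, 60, 80]
        assert np.allclose(inside, 33.0, atol=0.01)
        assert np.allclose(stack.frames[:, 0, 0], 24.0)  # ambient outside the mask

    def test_hotspot_center_profile_matches_trace_oracle(self, quiet_camera):
        g = SimGroupParams(975, GNR, t0_mean=29, t0_sd=0, tinf_mean=87.3, tinf_sd=0,
                           tau_mean=31.3, tau_sd=0)
        scene = SceneSpec(exposure_s=30, pre_exposure_s=0)
        stack = simulate_stack(g, quiet_camera, scene, seed=0)
        r, c = stack.truth["hotspot_center"]
        profile = stack.frames[:, r, c]
        expected = first_order(stack.times, 29.0, 87.3, 31.3)
        np.testing.assert_allclose(profile, expected, atol=1e-9)

    def test_quantization_bounds_center_profile_error(self):
        cam = CameraModel(noise_sd=0.0, quantization_step=0.01)
        g = SimGroupParams(808, GNR, t0_mean=29, t0_sd=0, tinf_mean=71.2, tinf_sd=0,
                           tau_mean=34.8, tau_sd=0)
        stack = simulate_stack(g, cam, SceneSpec(exposure_s=20, pre_exposure_s=0), seed=0)
        r, c = stack.truth["hotspot_center"]
        expected = first_order(stack.times, 29.0, 71.2, 34.8)
        assert np.max(np.abs(stack.frames[:, r, c] - expected)) <= 0.005 + 1e-12

    def test_frame_count_includes_pre_exposure(self, quiet_camera):
        stack = simulate_stack(default_paper_params()[0], quiet_camera,
                               SceneSpec(exposure_s=90, pre_exposure_s=5), seed=0)
        assert stack.n_frames == int(np.floor(95 * 6))  # 570
        assert stack.laser_on_index == 30
        assert np.all(stack.times[:30] < 0)

    def test_noiseless_spatial_maximum_at_hotspot(self, quiet_camera):
        scene = SceneSpec(hotspot_center=(50, 60), exposure_s=20, pre_exposure_s=0)
        stack = simulate_stack(default_paper_params()[0], quiet_camera, scene, seed=2)
        last = stack.frames[-1]
        assert np.unravel_index(np.argmax(last), last.shape) == (50, 60)

    def test_hotspot_outside_mask_rejected(self, quiet_camera):
        scene = SceneSpec(hotspot_center=(0, 0), exposure_s=10)
        with pytest.raises(ValueError, match="outside the body mask"):
            simulate_stack(default_paper_params()[0], quiet_camera, scene, seed=0)


class TestDesignSimulation:
    def test_full_design_animal_count_and_manifest(self, paper_groups):
        traces, manifest = simulate_design(paper_groups, seed=3)
        assert len(traces) == 32
        assert len(manifest) == 32
        assert set(manifest.columns) >= {"animal_id", "wavelength", "injection",
                                         "t0", "tinf", "tau"}

    def test_substreams_stable_under_added_animals(self, paper_groups):
        assert animal_seed(5, 808, "GNR", 0).entropy == animal_seed(5, 808, "GNR", 0).entropy
        small, _ = simulate_design(default_paper_params(n_animals=2), seed=9)
        large, _ = simulate_design(default_paper_params(n_animals=4), seed=9)
        by_id = {tr.animal_id: tr for tr in large}
        for tr in small:
            np.testing.assert_array_equal(tr.temp_mean, by_id[tr.animal_id].temp_mean)
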