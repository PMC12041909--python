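"""Ground-truth generators: determinism, photon accounting, step statistics."""

import numpy as np
import pytest

from tconfine.simulate import (
    CellSpec,
    DeflectionProfile,
    PlacementError,
    SimParams,
    brownian_tracks,
    gen_confined_zstack,
    gen_deflection_profiles,
    gen_fura_stack,
    gen_immuno_image,
    gen_sm_movie,
)


class TestSmMovie:
    def test_identical_seed_gives_bit_identical_output(self, sm_params):
        s1, t1 = gen_sm_movie(sm_params, density=0.2)
        s2, t2 = gen_sm_movie(sm_params, density=0.2)
        np.testing.assert_array_equal(s1.data, s2.data)
        assert t1.table.equals(t2.table)

    def test_zero_density_gives_background_only(self):
        p = SimParams(field_size=(5, 5), n_frames=3, background_level=10.0,
                      noise_sd=0.0, seed=0)
        stack, truth = gen_sm_movie(p, density=0.0)
        np.testing.assert_allclose(stack.data, 10.0)
        assert truth.table.empty

    def test_initial_count_matches_poisson_mean(self):
        # Monte-Carlo over seeds vs the Poisson mean density × area
        counts = []
        for seed in range(100):
            p = SimParams(field_size=(10, 10), n_frames=1, seed=seed)
            _, truth = gen_sm_movie(p, density=0.5)
            counts.append(truth.extra["n_initial"])
        mean = np.mean(counts)
        se = np.std(counts) / np.sqrt(len(counts))
        assert abs(mean - 50.0) < 3 * se + 1e-9

    def test_frozen_dynamics_when_d_zero_and_no_bleach(self):
        p = SimParams(field_size=(10, 10), n_frames=5, bleach_rate=0.0, seed=3)
        _, truth = gen_sm_movie(p, density=0.3, d=0.0)
        for _, g in truth.table.groupby("id"):
            assert g["x_um"].nunique() == 1
            assert g["y_um"].nunique() == 1
            assert len(g) == 5

    def test_photon_accounting_noiseless(self):
        # total frame intensity equals the summed brightness of unbleached
        # molecules, up to PSF truncation at the field edge
        p = SimParams(field_size=(20, 20), n_frames=4, noise_sd=0.0,
                      background_level=0.0, bleach_rate=0.2, seed=5)
        stack, truth = gen_sm_movie(p, density=0.2)
        for t in range(p.n_frames):
            expected = truth.table.loc[truth.table["frame"] == t, "brightness"].sum()
            total = stack.data[t].sum()
            # molecules within ~4σ of the border lose flux off-field; allow
            # that on top of the 1e-3 truncation tolerance
            assert total <= expected * (1 + 1e-3)
            assert total >= expected * 0.8

    def test_step_variance_matches_2d_over_rate(self):
        rng = np.random.default_rng(11)
        d, dt = 0.5, 0.025
        pos = brownian_tracks(rng, 200, 101, d, dt, (1e6, 1e6))  # huge field: no reflection
        steps = np.diff(pos, axis=1).reshape(-1, 2)
        var = steps.var(axis=0, ddof=1)
        n = steps.shape[0]
        se = np.sqrt(2.0 / (n - 1)) * 2 * d * dt
        assert np.all(np.abs(var - 2 * d * dt) < 3 * se)

    def test_invalid_parameters_rejected(self):
        p = SimParams()
        with pytest.raises(ValueError):
            gen_sm_movie(p, density=0.1, d=-1.0)
        with pytest.raises(ValueError):
            gen_sm_movie(p, density=-0.1)
        with pytest.raises(ValueError):
            SimParams(bleach_rate=1.5)


class TestFuraStack:
    def test_unit_ratio_makes_channels_equal_on_cell(self):
        p = SimParams(field_size=(20, 20), pixel_size=0.5, n_frames=2,
                      background_level=0.0, noise_sd=0.0, seed=0)
        cell = CellSpec(np.full((2, 2), 10.0), np.full(2, 100.0), np.full(2, 1.0))
        stack, _ = gen_fura_stack(p, [cell])
        np.testing.assert_allclose(stack.data[0], stack.data[1])

    def test_rendered_area_matches_requested(self):
        p = SimParams(field_size=(20, 20), pixel_size=0.5, n_frames=1,
                      background_level=0.0, noise_sd=0.0, seed=0)
        cell = CellSpec(np.full((1, 2), 10.0), np.full(1, 100.0), np.full(1, 1.2))
        stack, _ = gen_fura_stack(p, [cell])
        # pixels above half amplitude approximate the disk footprint
        mask = stack.data[1][0] > 500.0
        area = mask.sum() * 0.5**2
        ring = 2 * np.pi * np.sqrt(100 / np.pi) * 0.5  # one-pixel ring
        assert abs(area - 100.0) < ring

    def test_ratio_fidelity_noiseless(self):
        # pixelwise (I340−B)/(I380−B) reproduces the input ratio curve
        p = SimParams(field_size=(20, 20), pixel_size=0.5, n_frames=3,
                      background_level=50.0, noise_sd=0.0, seed=0)
        ratios = np.array([0.8, 1.3, 2.0])
        cell = CellSpec(np.full((3, 2), 10.0), np.full(3, 80.0), ratios)
        stack, _ = gen_fura_stack(p, [cell])
        for t, r in enumerate(ratios):
            i340, i380 = stack.data[0, t], stack.data[1, t]
            on = (i380 - 50.0) > 1.0
            rec = (i340[on] - 50.0) / (i380[on] - 50.0)
            np.testing.assert_allclose(rec, r, rtol=1e-6)

    def test_zero_cells_gives_background_only(self):
        p = SimParams(field_size=(10, 10), pixel_size=0.5, n_frames=2,
                      background_level=7.0, noise_sd=0.0, seed=0)
        stack, truth = gen_fura_stack(p, [])
        np.testing.assert_allclose(stack.data, 7.0)
        assert truth.table.empty

    def test_overlapping_cells_warn_and_are_recorded(self):
        p = SimParams(field_size=(20, 20), pixel_size=0.5, n_frames=1, seed=0)
        c1 = CellSpec(np.full((1, 2), 9.0), np.full(1, 100.0), np.full(1, 1.0))
        c2 = CellSpec(np.full((1, 2), 11.0), np.full(1, 100.0), np.full(1, 1.0))
        with pytest.warns(UserWarning, match="overlap"):
            _, truth = gen_fura_stack(p, [c1, c2])
        assert truth.extra["overlap_frames"] == [0]


class TestConfinedZstack:
    @pytest.mark.parametrize("height", [6.0, 4.0])
    def test_two_axial_maxima_separated_by_height(self, height):
        stack = gen_confined_zstack(height, z_step=0.5)
        nz, ny, nx = stack.data.shape
        profile = stack.data[:, ny // 2, nx // 2]
        from scipy.signal import find_peaks

        peaks, _ = find_peaks(profile, prominence=0.1 * profile.max())
        assert len(peaks) == 2
        sep = (peaks[-1] - peaks[0]) * 0.5
        assert abs(sep - height) <= 0.5  # grid resolution before interpolation

    def test_delta_lamella_limit_concentrates_two_slices(self):
        stack = gen_confined_zstack(6.0, z_step=0.5, membrane_sigma=1e-6,
                                    lateral_radius=4.0)
        nz, ny, nx = stack.data.shape
        profile = stack.data[:, ny // 2, nx // 2]
        assert (profile > 1e-6 * profile.max()).sum() == 2

    def test_degenerate_height_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            gen_confined_zstack(0.8, z_step=0.5)


class TestImmunoImage:
    def test_zero_cells_blank(self):
        stack, truth = gen_immuno_image(0, seed=0)
        assert stack.data.max() == 0
        assert truth.table.empty

    def test_disk_areas_match_analytic(self):
        stack, truth = gen_immuno_image(3, cell_radius=8.0, seed=1)
        perk = stack.data[1][0]
        area = (perk > truth.table["perk_level"].iloc[0] / 2).sum() * 0.22**2
        assert abs(area - 3 * np.pi * 64) < 3 * 2 * np.pi * 8 * 0.22

    def test_uniform_level_noiseless(self):
        stack, truth = gen_immuno_image(2, perk_level=500.0, noise_sd=0.0, seed=2)
        perk = stack.data[1][0]
        ny, nx = perk.shape
        yy, xx = np.mgrid[0:ny, 0:nx] * 0.22 + 0.11
        interior = np.zeros_like(perk, dtype=bool)
        for _, row in truth.table.iterrows():
            interior |= np.hypot(xx - row.x_um, yy - row.y_um) < 8.0 - 0.5
        np.testing.assert_allclose(perk[interior], 500.0)

    def test_placement_error_when_field_too_small(self):
        with pytest.raises(PlacementError):
            gen_immuno_image(50, cell_radius=8.0, field_size=(40.0, 40.0), seed=0)

    def test_nucleus_must_fit_in_cell(self):
        with pytest.raises(ValueError):
            gen_immuno_image(1, nucleus_radius=9.0, cell_radius=8.0)


class TestDeflectionProfiles:
    def test_apex_is_slope_times_pressure(self):
        (prof,) = gen_deflection_profiles(6.5, [200.0], noise_sd=0.0)
        assert abs(prof.z_um.max() - 1300.0) < 1e-9

    def test_linearity_by_construction(self):
        p1, p2 = gen_deflection_profiles(6.5, [100.0, 200.0], noise_sd=0.0)
        np.testing.assert_allclose(2 * p1.z_um, p2.z_um, atol=1e-9)

    def test_shape_vanishes_at_rim(self):
        (prof,) = gen_deflection_profiles(5.0, [100.0], noise_sd=0.0)
        assert abs(prof.z_um[0]) < 1e-9
        assert abs(prof.z_um[-1]) < 1e-9

    def test_invalid_shape_rejected(self):
        with pytest.raises(ValueError, match="rim"):
            gen_deflection_profiles(5.0, [100.0], profile_shape=(1.0, -0.5))
        with pytest.raises(ValueError):
            gen_deflection_profiles(5.0, [-10.0])

    def test_profile_positions_must_increase(self):
        with pytest.raises(ValueError):
            DeflectionProfile(x_mm=np.array([0.0, 0.0, 1.0]),
                              z_um=np.zeros(3), pressure_mbar=10.0)
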