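"""Bilayer characterization: localization, filtering, density, tracking, D."""

import numpy as np
import pandas as pd
import pytest

from tconfine.io import ImageStack
from tconfine.simulate import SimParams, gen_sm_movie, render_spots
from tconfine.slb import (
    SLBError,
    estimate_density,
    filter_spots,
    link_molecules,
    localize_spots,
    molecule_diffusion,
    single_molecule_brightness,
)


def spot_stack(xs, ys, brightness=1000.0, sigma=1.0, shape=(32, 32), noise=0.0, seed=0):
    img = render_spots(shape, np.asarray(xs, float), np.asarray(ys, float),
                       np.asarray(brightness, float), sigma)
    if noise:
        img = img + np.random.default_rng(seed).normal(0, noise, img.shape)
    return ImageStack(img[None], pixel_size=0.16, frame_interval=0.025)


class TestLocalize:
    def test_single_spot_recovered_with_subpixel_accuracy(self):
        locs = localize_spots(spot_stack([15.3], [12.7]), detection_threshold=30)
        assert len(locs) == 1
        row = locs.iloc[0]
        assert abs(row.x_px - 15.3) < 0.05
        assert abs(row.y_px - 12.7) < 0.05
        assert 0.95 < row.size_px < 1.05
        assert 950 < row.brightness < 1050

    def test_blank_frame_gives_no_localizations(self):
        stack = ImageStack(np.zeros((1, 32, 32)), pixel_size=0.16)
        assert localize_spots(stack).empty

    def test_two_spots_ten_px_apart_both_found(self):
        locs = localize_spots(spot_stack([10.0, 20.0], [16.0, 16.0]), detection_threshold=30)
        assert len(locs) == 2
        xs = np.sort(locs["x_px"].to_numpy())
        np.testing.assert_allclose(xs, [10.0, 20.0], atol=0.5)

    def test_saturated_spot_flagged_not_fitted(self):
        img = render_spots((32, 32), np.array([16.0]), np.array([16.0]),
                           np.array([1e6]), 1.0)
        data = np.clip(img, 0, 65535).astype(np.uint16)
        stack = ImageStack(data[None], pixel_size=0.16)
        locs = localize_spots(stack, detection_threshold=30)
        assert locs["saturated"].all()
        assert locs["brightness"].isna().all()

    def test_duplicates_within_one_px_merged_keeping_brighter(self):
        locs = localize_spots(spot_stack([16.0, 16.4], [16.0, 16.0], [1000.0, 400.0]),
                              detection_threshold=30)
        assert len(locs) == 1
        assert locs.iloc[0].brightness > 1000  # merged flux fitted as one spot


class TestFilterAndBrightness:
    def locs_frame(self, sizes, frame=0):
        return pd.DataFrame(
            {"frame": frame, "x_px": 10.0, "y_px": 10.0, "x_um": 1.6, "y_um": 1.6,
             "brightness": 1000.0, "size_px": sizes, "bg": 0.0, "saturated": False}
        )

    def test_size_bounds_are_exclusive(self):
        locs = self.locs_frame([0.5, 1.0, 1.3, 0.75, 1.25])
        filtered, _ = filter_spots(locs, field_area=1000.0)
        assert filtered["size_px"].tolist() == [1.0]

    def test_first_qualifying_frame_by_count_arithmetic(self):
        # 100 spots in 1000 μm² (0.10) frames 0–4, 80 (0.08) from frame 5
        parts = [self.locs_frame([1.0] * (100 if f < 5 else 80), frame=f) for f in range(8)]
        locs = pd.concat(parts, ignore_index=True)
        _, fq = filter_spots(locs, field_area=1000.0)
        assert fq == 5

    def test_threshold_comparison_is_inclusive(self):
        locs = pd.concat([self.locs_frame([1.0] * 90, frame=0)], ignore_index=True)
        _, fq = filter_spots(locs, field_area=1000.0)  # exactly 0.09
        assert fq == 0

    def test_density_never_qualifying_raises(self):
        locs = self.locs_frame([1.0] * 100)
        with pytest.raises(SLBError, match="never below"):
            filter_spots(locs, field_area=100.0, n_frames=1)

    def test_empty_table_raises(self):
        with pytest.raises(SLBError):
            filter_spots(pd.DataFrame(columns=["frame", "size_px", "saturated"]),
                         field_area=100.0)

    def test_brightness_is_interval_mean(self):
        rows = pd.DataFrame(
            {"frame": [5, 6, 7, 20], "brightness": [900.0, 1000.0, 1100.0, 99999.0]}
        )
        assert single_molecule_brightness(rows, 5, interval=10) == 1000.0
        with pytest.raises(SLBError):
            single_molecule_brightness(rows, 100, interval=10)

    def test_brightness_recovered_from_generator_movie(self, sm_params):
        stack, truth = gen_sm_movie(sm_params, density=0.3)
        locs = localize_spots(stack)
        filtered, fq = filter_spots(locs, field_area=stack.field_area,
                                    n_frames=sm_params.n_frames)
        smb = single_molecule_brightness(filtered, fq)
        sel = filtered[(filtered.frame >= fq) & (filtered.frame < fq + 10)]
        se = 1000 * 0.1 / np.sqrt(max(sel["brightness"].size, 1))
        assert abs(smb - 1000.0) < max(3 * se, 60.0)


class TestDensity:
    def test_density_from_known_total_flux(self):
        # 50 molecules × 1000 counts in 100 μm², background 0 → 0.5 μm⁻²
        rng = np.random.default_rng(2)
        n, b = 50, 1000.0
        shape = (50, 50)  # 10×10 μm at 0.2 μm/px
        xs = rng.uniform(8, 42, n)
        ys = rng.uniform(8, 42, n)
        img = render_spots(shape, xs, ys, np.full(n, b), 1.0)
        stack = ImageStack(img[None], pixel_size=0.2)
        est = estimate_density(stack, smb=b, background=0.0)
        assert abs(est.density - 0.5) / 0.5 < 0.01

    def test_blank_field_gives_zero(self):
        stack = ImageStack(np.zeros((1, 20, 20)), pixel_size=0.2)
        est = estimate_density(stack, smb=1000.0, background=0.0)
        assert est.density == 0.0

    def test_scale_invariance(self):
        img = render_spots((40, 40), np.array([20.0]), np.array([20.0]),
                           np.array([1000.0]), 1.0)
        s1 = ImageStack(img[None], pixel_size=0.2)
        s2 = ImageStack(2 * img[None], pixel_size=0.2)
        d1 = estimate_density(s1, smb=1000.0, background=0.0).density
        d2 = estimate_density(s2, smb=2000.0, background=0.0).density
        np.testing.assert_allclose(d1, d2, rtol=1e-12)

    def test_nonpositive_brightness_rejected(self):
        stack = ImageStack(np.zeros((1, 8, 8)), pixel_size=0.2)
        with pytest.raises(SLBError):
            estimate_density(stack, smb=0.0)

    def test_excess_background_clips_to_zero_with_warning(self):
        stack = ImageStack(np.full((1, 8, 8), 5.0), pixel_size=0.2)
        with pytest.warns(UserWarning, match="clip"):
            est = estimate_density(stack, smb=1000.0, background=50.0)
        assert est.density == 0.0

    def test_relative_bias_under_five_percent(self):
        # full pipeline bias across the working density range
        for dens in (0.05, 0.5):
            ests, trues = [], []
            for seed in range(3):
                p = SimParams(field_size=(15, 15), n_frames=150, noise_sd=3.0,
                              bleach_rate=0.04, seed=seed)
                stack, truth = gen_sm_movie(p, density=dens)
                locs = localize_spots(stack)
                filtered, fq = filter_spots(locs, field_area=stack.field_area,
                                            n_frames=p.n_frames)
                smb = single_molecule_brightness(filtered, fq)
                ests.append(estimate_density(stack, smb, background=0.0).density)
                trues.append(truth.density)
            bias = abs(np.mean(ests) - np.mean(trues)) / np.mean(trues)
            assert bias < 0.05


def tracks_from_positions(pos_list):
    rows = []
    for i, pos in enumerate(pos_list):
        pos = np.asarray(pos, float)
        rows.append(pd.DataFrame({"particle": i, "frame": np.arange(len(pos)),
                                  "x_um": pos[:, 0], "y_um": pos[:, 1]}))
    return pd.concat(rows, ignore_index=True)


def locs_from_positions(pos_px, pixel_size=1.0):
    """Localization table from per-frame pixel positions [(n_frames, 2), ...]."""
    rows = []
    for pos in pos_px:
        pos = np.asarray(pos, float)
        for f, (x, y) in enumerate(pos):
            rows.append({"frame": f, "x_px": x, "y_px": y,
                         "x_um": (x + 0.5) * pixel_size, "y_um": (y + 0.5) * pixel_size,
                         "brightness": 1000.0, "size_px": 1.0, "bg": 0.0,
                         "saturated": False})
    return pd.DataFrame(rows)


class TestLinking:
    def test_single_molecule_single_track(self):
        pos = np.column_stack([np.linspace(5, 15, 11), np.full(11, 5.0)])
        tracks = link_molecules(locs_from_positions([pos]))
        assert tracks["particle"].nunique() == 1
        assert len(tracks) == 11

    def test_step_beyond_radius_splits_track(self):
        pos = np.array([[5.0, 5.0], [5.5, 5.0], [12.5, 5.0], [13.0, 5.0]])
        tracks = link_molecules(locs_from_positions([pos]), search_radius=6.0)
        assert tracks["particle"].nunique() == 2

    def test_well_separated_molecules_never_swap(self):
        rng = np.random.default_rng(4)
        a = np.cumsum(rng.normal(0, 0.5, (20, 2)), axis=0) + [10, 10]
        b = np.cumsum(rng.normal(0, 0.5, (20, 2)), axis=0) + [60, 60]
        tracks = link_molecules(locs_from_positions([a, b]), search_radius=6.0)
        assert tracks["particle"].nunique() == 2
        for _, g in tracks.groupby("particle"):
            span = g[["x_px", "y_px"]].agg(np.ptp).max()
            assert span < 20  # stayed near its own cluster

    def test_linking_reproduces_generator_ids_up_to_relabeling(self):
        # feed the generator's noiseless truth positions straight into the
        # linker: the recovered partition must equal the true one
        p = SimParams(field_size=(15, 15), n_frames=15, bleach_rate=0.1, seed=6)
        _, truth = gen_sm_movie(p, density=0.08)
        tt = truth.table
        locs = pd.DataFrame(
            {"frame": tt["frame"], "x_px": tt["x_um"] / 0.16 - 0.5,
             "y_px": tt["y_um"] / 0.16 - 0.5, "x_um": tt["x_um"],
             "y_um": tt["y_um"], "brightness": 1000.0, "size_px": 1.0,
             "bg": 0.0, "saturated": False}
        )
        tracks = link_molecules(locs)
        assert tracks["particle"].nunique() == tt["id"].nunique()
        joined = tracks.merge(tt, on=["frame", "x_um", "y_um"])
        # permutation-invariant: each recovered id maps to exactly one truth id
        assert (joined.groupby("particle")["id"].nunique() == 1).all()

    def test_empty_input_gives_empty_table(self):
        out = link_molecules(pd.DataFrame(columns=["frame", "x_px", "y_px",
                                                   "x_um", "y_um", "saturated"]))
        assert out.empty


class TestDiffusion:
    def test_static_tracks_give_zero_d_and_immobile(self):
        pos = [np.tile([5.0, 5.0], (10, 1)) for _ in range(12)]
        mob = molecule_diffusion(tracks_from_positions(pos), frame_interval=0.025)
        assert mob.d < 1e-12
        assert mob.mobile_fraction == 0.0

    def test_d_recovered_from_222_tracks(self):
        # oracle: per-axis step SD σ at interval Δt implies D = σ²/(2Δt)
        rng = np.random.default_rng(0)
        sd, dt = 0.2408, 0.025
        pos = [np.cumsum(rng.normal(0, sd, (30, 2)), axis=0) for _ in range(222)]
        mob = molecule_diffusion(tracks_from_positions(pos), frame_interval=dt)
        truth = sd**2 / (2 * dt)
        assert abs(mob.d - truth) / truth < 0.10
        assert mob.mobile_fraction > 0.98

    def test_minimum_step_filter(self):
        short = [np.cumsum(np.random.default_rng(i).normal(0, 0.2, (4, 2)), axis=0)
                 for i in range(5)]
        with pytest.raises(SLBError):
            molecule_diffusion(tracks_from_positions(short), frame_interval=0.025)

    def test_estimator_consistency_over_seeds(self):
        # mean recovered D within 3 SE of truth across seeds
        dt = 0.025
        for truth in (0.1, 1.16):
            est = []
            for seed in range(20):
                rng = np.random.default_rng(seed)
                sd = np.sqrt(2 * truth * dt)
                pos = [np.cumsum(rng.normal(0, sd, (25, 2)), axis=0) for _ in range(60)]
                est.append(molecule_diffusion(tracks_from_positions(pos),
                                              frame_interval=dt).d)
            se = np.std(est, ddof=1) / np.sqrt(len(est))
            assert abs(np.mean(est) - truth) < 3 * se + 0.01 * truth

    def test_low_sample_warning_flag(self):
        pos = [np.cumsum(np.random.default_rng(1).normal(0, 0.2, (10, 2)), axis=0)]
        with pytest.warns(UserWarning, match="low-sample"):
            mob = molecule_diffusion(tracks_from_positions(pos), frame_interval=0.025)
        assert mob.low_sample
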