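"""Region-competition speed terms, energy functional, and speed bounds."""

import numpy as np
import pytest

import contourctl as cc
from contourctl.region import _ball_footprint


def disc_image(grid, center, radius, inside=10.0, outside=2.0):
    rr, cci = grid.coordinate_arrays()
    mask = np.hypot(rr - center[0], cci - center[1]) <= radius
    return cc.ScalarField(np.where(mask, inside, outside), grid), mask


class TestRegionMeans:
    def test_constant_image(self, circle_sdf):
        image = cc.ScalarField(np.full(circle_sdf.grid.shape, 7.0), circle_sdf.grid)
        assert cc.region_means(image, circle_sdf) == pytest.approx((7.0, 7.0))

    def test_two_level_image_recovered(self, grid64, circle_sdf):
        image, _ = disc_image(grid64, (32, 32), 20.0)
        mu_in, mu_out = cc.region_means(image, circle_sdf)
        assert mu_in == pytest.approx(10.0, abs=0.2)
        assert mu_out == pytest.approx(2.0, abs=0.2)

    def test_matches_brute_force_masked_average(self, grid64):
        rng = np.random.default_rng(3)
        image = cc.ScalarField(rng.normal(5.0, 2.0, grid64.shape), grid64)
        phi = cc.circle_seed(grid64, (30, 34), 15.0)
        mu_in, _ = cc.region_means(image, phi)
        H = cc.heaviside_eps(phi.values, phi.eps_phys)
        oracle = (H * image.values).sum() / H.sum()
        assert mu_in == pytest.approx(oracle, rel=1e-12)

    def test_collapsed_interior_rejected(self, grid64):
        image = cc.ScalarField(np.zeros(grid64.shape), grid64)
        phi = cc.LevelSetField(np.full(grid64.shape, -5.0), grid64)
        with pytest.raises(cc.CollapsedSegmentationError):
            cc.region_means(image, phi)


class TestChanVeseSpeed:
    def test_sign_structure(self, grid64, circle_sdf):
        image, _ = disc_image(grid64, (32, 32), 20.0)
        mu_in, mu_out = cc.region_means(image, circle_sdf)
        G = cc.chan_vese_speed(image, circle_sdf).values
        # interior-matching pixels expand, exterior-matching contract
        assert G[32, 32] == pytest.approx((mu_in - mu_out) ** 2, rel=0.05)
        assert G[2, 2] == pytest.approx(-((mu_in - mu_out) ** 2), rel=0.05)

    def test_midpoint_intensity_is_neutral(self, grid64, circle_sdf):
        image, _ = disc_image(grid64, (32, 32), 20.0)
        mu_in, mu_out = cc.region_means(image, circle_sdf)
        mid = cc.ScalarField(np.full(grid64.shape, (mu_in + mu_out) / 2), grid64)
        G = -((mid.values - mu_in) ** 2) + (mid.values - mu_out) ** 2
        assert np.abs(G).max() < 1e-10

    def test_antisymmetric_under_label_swap(self, grid64):
        rng = np.random.default_rng(7)
        image = cc.ScalarField(rng.uniform(0, 10, grid64.shape), grid64)
        phi = cc.circle_seed(grid64, (32, 32), 18.0)
        G = cc.chan_vese_speed(image, phi).values
        G_swapped = cc.chan_vese_speed(image, phi.with_values(-phi.values)).values
        assert np.allclose(G_swapped, -G, atol=1e-10)


class TestEnergy:
    def test_perfect_partition_zero_data_energy(self, grid64):
        phi = cc.circle_seed(grid64, (32, 32), 20.0)
        rr, cci = grid64.coordinate_arrays()
        sharp = np.where(np.hypot(rr - 32, cci - 32) <= 20.0, 10.0, 2.0)
        image = cc.ScalarField(sharp, grid64)
        aligned = cc.energy(image, phi, lambda_smooth=0.0)
        misplaced = cc.energy(image, cc.circle_seed(grid64, (20, 44), 20.0), 0.0)
        # the smeared Heaviside band carries O(perimeter * contrast^2)
        # residual energy even for a perfect partition
        assert aligned < 0.1 * misplaced

    def test_length_term_recovers_perimeter(self):
        grid = cc.Grid((128, 128))
        phi = cc.circle_seed(grid, (64, 64), 30.0)
        image = cc.ScalarField(np.zeros(grid.shape), grid)
        lam = 2.0
        E = cc.energy(image, phi, lam)
        assert E == pytest.approx(lam * 2 * np.pi * 30.0, rel=0.05)

    def test_open_loop_flow_decreases_energy(self, phantom):
        image, _ = phantom
        seed = cc.circle_seed(image.grid, (64, 38), 8.0)
        cfg = cc.SessionConfig(mode="open_loop", max_steps=200)
        res = cc.run_open_loop(image, seed, cfg)
        E = np.array(res.diagnostics.E)
        dE = np.diff(E)
        redist = (np.arange(1, len(E)) + 1) % cfg.redist_every == 0
        between = dE[~redist[: len(dE)]]
        assert (between <= 1e-6 * np.abs(E[:-1][~redist[: len(dE)]])).all()


class TestLocalizedSpeed:
    def test_constant_image_is_neutral(self, circle_sdf):
        image = cc.ScalarField(np.full(circle_sdf.grid.shape, 4.0), circle_sdf.grid)
        G = cc.localized_speed(image, circle_sdf, r_loc=6.0)
        assert np.abs(G.values).max() < 1e-9

    def test_matches_double_loop_oracle(self):
        grid = cc.Grid((32, 32))
        rng = np.random.default_rng(11)
        image = cc.ScalarField(rng.uniform(0, 1, grid.shape), grid)
        phi = cc.circle_seed(grid, (16, 16), 9.0)
        r_loc = 6.0
        G = cc.localized_speed(image, phi, r_loc).values

        eps = phi.eps_phys
        H = cc.heaviside_eps(phi.values, eps)
        rr, cci = grid.coordinate_arrays()
        band = np.argwhere(np.abs(phi.values) <= eps)
        for row, col in band[::7]:
            ball = (rr - rr[row, col]) ** 2 + (cci - cci[row, col]) ** 2 <= r_loc**2
            mu_in = (H * image.values)[ball].sum() / H[ball].sum()
            mu_out = ((1 - H) * image.values)[ball].sum() / (1 - H)[ball].sum()
            oracle = -(image.values[row, col] - mu_in) ** 2 \
                + (image.values[row, col] - mu_out) ** 2
            assert G[row, col] == pytest.approx(oracle, rel=1e-6, abs=1e-9)

    def test_reduces_to_global_for_huge_ball(self):
        grid = cc.Grid((32, 32))
        rng = np.random.default_rng(5)
        image = cc.ScalarField(rng.uniform(0, 1, grid.shape), grid)
        phi = cc.circle_seed(grid, (16, 16), 9.0)
        G_loc = cc.localized_speed(image, phi, r_loc=100.0).values
        G_glob = cc.chan_vese_speed(image, phi).values
        band = np.abs(phi.values) <= phi.eps_phys
        assert np.allclose(G_loc[band], G_glob[band], rtol=1e-9)

    def test_bright_disc_on_ramp_sign_structure(self):
        grid = cc.Grid((64, 64))
        rr, cci = grid.coordinate_arrays()
        image = cc.ScalarField(cci * 0.1 + np.where(
            np.hypot(rr - 32, cci - 32) <= 12.0, 3.0, 0.0), grid)
        phi = cc.circle_seed(grid, (32, 32), 12.0)
        G = cc.localized_speed(image, phi, r_loc=6.0).values
        assert G[32, 32 + 10] > 0   # just inside the disc edge
        assert G[32, 32 + 14] < 0   # just outside

    def test_tiny_ball_rejected(self, circle_sdf):
        image = cc.ScalarField(np.zeros(circle_sdf.grid.shape), circle_sdf.grid)
        with pytest.raises(ValueError):
            cc.localized_speed(image, circle_sdf, r_loc=0.5)


class TestSpeedBound:
    @pytest.mark.parametrize("lo,hi,expected", [
        (0.0, 10.0, 100.0),
        (2.0, 10.0, 64.0),
        (5.0, 5.0, 0.0),
    ])
    def test_range_squared(self, grid64, lo, hi, expected):
        vals = np.linspace(lo, hi, np.prod(grid64.shape)).reshape(grid64.shape)
        bound = cc.speed_bound(cc.RegionModel(), cc.ScalarField(vals, grid64))
        assert bound.global_bound == pytest.approx(expected)
        assert (bound.pointwise <= bound.global_bound + 1e-12).all()

    @pytest.mark.parametrize("kind,r_loc", [("global_means", 8.0),
                                            ("localized_means", 6.0)])
    def test_bound_dominates_any_encountered_speed(self, grid64, kind, r_loc):
        rng = np.random.default_rng(2)
        image = cc.ScalarField(rng.uniform(0, 10, grid64.shape), grid64)
        model = cc.RegionModel(kind=kind, r_loc=r_loc)
        bound = model.bound(image)
        for center, radius in [((32, 32), 20.0), ((20, 40), 8.0)]:
            phi = cc.circle_seed(grid64, center, radius)
            G = model.speed(image, phi).values
            assert np.abs(G).max() <= bound.global_bound + 1e-9

    def test_ball_footprint_is_symmetric(self, grid64):
        fp = _ball_footprint(grid64, 5.0)
        assert np.array_equal(fp, fp[::-1, :])
        assert np.array_equal(fp, fp[:, ::-1])
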