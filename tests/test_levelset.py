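"""Level-set primitives: regularized step/delta, curvature, redistancing."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import contourctl as cc
from contourctl.levelset import (curvature_array, gradient_norm,
                                 stability_limit)

from conftest import brute_force_interface_distance


class TestHeavisideDelta:
    @pytest.mark.parametrize("phi,eps,expected", [
        (3.0, 2.0, 1.0),
        (-3.0, 2.0, 0.0),
        (0.0, 2.0, 0.5),
        (1.0, 2.0, 0.75 + 1.0 / (2 * np.pi)),
    ])
    def test_heaviside_values(self, phi, eps, expected):
        assert cc.heaviside_eps(phi, eps) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("phi,eps,expected", [
        (0.0, 2.0, 0.5),
        (3.0, 2.0, 0.0),
        (-3.0, 2.0, 0.0),
        (1.0, 2.0, 0.25),
    ])
    def test_delta_values(self, phi, eps, expected):
        assert cc.delta_eps(phi, eps) == pytest.approx(expected, abs=1e-12)

    @given(st.floats(-4.0, 4.0), st.floats(0.5, 3.0))
    @settings(max_examples=200, derandomize=True)
    def test_heaviside_symmetry(self, phi, eps):
        total = cc.heaviside_eps(phi, eps) + cc.heaviside_eps(-phi, eps)
        assert total == pytest.approx(1.0, abs=1e-12)

    @given(st.floats(0.5, 3.0))
    @settings(max_examples=30, derandomize=True)
    def test_delta_is_derivative_of_heaviside(self, eps):
        phis = np.linspace(-2 * eps, 2 * eps, 401)
        step = 1e-4
        fd = (cc.heaviside_eps(phis + step, eps)
              - cc.heaviside_eps(phis - step, eps)) / (2 * step)
        assert np.abs(fd - cc.delta_eps(phis, eps)).max() < 1e-3

    def test_heaviside_monotone(self):
        phis = np.linspace(-5, 5, 1001)
        H = cc.heaviside_eps(phis, 1.5)
        assert (np.diff(H) >= -1e-15).all()

    def test_invalid_eps_rejected(self):
        with pytest.raises(ValueError):
            cc.heaviside_eps(0.0, -1.0)
        with pytest.raises(ValueError):
            cc.delta_eps(0.0, 0.0)

    def test_delta_support_is_the_band(self):
        phis = np.linspace(-6, 6, 1201)
        d = cc.delta_eps(phis, 1.5)
        assert (d[np.abs(phis) > 1.5] == 0).all()
        assert (d[np.abs(phis) < 1.5] > 0).all()


class TestCurvature:
    @pytest.mark.parametrize("radius", [10.0, 20.0, 40.0])
    def test_circle_signed_distance(self, radius):
        grid = cc.Grid((128, 128))
        phi = cc.circle_seed(grid, (64, 64), radius)
        kappa = curvature_array(phi.values, grid.spacing)
        # sample on the circle, away from center and border
        theta = np.linspace(0, 2 * np.pi, 60, endpoint=False)
        rows = np.clip(np.round(64 + radius * np.sin(theta)).astype(int), 2, 125)
        cols = np.clip(np.round(64 + radius * np.cos(theta)).astype(int), 2, 125)
        dist = np.hypot(rows - 64.0, cols - 64.0)   # actual sample radius
        assert np.allclose(kappa[rows, cols], -1.0 / dist, rtol=0.05)

    def test_planar_ramp_is_flat(self, grid64):
        rr, cci = grid64.coordinate_arrays()
        field = cc.ScalarField(0.7 * rr + 0.1 * cci + 3.0, grid64)
        kappa = cc.curvature(field)
        # replicate boundaries bend the level lines near the border (the
        # divergence stencil reaches two cells in); the operator must be
        # exactly flat on the interior
        assert np.abs(kappa.values[2:-2, 2:-2]).max() < 1e-10

    def test_constant_field_uses_floor_branch(self, grid64):
        field = cc.ScalarField(np.full(grid64.shape, 2.5), grid64)
        assert np.all(cc.curvature(field).values == 0.0)

    def test_sphere_in_3d(self):
        grid = cc.Grid((48, 48, 48))
        phi = cc.circle_seed(grid, (24, 24, 24), 12.0)
        kappa = curvature_array(phi.values, grid.spacing)
        # mean curvature of a sphere with interior-positive distance: -2/r
        assert kappa[24, 24, 24 + 12] == pytest.approx(-2.0 / 12.0, rel=0.08)


class TestRedistance:
    def test_zero_set_invariant_under_scaling(self, circle_sdf):
        scaled = circle_sdf.with_values(2.0 * circle_sdf.values)
        rd = cc.redistance(scaled)
        band = rd.band_mask()
        assert np.abs(rd.values - circle_sdf.values)[band].max() < 0.1

    def test_idempotence(self, circle_sdf):
        once = cc.redistance(circle_sdf)
        twice = cc.redistance(once)
        band = once.band_mask()
        assert np.abs(twice.values - once.values)[band].max() < 0.1

    def test_gradient_bounds_on_band(self, circle_sdf):
        rd = cc.redistance(circle_sdf.with_values(3.0 * circle_sdf.values))
        gn = gradient_norm(rd.values, rd.grid.spacing)
        band = rd.band_mask()
        assert gn[band].min() > 0.8
        assert gn[band].max() < 1.2

    def test_two_disjoint_circles_against_brute_force(self, grid64):
        a = cc.circle_seed(grid64, (20, 20), 9.0).values
        b = cc.circle_seed(grid64, (45, 45), 11.0).values
        phi = cc.LevelSetField(np.maximum(a, b), grid64)
        rd = cc.redistance(phi)
        oracle = brute_force_interface_distance(phi)
        near = np.abs(rd.values) < 3.0
        assert np.abs(np.abs(rd.values) - oracle)[near].max() < 1.0

    def test_sign_pattern_preserved(self, circle_sdf):
        rd = cc.redistance(circle_sdf.with_values(5.0 * circle_sdf.values))
        away = np.abs(circle_sdf.values) > 1.0
        assert np.array_equal(np.sign(rd.values[away]),
                              np.sign(circle_sdf.values[away]))

    def test_uniform_sign_rejected(self, grid64):
        phi = cc.LevelSetField(np.full(grid64.shape, 3.0), grid64)
        with pytest.raises(cc.DegenerateLevelSetError):
            cc.redistance(phi)


class TestNarrowband:
    def test_circle_band_matches_distance_check(self, circle_sdf):
        idx = cc.narrowband(circle_sdf)
        mask = np.zeros(circle_sdf.grid.shape, bool)
        mask[tuple(idx.T)] = True
        rr, cci = circle_sdf.grid.coordinate_arrays()
        d = np.abs(np.hypot(rr - 32, cci - 32) - 20.0)
        assert np.array_equal(mask, d <= circle_sdf.eps_phys)

    def test_empty_when_far_from_zero(self, grid64):
        phi = cc.LevelSetField(np.full(grid64.shape, 10.0), grid64)
        assert len(cc.narrowband(phi)) == 0

    def test_everything_when_eps_exceeds_domain(self, circle_sdf):
        wide = cc.LevelSetField(circle_sdf.values, circle_sdf.grid, eps=1000.0)
        assert len(cc.narrowband(wide)) == np.prod(circle_sdf.grid.shape)


class TestEvolveStep:
    def test_zero_speed_is_identity(self, circle_sdf):
        out = cc.evolve_step(circle_sdf, np.zeros(circle_sdf.grid.shape), 0.1)
        assert np.array_equal(out.values, circle_sdf.values)

    def test_positive_speed_inflates_interior(self, circle_sdf):
        phi = circle_sdf
        areas = [phi.interior_mask().sum()]
        for _ in range(40):
            phi = cc.evolve_step(phi, np.full(phi.grid.shape, 1.0), 0.4)
            phi = cc.redistance(phi)
            areas.append(phi.interior_mask().sum())
        assert areas[-1] > areas[0]
        assert (np.diff(areas) >= 0).all()

    def test_step_reversible_in_dt(self, circle_sdf):
        rng = np.random.default_rng(0)
        speed = rng.normal(size=circle_sdf.grid.shape)
        dt = 1e-6
        fwd = cc.evolve_step(circle_sdf, speed, dt)
        back = cc.evolve_step(fwd, speed, -dt)
        assert np.abs(back.values - circle_sdf.values).max() < 1e-10

    def test_narrowband_containment_exact(self, circle_sdf):
        speed = np.full(circle_sdf.grid.shape, 0.9)
        out = cc.evolve_step(circle_sdf, speed, 0.5)
        outside = np.abs(circle_sdf.values) > circle_sdf.eps_phys
        assert np.array_equal(out.values[outside], circle_sdf.values[outside])

    def test_unstable_dt_rejected(self, circle_sdf):
        speed = np.full(circle_sdf.grid.shape, 10.0)
        limit = stability_limit(circle_sdf, speed)
        with pytest.raises(cc.StabilityError):
            cc.evolve_step(circle_sdf, speed, 2.1 * limit)
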