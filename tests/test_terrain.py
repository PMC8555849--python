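"""Terrain derivative oracles: flat surfaces, analytic planes, ray casts."""

import numpy as np
import pytest

from benthoscape.grids import DepthGrid
from benthoscape.terrain import (
    BpiSpec,
    FetchSpec,
    bpi,
    block_mean,
    build_stack,
    derive_local,
    fetch_sum,
    resample_energy,
)


class TestLocalDerivatives:
    def test_flat_surface_is_featureless(self, flat_grid):
        assert np.allclose(derive_local(flat_grid, "slope"), 0.0)
        assert np.allclose(derive_local(flat_grid, "curvature"), 0.0)
        assert np.allclose(derive_local(flat_grid, "slope_sd"), 0.0)
        assert np.allclose(derive_local(flat_grid, "rugosity"), 1.0)

    def test_inclined_plane_slope_is_analytic(self, plane_grid):
        # interior cells see the full 3x3 window; edge rows use the
        # replicated partial window and are checked only for sanity
        slope = derive_local(plane_grid, "slope")
        expected = np.degrees(np.arctan(0.1))  # 5.71 degrees
        assert np.allclose(slope[1:-1, 1:-1], expected, atol=1e-9)
        assert slope[20, 20] == pytest.approx(5.71, abs=0.01)
        assert ((slope >= 0) & (slope <= expected + 1e-9)).all()

    def test_inclined_plane_has_constant_slope(self, plane_grid):
        interior = np.s_[2:-2, 2:-2]
        assert np.allclose(derive_local(plane_grid, "slope_sd")[interior], 0.0, atol=1e-5)
        assert np.allclose(derive_local(plane_grid, "curvature")[1:-1, 1:-1], 0.0, atol=1e-9)
        # rugosity of a plane = sec(slope)
        rug = derive_local(plane_grid, "rugosity")
        assert np.allclose(
            rug[1:-1, 1:-1], 1.0 / np.cos(np.arctan(0.1)), atol=1e-9
        )

    def test_unknown_metric_and_degenerate_grids_rejected(self, flat_grid):
        with pytest.raises(ValueError, match="unknown metric"):
            derive_local(flat_grid, "tpi")
        with pytest.raises(ValueError, match="3x3"):
            derive_local(DepthGrid(values=np.ones((2, 5))), "slope")
        with pytest.raises(ValueError, match="all-nodata"):
            derive_local(DepthGrid(values=np.full((5, 5), np.nan)), "slope")

    def test_nodata_propagates_without_spreading_everywhere(self, flat_grid):
        v = flat_grid.values.copy()
        v[10, 10] = np.nan
        slope = derive_local(flat_grid.with_values(v), "slope")
        assert np.isnan(slope[10, 10])
        assert np.isfinite(slope[0, 0])

    def test_rugosity_floor_and_slope_range_on_rough_terrain(self):
        rng = np.random.default_rng(7)
        g = DepthGrid(values=50 + 5 * rng.standard_normal((30, 30)), cell=10.0)
        slope = derive_local(g, "slope")
        assert ((slope >= 0) & (slope < 90)).all()
        assert (derive_local(g, "rugosity") >= 1.0).all()
        assert (derive_local(g, "slope_sd") >= 0.0).all()

    def test_coarsening_smooths_slope(self):
        # deriving slope after 5x block-mean aggregation yields lower
        # mean slope than deriving at the fine scale on rough terrain
        rng = np.random.default_rng(11)
        fine = DepthGrid(values=50 + 8 * rng.standard_normal((100, 100)), cell=10.0)
        coarse = block_mean(fine, 5)
        assert derive_local(coarse, "slope").mean() < derive_local(fine, "slope").mean()


class TestBpi:
    def test_flat_grid_is_identically_zero(self, flat_grid):
        assert np.allclose(bpi(flat_grid, BpiSpec(0, 3, "fine")), 0.0, atol=1e-9)

    def test_single_shoal_against_brute_force_annulus(self):
        v = np.full((21, 21), 40.0)
        v[10, 10] = 30.0  # 10 m shoal
        g = DepthGrid(values=v, cell=10.0)
        spec = BpiSpec(0, 3, "fine")
        out = bpi(g, spec)
        # brute-force annulus mean at the shoal cell
        acc, cnt = 0.0, 0
        for r in range(21):
            for c in range(21):
                d = np.hypot(r - 10, c - 10)
                if 0 < d <= 3:
                    acc += v[r, c]
                    cnt += 1
        expected = acc / cnt - v[10, 10]
        assert out[10, 10] == pytest.approx(expected, abs=1e-9)
        assert out[10, 10] > 0  # crest is positive

    def test_sign_flip_negates(self):
        rng = np.random.default_rng(3)
        v = 50 + 5 * rng.standard_normal((30, 30))
        spec = BpiSpec(1, 4, "fine")
        a = bpi(DepthGrid(values=v, cell=10.0), spec)
        b = bpi(DepthGrid(values=-v, cell=10.0), spec)
        assert np.allclose(a, -b, atol=1e-9)

    def test_invalid_radii_rejected(self, flat_grid):
        with pytest.raises(ValueError):
            BpiSpec(3, 3, "x")
        with pytest.raises(ValueError, match="outer radius"):
            bpi(flat_grid, BpiSpec(0, 60, "x"))


class TestFetch:
    def test_open_ocean_cell_saturates_at_bearings_times_cap(self):
        g = DepthGrid(values=np.full((30, 30), 50.0), cell=100.0)
        spec = FetchSpec(bearings=16, cap=1000.0)
        out = fetch_sum(g, spec)
        assert out[15, 15] == pytest.approx(16 * 1000.0)

    def test_circular_basin_matches_ray_oracle_within_discretization(self):
        n, cell, radius = 61, 10.0, 250.0
        rr, cc = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
        dist = np.hypot(rr - n // 2, cc - n // 2) * cell
        v = np.where(dist <= radius, 30.0, -5.0)  # basin ringed by land
        g = DepthGrid(values=v, cell=cell)
        spec = FetchSpec(bearings=32, cap=5000.0)
        out = fetch_sum(g, spec)
        center = out[n // 2, n // 2]
        assert center == pytest.approx(32 * radius, rel=0.10)

    def test_first_hit_semantics_ignore_a_farther_coast(self):
        n, cell, radius = 61, 10.0, 200.0
        rr, cc = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
        dist = np.hypot(rr - n // 2, cc - n // 2) * cell
        basin = np.where(dist <= radius, 30.0, -5.0)
        # second, farther coast: land beyond 280 m is already behind
        # the first ring, so it must change nothing
        ringed = basin.copy()
        ringed[dist > 280.0] = -20.0
        spec = FetchSpec(bearings=16, cap=2000.0)
        a = fetch_sum(DepthGrid(values=basin, cell=cell), spec)
        b = fetch_sum(DepthGrid(values=ringed, cell=cell), spec)
        marine = basin > 0
        assert np.allclose(a[marine], b[marine])

    def test_land_is_nodata_and_all_land_rejected(self):
        v = np.full((20, 20), 30.0)
        v[0, :] = -2.0
        out = fetch_sum(DepthGrid(values=v, cell=50.0), FetchSpec(bearings=8, cap=500.0))
        assert np.isnan(out[0]).all()
        with pytest.raises(ValueError, match="no marine"):
            fetch_sum(DepthGrid(values=-np.ones((20, 20))), FetchSpec())


class TestResample:
    def _coarse(self, values):
        return DepthGrid(values=values, x0=0.0, y0=400.0, cell=100.0)

    def _target(self):
        return DepthGrid(values=np.full((20, 20), 10.0), x0=0.0, y0=400.0, cell=20.0)

    def test_constant_field_preserved(self):
        out = resample_energy(self._coarse(np.full((4, 4), 3.25)), self._target())
        assert np.allclose(out, 3.25)

    def test_coinciding_centers_take_coarse_values(self):
        coarse = self._coarse(np.arange(16, dtype=float).reshape(4, 4))
        target = self._target()
        out = resample_energy(coarse, target)
        # target cell (2, 2) center = (50, 350) = coarse cell (0, 0) center
        assert out[2, 2] == pytest.approx(coarse.values[0, 0])
        assert out[7, 7] == pytest.approx(coarse.values[1, 1])

    def test_linear_ramp_reproduced_exactly(self):
        rr, cc = np.meshgrid(np.arange(4), np.arange(4), indexing="ij")
        coarse = self._coarse(2.0 * rr + 3.0 * cc + 1.0)
        out = resample_energy(coarse, self._target())
        # interior target centers: bilinear reproduces linear functions
        rr_t = np.arange(20)[:, None] + 0.5
        cc_t = np.arange(20)[None, :] + 0.5
        expected = 2.0 * (rr_t * 0.2 - 0.5) + 3.0 * (cc_t * 0.2 - 0.5) + 1.0
        interior = np.s_[3:17, 3:17]
        assert np.allclose(out[interior], np.broadcast_to(expected, (20, 20))[interior])

    def test_land_masked_and_disjoint_extents_rejected(self):
        target = self._target()
        v = target.values.copy()
        v[0, 0] = -1.0
        out = resample_energy(self._coarse(np.ones((4, 4))), target.with_values(v))
        assert np.isnan(out[0, 0])
        far = DepthGrid(values=np.ones((4, 4)), x0=1e7, y0=1e7, cell=100.0)
        with pytest.raises(ValueError, match="overlap"):
            resample_energy(far, target)


class TestBuildStack:
    @pytest.fixture
    def shelf(self):
        rows = np.arange(40)[:, None] + 0.5
        v = np.broadcast_to((rows - 6) * 2.0, (40, 40)).copy()
        return DepthGrid(values=v, x0=0.0, y0=400.0, cell=10.0)

    @pytest.fixture
    def energy(self, shelf):
        tide = DepthGrid(values=np.ones((5, 5)), x0=0.0, y0=400.0, cell=100.0)
        circ = DepthGrid(values=0.5 * np.ones((5, 5)), x0=0.0, y0=400.0, cell=100.0)
        return tide, circ

    _bpi = (BpiSpec(0, 3, "fine"), BpiSpec(0, 6, "medium"), BpiSpec(0, 12, "broad"))

    def test_regional_stack_has_eleven_layers_with_fetch(self, shelf, energy):
        tide, circ = energy
        stack = build_stack(
            shelf, tide=tide, circulation=circ, bpi_specs=self._bpi,
            fetch_spec=FetchSpec(bearings=8, cap=400.0), resolution_class="regional",
        )
        assert len(stack.names) == 11
        assert "fetch" in stack

    def test_coastwide_stack_has_ten_layers_without_fetch(self, shelf, energy):
        tide, circ = energy
        stack = build_stack(
            shelf, tide=tide, circulation=circ, bpi_specs=self._bpi,
            resolution_class="coastwide",
        )
        assert len(stack.names) == 10
        assert "fetch" not in stack

    def test_stack_geometry_and_marine_footprint(self, shelf, energy):
        tide, circ = energy
        stack = build_stack(
            shelf, tide=tide, circulation=circ, bpi_specs=self._bpi,
            resolution_class="coastwide",
        )
        assert stack.geometry.same_geometry(shelf)
        land = shelf.land
        for name in stack.names:
            assert np.isnan(stack[name][land]).all(), name
            assert np.isfinite(stack[name][~land]).all(), name
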