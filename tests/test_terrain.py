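"""Terrain covariates: slope, TRI, TPI, HLI, TWI, distances, kernel density."""

import numpy as np
import pytest

from charcoalscape import DemGrid
from charcoalscape.terrain import (
    distance_raster,
    flow_accumulation_d8,
    hli,
    kernel_density,
    slope,
    tpi,
    tri_riley,
    twi,
)


def grid(vals, cell=1.0, **kw):
    return DemGrid(np.asarray(vals, dtype=float), cell_size_m=cell, **kw)


class TestSlope:
    def test_constant_raster_is_flat(self):
        s = slope(grid(np.full((10, 10), 7.0)))
        assert np.allclose(s.values, 0.0)

    @pytest.mark.parametrize("gradient,expected", [(1.0, 45.0), (0.5, 26.565051)])
    def test_inclined_plane(self, gradient, expected):
        vals = np.fromfunction(lambda i, j: gradient * j, (20, 20))
        s = slope(grid(vals))
        assert np.allclose(s.values[2:-2, 2:-2], expected, atol=1e-6)

    def test_matches_central_difference_oracle(self):
        # independent oracle: plain central differences agree with Horn's
        # weighted differences on a smooth separable surface
        i, j = np.mgrid[0:30, 0:30]
        z = 5 * np.sin(j / 7.0) + 3 * np.cos(i / 9.0)
        s = slope(grid(z)).values
        dzdx = (z[1:-1, 2:] - z[1:-1, :-2]) / 2.0
        dzdy = (z[:-2, 1:-1] - z[2:, 1:-1]) / 2.0
        oracle = np.degrees(np.arctan(np.hypot(dzdx, dzdy)))
        assert np.allclose(s[1:-1, 1:-1], oracle, atol=1e-9)

    def test_transpose_consistency(self):
        rng = np.random.default_rng(1)
        z = rng.standard_normal((15, 22))
        a = slope(grid(z)).values
        b = slope(grid(z.T)).values
        assert np.allclose(a, b.T, atol=1e-12)

    def test_nodata_propagates(self):
        z = np.full((8, 8), 5.0)
        z[3, 3] = -9999.0
        s = slope(grid(z, nodata=-9999.0))
        assert s.values[3, 3] == -9999.0
        assert np.allclose(s.values[s.mask()], 0.0)

    def test_too_small_raster_raises(self):
        with pytest.raises(ValueError):
            slope(grid(np.zeros((2, 5))))


class TestIndices:
    def test_constant_gives_zero_tri_and_tpi(self):
        g = grid(np.full((12, 12), 3.0))
        assert np.allclose(tri_riley(g).values, 0.0)
        assert np.allclose(tpi(g, radius_m=3.0).values, 0.0, atol=1e-9)

    def test_tri_single_peak(self):
        z = np.zeros((5, 5))
        z[2, 2] = 1.0
        t = tri_riley(grid(z))
        assert t.values[2, 2] == pytest.approx(np.sqrt(8.0))

    def test_tpi_sums_to_zero_on_periodic_surface(self):
        i, j = np.mgrid[0:40, 0:40]
        z = np.sin(2 * np.pi * i / 10) + np.cos(2 * np.pi * j / 8)
        t = tpi(grid(z), radius_m=4.0)
        # average over whole periods (2 x 10 rows, 3 x 8 cols), away from edges
        interior = t.values[8:28, 8:32]
        assert abs(interior.mean()) < 1e-6

    def test_hli_flat_cell_closed_form(self):
        lat = 45.67
        h = hli(grid(np.full((6, 6), 100.0)), latitude_deg=lat, equation=3)
        expected = 0.339 + 0.808 * np.cos(np.radians(lat))
        assert np.allclose(h.values, expected, atol=1e-9)

    def test_hli_requires_latitude(self):
        with pytest.raises(ValueError):
            hli(grid(np.zeros((5, 5))))

    def test_hli_southwest_warmer_than_northeast(self):
        # same slope angle, opposite exposure: the SW-facing plane must score
        # a higher heat load than the NE-facing one (aspect folded about 225)
        base = DemGrid(np.zeros((20, 20)), cell_size_m=1.0, origin_xy=(0.0, 20.0))
        x, y = base.cell_centers()
        sw_facing = base.like(0.3 * (x + y))    # downslope azimuth 225
        ne_facing = base.like(-0.3 * (x + y))   # downslope azimuth 45
        h_sw = hli(sw_facing, latitude_deg=45.0).values[10, 10]
        h_ne = hli(ne_facing, latitude_deg=45.0).values[10, 10]
        assert h_sw > h_ne

    def test_twi_accumulates_downslope_on_a_ramp(self):
        vals = np.fromfunction(lambda i, j: -0.2 * j, (12, 16))
        g = grid(vals)
        acc = flow_accumulation_d8(g)
        # every cell drains straight east: accumulation = column index + 1
        assert np.array_equal(acc[5], np.arange(1, 17))
        w = twi(g)
        # wetter downslope (interior columns; the outermost columns feel the
        # reflect padding of the slope estimate)
        assert np.all(np.diff(w.values[5][1:-1]) > 0)


class TestProximity:
    def test_distance_zero_at_coincident_cell(self):
        g = DemGrid(np.zeros((10, 10)), cell_size_m=1.0, origin_xy=(0.0, 10.0))
        # cell (0,0) centre is (0.5, 9.5)
        d = distance_raster(np.array([[0.5, 9.5]]), g)
        assert d.values[0, 0] == pytest.approx(0.0)

    def test_three_four_five(self):
        g = DemGrid(np.zeros((12, 12)), cell_size_m=1.0, origin_xy=(-0.5, 11.5))
        d = distance_raster(np.array([[0.0, 0.0]]), g)
        r, c = g.rowcol_of(3.0, 4.0)
        assert d.values[int(r), int(c)] == pytest.approx(5.0)

    def test_empty_features_raise(self):
        g = DemGrid(np.zeros((5, 5)))
        with pytest.raises(ValueError):
            distance_raster(np.empty((0, 2)), g)

    def test_distance_lipschitz(self):
        # |d(a) - d(b)| <= |a - b| for cells sharing the metric plane
        rng = np.random.default_rng(2)
        pts = rng.uniform(0, 20, size=(5, 2))
        g = DemGrid(np.zeros((20, 20)), cell_size_m=1.0, origin_xy=(0.0, 20.0))
        d = distance_raster(pts, g).values
        assert np.all(np.abs(np.diff(d, axis=1)) <= 1.0 + 1e-9)
        assert np.all(np.abs(np.diff(d, axis=0)) <= 1.0 + 1e-9)

    def test_kernel_density_integrates_to_point_count(self):
        rng = np.random.default_rng(3)
        pts = rng.uniform(80, 120, size=(10, 2))
        g = DemGrid(np.zeros((200, 200)), cell_size_m=1.0, origin_xy=(0.0, 200.0))
        dens = kernel_density(pts, g, bandwidth_m=5.0)
        total = dens.values.sum() * g.cell_size_m**2
        assert total == pytest.approx(10.0, rel=0.01)
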