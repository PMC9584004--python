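"""Species proportions, IDW interpolation and the Brillouin index."""

import itertools

import numpy as np
import pandas as pd
import pytest

from charcoalscape import DemGrid
from charcoalscape.composition import (
    brillouin,
    brillouin_from_basal_area,
    change_map,
    idw_accuracy,
    idw_surface,
    idw_surfaces,
    to_proportions,
)


class TestProportions:
    def test_counts(self):
        t = pd.DataFrame({"unit_id": [1], "x": [0.0], "y": [0.0], "A": [3], "B": [1]})
        out = to_proportions(t)
        assert out.loc[0, "A"] == 0.75 and out.loc[0, "B"] == 0.25

    def test_basal_areas_with_zero(self):
        t = pd.DataFrame({"A": [10.0], "B": [10.0], "C": [0.0]})
        out = to_proportions(t)
        assert list(out.iloc[0]) == [0.5, 0.5, 0.0]

    def test_zero_total_rows_dropped_with_warning(self):
        t = pd.DataFrame({"A": [1, 0], "B": [1, 0]})
        with pytest.warns(UserWarning):
            out = to_proportions(t)
        assert len(out) == 1

    def test_rows_sum_to_one(self):
        rng = np.random.default_rng(0)
        t = pd.DataFrame(rng.integers(0, 9, size=(30, 4)) + 0.0,
                         columns=list("ABCD"))
        t = t[t.sum(axis=1) > 0]
        out = to_proportions(t)
        assert np.allclose(out.sum(axis=1), 1.0, atol=1e-9)


def _grid(n=20, cell=1.0):
    return DemGrid(np.zeros((n, n)), cell_size_m=cell, origin_xy=(0.0, n * cell))


class TestIdw:
    def test_exact_interpolator_at_sample(self):
        g = _grid(10)
        # sample exactly on a cell centre
        pts = np.array([[3.5, 6.5], [8.5, 1.5]])
        surf = idw_surface(pts, np.array([2.0, 9.0]), g)
        r, c = g.rowcol_of(3.5, 6.5)
        assert surf.values[int(r), int(c)] == pytest.approx(2.0)

    def test_symmetric_pair_averages(self):
        g = DemGrid(np.zeros((1, 1)), cell_size_m=1.0, origin_xy=(-0.5, 0.5))
        # cell centre (0,0); points at x = -3 and +3 with values 0 and 1
        surf = idw_surface(np.array([[-3.0, 0.0], [3.0, 0.0]]), np.array([0.0, 1.0]), g)
        assert surf.values[0, 0] == pytest.approx(0.5)

    def test_hand_computed_weights(self):
        g = DemGrid(np.zeros((1, 1)), cell_size_m=1.0, origin_xy=(-0.5, 0.5))
        # distances 1 and 2, power 2: (1*10 + 0.25*40) / 1.25 = 16
        surf = idw_surface(np.array([[1.0, 0.0], [-2.0, 0.0]]),
                           np.array([10.0, 40.0]), g, power=2.0)
        assert surf.values[0, 0] == pytest.approx(16.0)

    def test_empty_input_raises(self):
        with pytest.raises(ValueError):
            idw_surface(np.empty((0, 2)), np.empty(0), _grid(5))

    def test_never_extrapolates_beyond_sample_range(self):
        rng = np.random.default_rng(1)
        pts = rng.uniform(0, 20, size=(15, 2))
        vals = rng.uniform(0.2, 0.8, 15)
        surf = idw_surface(pts, vals, _grid(20))
        assert surf.values.min() >= vals.min() - 1e-12
        assert surf.values.max() <= vals.max() + 1e-12

    def test_proportion_surfaces_close_to_one(self):
        rng = np.random.default_rng(2)
        pts = rng.uniform(0, 20, size=(12, 2))
        counts = rng.integers(1, 6, size=(12, 3)).astype(float)
        props = counts / counts.sum(axis=1, keepdims=True)
        surfaces = idw_surfaces(pts, props, _grid(20), n_neighbours=8)
        total = sum(s.values for s in surfaces)
        assert np.allclose(total, 1.0, atol=1e-6)


class TestIdwAccuracy:
    def test_constant_values_zero_error(self):
        pts = np.array([[0.0, 0.0], [5.0, 0.0], [0.0, 5.0]])
        acc = idw_accuracy(pts, np.array([4.0, 4.0, 4.0]))
        assert acc["ME"] == acc["MAE"] == acc["RMSE"] == 0.0

    def test_hand_computed_loo_errors(self):
        # collinear points 0,1,2 with values 0,1,0:
        # LOO predictions 0.8, 0.0, 0.8 -> errors +0.8, -1.0, +0.8
        pts = np.array([[0.0, 0.0], [1.0, 0.0], [2.0, 0.0]])
        acc = idw_accuracy(pts, np.array([0.0, 1.0, 0.0]), power=2.0)
        assert acc["ME"] == pytest.approx(0.2)
        assert acc["MAE"] == pytest.approx(2.6 / 3)
        assert acc["RMSE"] == pytest.approx(np.sqrt((0.64 + 1 + 0.64) / 3))

    def test_mae_never_exceeds_rmse(self):
        rng = np.random.default_rng(3)
        for _ in range(5):
            pts = rng.uniform(0, 10, size=(12, 2))
            vals = rng.uniform(0, 1, 12)
            acc = idw_accuracy(pts, vals)
            assert acc["MAE"] <= acc["RMSE"] + 1e-12

    def test_too_few_points_raise(self):
        with pytest.raises(ValueError):
            idw_accuracy(np.array([[0.0, 0.0], [1.0, 1.0]]), np.array([1.0, 2.0]))


class TestChangeMap:
    def test_identical_inputs_give_zero(self):
        g = _grid(5)
        a = g.like(np.full((5, 5), 0.4))
        assert np.allclose(change_map(a, a).values, 0.0)

    def test_simple_difference(self):
        g = _grid(3)
        cur = g.like(np.full((3, 3), 1.0))
        hist = g.like(np.full((3, 3), 0.25))
        assert np.allclose(change_map(cur, hist).values, 0.75)

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError):
            change_map(_grid(4), _grid(5))


class TestBrillouin:
    def test_single_species_is_zero(self):
        assert brillouin([7]) == 0.0
        assert brillouin([0, 12, 0]) == 0.0

    def test_two_by_two(self):
        expected = (np.log(24) - 2 * np.log(2)) / 4
        assert brillouin([2, 2]) == pytest.approx(expected)

    def test_even_composition_maximises_index(self):
        # brute force over all integer compositions of N into k parts
        for total in (6, 9, 12):
            for k in (2, 3):
                best = max(
                    (brillouin(c), c)
                    for c in itertools.product(range(total + 1), repeat=k)
                    if sum(c) == total
                )[1]
                counts = sorted(best)
                assert max(counts) - min(counts) <= 1

    def test_bounded_by_shannon_and_converges(self):
        p = np.array([0.5, 0.3, 0.2])
        shannon = -np.sum(p * np.log(p))
        for n in (10, 100, 10000):
            counts = np.round(p * n).astype(int)
            h = brillouin(counts)
            assert h <= shannon + 1e-12
        assert abs(h - shannon) < 0.01  # N = 10000

    def test_non_integer_raises(self):
        with pytest.raises(ValueError):
            brillouin([1.5, 2.0])

    def test_basal_area_conversion(self):
        assert brillouin_from_basal_area([10.0, 10.0], scale=10.0) == pytest.approx(
            brillouin([100, 100])
        )
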