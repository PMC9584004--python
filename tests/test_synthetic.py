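"""Synthetic landscape, charcoal and forest-plot generators."""

import numpy as np
import pandas as pd
import pytest
from scipy import ndimage

from charcoalscape import slope
from charcoalscape.ordination import permutation_test, rda
from charcoalscape.synthetic import (
    DEFAULT_TAXON_PROBS,
    PlacementError,
    TerrainScenario,
    generate_charcoal_samples,
    generate_dtm,
    generate_forest_plots,
)


class TestGenerateDtm:
    def test_noise_free_ramp_is_a_plane(self):
        sc = TerrainScenario(extent_m=(60.0, 60.0), n_platforms=0, n_confusers=0,
                             relief_amplitude_m=0.0, base_slope_deg=20.0, seed=0)
        dem, truths = generate_dtm(sc)
        assert truths == []
        s = slope(dem)
        assert np.allclose(s.values[5:-5, 5:-5], 20.0, atol=1e-6)

    def test_platform_flat_inside_steep_lip(self):
        sc = TerrainScenario(extent_m=(80.0, 80.0), n_platforms=1, n_confusers=0,
                             platform_area_range_m2=(63.0, 63.0),
                             base_slope_deg=25.0, seed=1)
        dem, truths = generate_dtm(sc)
        (t,) = truths
        s = slope(dem).values
        footprint = t.footprint_mask(dem.shape)
        interior = ndimage.binary_erosion(footprint, iterations=2)
        assert s[interior].max() < 3.0
        wpx = int(np.ceil(t.lip_width_m / dem.cell_size_m))
        lip = ndimage.binary_dilation(footprint, iterations=wpx) & ~footprint
        # the cut/fill sectors of the lip are steeper than the hillslope
        assert np.percentile(s[lip], 75) > 25.0

    def test_footprint_area_matches_analytic_within_15pct(self, small_scene):
        for t in small_scene["truths"]:
            assert t.footprint_area_m2 == pytest.approx(t.area_m2, rel=0.15)

    def test_deterministic_bit_identical(self):
        sc = TerrainScenario(extent_m=(100.0, 100.0), n_platforms=3,
                             n_confusers=5, seed=9)
        dem1, t1 = generate_dtm(sc)
        dem2, t2 = generate_dtm(sc)
        assert np.array_equal(dem1.values, dem2.values)
        assert [t.centroid_xy for t in t1] == [t.centroid_xy for t in t2]

    def test_platforms_do_not_overlap(self, small_scene):
        shape = small_scene["dem"].shape
        total = np.zeros(shape, dtype=int)
        for t in small_scene["truths"]:
            total += t.footprint_mask(shape)
        assert total.max() == 1

    def test_impossible_placement_reports_count(self):
        sc = TerrainScenario(extent_m=(60.0, 60.0), n_platforms=200,
                             n_confusers=0, seed=2)
        with pytest.raises(PlacementError) as err:
            generate_dtm(sc)
        assert 0 <= err.value.placed < 200

    def test_invalid_scenarios_raise(self):
        with pytest.raises(ValueError):
            TerrainScenario(cell_size_m=0.0).validate()
        with pytest.raises(ValueError):
            TerrainScenario(platform_area_range_m2=(170.0, 20.0)).validate()


class TestCharcoalSamples:
    def _truths(self, n=125, seed=0):
        rng = np.random.default_rng(seed)
        from charcoalscape.synthetic import RchTruth

        return [
            RchTruth(id=i + 1, centroid_xy=tuple(rng.uniform(0, 500, 2)),
                     area_m2=60.0, ellipse_axes_m=(4.0, 4.0), theta_rad=0.0,
                     lip_width_m=1.5, rows=np.array([0]), cols=np.array([0]))
            for i in range(n)
        ]

    def test_degenerate_single_taxon(self):
        table = generate_charcoal_samples(self._truths(10), {"A": 1.0}, seed=0)
        assert (table["A"] >= 2).all()

    def test_row_totals_in_fragment_range(self):
        table = generate_charcoal_samples(self._truths(60), seed=1)
        taxa = list(DEFAULT_TAXON_PROBS)
        totals = table[taxa].sum(axis=1)
        assert totals.between(2, 6).all()

    def test_pooled_proportions_recover_probabilities(self):
        table = generate_charcoal_samples(self._truths(125), seed=2)
        taxa = list(DEFAULT_TAXON_PROBS)
        pooled = table[taxa].sum()
        n = pooled.sum()
        for taxon, p in DEFAULT_TAXON_PROBS.items():
            se = np.sqrt(p * (1 - p) / n)
            assert abs(pooled[taxon] / n - p) <= 3 * se + 1e-12

    def test_law_of_large_numbers(self):
        # ~10 000 fragments: proportions converge to the probabilities
        truths = self._truths(2500, seed=3)
        table = generate_charcoal_samples(truths, seed=3)
        taxa = list(DEFAULT_TAXON_PROBS)
        pooled = table[taxa].sum()
        props = pooled / pooled.sum()
        for taxon, p in DEFAULT_TAXON_PROBS.items():
            assert abs(props[taxon] - p) < 0.02

    def test_invalid_probabilities_raise(self):
        with pytest.raises(ValueError):
            generate_charcoal_samples(self._truths(5), {"A": 0.6, "B": 0.3})
        with pytest.raises(ValueError):
            generate_charcoal_samples(self._truths(5), {"A": 1.5, "B": -0.5})
        with pytest.raises(ValueError):
            generate_charcoal_samples(self._truths(5), {"A": 1.0}, frags_per_rch=(0, 3))


class TestForestPlots:
    def test_default_shapes_match_study_design(self):
        data = generate_forest_plots(267, seed=0)
        assert data.env_matrix.shape == (267, 15)
        assert data.response_matrix.shape == (267, 11)
        assert data.coef.shape == (15, 11)

    def test_deterministic(self):
        a = generate_forest_plots(50, seed=4)
        b = generate_forest_plots(50, seed=4)
        pd.testing.assert_frame_equal(a.plots, b.plots)
        pd.testing.assert_frame_equal(a.env, b.env)

    def test_noiseless_single_gradient_fully_explained(self):
        rng = np.random.default_rng(5)
        env = rng.standard_normal((40, 1))
        model = {"env": env, "coef": np.array([[2.0]]), "noise_sd": 0.0,
                 "env_names": ["elev"], "response_names": ["ba"]}
        data = generate_forest_plots(40, env_model=model, seed=5)
        res = rda(data.response_matrix, data.env_matrix,
                  standardise_y=False, standardise_x=False)
        assert res.explained_pct[0] == pytest.approx(100.0, abs=1e-6)

    def test_null_responses_give_uniform_p(self):
        # responses independent of predictors: rejection rate ~ alpha
        rejections = 0
        reps = 200
        for i in range(reps):
            model = {"coef": np.zeros((15, 11)), "noise_sd": 1.0}
            data = generate_forest_plots(30, env_model=model, seed=1000 + i)
            p = permutation_test(data.response_matrix, data.env_matrix.iloc[:, :3],
                                 n_perm=99, seed=i)
            rejections += p <= 0.05
        rate = rejections / reps
        assert 0.01 <= rate <= 0.10

    def test_zero_variance_predictor_raises(self):
        env = np.ones((30, 2))
        env[:, 1] = np.arange(30)
        model = {"env": env, "env_names": ["a", "b"]}
        with pytest.raises(ValueError, match="a"):
            generate_forest_plots(30, env_model=model, seed=6)

    def test_too_few_plots_raise(self):
        with pytest.raises(ValueError):
            generate_forest_plots(5)
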