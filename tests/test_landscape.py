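"""Synthetic landscape generators: determinism, correlation structure,
truth surfaces, sampling and trait-catalog imperfections."""

import numpy as np
import pytest

import leaftypes as lt
from leaftypes.landscape import smoothed_field


def test_covariate_grid_deterministic():
    cfg = lt.LandscapeConfig(rows=16, cols=16, seed=1)
    g1 = lt.generate_covariate_grid(cfg)
    g2 = lt.generate_covariate_grid(cfg)
    assert np.array_equal(g1.values, g2.values)
    assert g1.names == g2.names


def test_covariate_layers_standardized(landscape):
    _, grid, _ = landscape
    means = grid.values.mean(axis=(1, 2))
    sds = grid.values.std(axis=(1, 2))
    assert np.allclose(means, 0, atol=1e-10)
    assert np.allclose(sds, 1, atol=1e-10)


def test_zero_between_group_correlation_bound():
    """With rho_b = 0, cross-group layer correlations stay near zero."""
    cfg = lt.LandscapeConfig(rows=100, cols=100, correlation_length=1.5,
                             between_group_correlation=0.0, seed=7)
    grid = lt.generate_covariate_grid(cfg)
    flat = grid.values.reshape(len(grid.names), -1)
    corr = np.corrcoef(flat)
    cross = []
    for i, ni in enumerate(grid.names):
        for j in range(i + 1, len(grid.names)):
            if grid.groups[ni] != grid.groups[grid.names[j]]:
                cross.append(abs(corr[i, j]))
    assert np.mean(cross) < 0.1


def test_within_group_correlation_exceeds_cross_group():
    cfg = lt.LandscapeConfig(rows=100, cols=100, correlation_length=1.5,
                             between_group_correlation=0.2, seed=3)
    grid = lt.generate_covariate_grid(cfg)
    flat = grid.values.reshape(len(grid.names), -1)
    corr = np.corrcoef(flat)
    within, cross = [], []
    for i, ni in enumerate(grid.names):
        for j in range(i + 1, len(grid.names)):
            (within if grid.groups[ni] == grid.groups[grid.names[j]] else cross).append(corr[i, j])
    assert np.mean(within) > np.mean(cross) + 0.2


def test_long_correlation_length_flattens_field():
    """Smoothing at a scale much larger than the grid shrinks variance far
    below the unit white-noise sd (smoothing oracle)."""
    rng = np.random.default_rng(5)
    field = smoothed_field(rng, (32, 32), length=100.0)
    assert field.std() < 0.1  # raw noise sd is 1


def test_invalid_config_rejected():
    with pytest.raises(ValueError):
        lt.LandscapeConfig(rows=4, cols=16)
    with pytest.raises(ValueError):
        lt.LandscapeConfig(correlation_length=0)
    with pytest.raises(ValueError):
        lt.LandscapeConfig(between_group_correlation=1.5)


class TestTrueComposition:
    def test_zero_coefficients_give_uniform(self, landscape):
        _, grid, _ = landscape
        resp = lt.ResponseConfig(drivers={"climate_00": ("form", 0.0),
                                          "climate_01": ("habit", 0.0)})
        comp = lt.generate_true_composition(grid, resp)
        assert np.allclose(comp, 0.25)

    def test_extreme_form_coefficient_saturates_broadleaf(self, landscape):
        _, grid, _ = landscape
        resp = lt.ResponseConfig(drivers={"climate_00": ("form", 500.0),
                                          "climate_01": ("habit", 0.0)})
        comp = lt.generate_true_composition(grid, resp)
        pos = grid.layer("climate_00") > 0.5
        broadleaf = comp[0] + comp[1]
        assert np.all(broadleaf[pos] > 1 - 1e-9)

    def test_pixels_sum_to_one(self, landscape):
        _, grid, truth = landscape
        assert np.abs(truth.sum(axis=0) - 1).max() < 1e-12

    def test_margins_separate_drivers(self, landscape):
        """Habit drivers move only the evergreen margin, form drivers only
        the broadleaf margin."""
        _, grid, _ = landscape
        base = lt.ResponseConfig(drivers={"climate_00": ("form", 1.0),
                                          "soil_00": ("habit", 1.0)})
        bumped = lt.ResponseConfig(drivers={"climate_00": ("form", 1.0),
                                            "soil_00": ("habit", 2.0)})
        c0 = lt.generate_true_composition(grid, base)
        c1 = lt.generate_true_composition(grid, bumped)
        broad0 = c0[0] + c0[1]
        broad1 = c1[0] + c1[1]
        assert np.allclose(broad0, broad1, atol=1e-12)
        assert not np.allclose(c0[0] + c0[2], c1[0] + c1[2])

    def test_unknown_driver_layer_rejected(self, landscape):
        _, grid, _ = landscape
        resp = lt.ResponseConfig(drivers={"nope": ("form", 1.0), "soil_00": ("habit", 1.0)})
        with pytest.raises(ValueError, match="nope"):
            lt.generate_true_composition(grid, resp)


class TestSamplePlots:
    def test_degenerate_composition_gives_single_type(self, landscape, pools, clean_catalog):
        _, grid, _ = landscape
        comp = np.zeros((4,) + grid.shape)
        comp[0] = 1.0  # pure BE everywhere
        plots = lt.sample_plots(grid, comp, 5, seed=1, pools=pools)
        for p in plots:
            for t in p.trees:
                assert lt.resolve_leaf_type(t, clean_catalog) == "BE"

    def test_frequencies_match_composition_within_3sd(self, landscape, pools, clean_catalog):
        """Binomial oracle: at n = 10^4 trees the empirical type counts sit
        within 3 binomial SDs of the pixel composition."""
        _, grid, _ = landscape
        target = np.array([0.5, 0.3, 0.15, 0.05])
        comp = np.broadcast_to(target[:, None, None], (4,) + grid.shape).copy()
        n = 10_000
        plots = lt.sample_plots(grid, comp, 1, trees_per_plot=lambda rng: n, seed=9, pools=pools)
        counts = np.zeros(4)
        for t in plots[0].trees:
            counts[lt.LEAF_TYPE_INDEX[lt.resolve_leaf_type(t, clean_catalog)]] += 1
        sd = np.sqrt(n * target * (1 - target))
        assert np.all(np.abs(counts - n * target) <= 3 * sd)

    def test_dbh_truncated_at_10(self, sampled_plots):
        for p in sampled_plots:
            assert all(t.dbh_cm >= 10 for t in p.trees)

    def test_min_trees_and_determinism(self, landscape, pools):
        _, grid, truth = landscape
        p1 = lt.sample_plots(grid, truth, 10, seed=3, pools=pools)
        p2 = lt.sample_plots(grid, truth, 10, seed=3, pools=pools)
        assert all(len(p.trees) >= 10 for p in p1)
        assert [p.trees for p in p1] == [p.trees for p in p2]

    def test_biome_labels_valid(self, sampled_plots):
        assert {p.biome for p in sampled_plots} <= set(lt.BIOMES)


class TestTraitCatalog:
    def test_perfect_catalog_reproduces_truth(self, pools, clean_catalog):
        for leaf_type, species in pools.items():
            for sp in species:
                entry = clean_catalog.lookup(sp)
                assert entry is not None and entry.leaf_type == leaf_type

    def test_rates_of_one_rejected(self, pools):
        with pytest.raises(ValueError):
            lt.generate_trait_catalog(pools, missing_rate=1.0)

    def test_conflicting_observations_keep_strict_majority(self, pools):
        cat = lt.generate_trait_catalog(pools, conflict_rate=0.9, seed=2)
        conflicted = [e for e in cat.entries.values()
                      if e.rank == "species" and len(set(e.habit_observations)) > 1]
        assert conflicted, "a high conflict rate must create conflicted entries"
        for e in conflicted:
            assert lt.majority_trait(e.habit_observations) == e.habit

    def test_missing_species_fall_back_to_genus(self, pools):
        cat = lt.generate_trait_catalog(pools, missing_rate=0.5, seed=4)
        for leaf_type, species in pools.items():
            for sp in species:
                tree = lt.TreeRecord(species=sp, genus=sp.split()[0], dbh_cm=20)
                assert lt.resolve_leaf_type(tree, cat) == leaf_type


class TestFutureClimate:
    def test_zero_shift_is_identity(self, landscape):
        _, grid, _ = landscape
        fut = lt.generate_future_climate(grid, {n: 0.0 for n in grid.layers_in_group("climate")})
        assert np.array_equal(fut.values, grid.values)

    def test_warming_offset_raises_means(self, landscape):
        _, grid, _ = landscape
        fut = lt.generate_future_climate(grid, {"climate_00": 1.0})
        assert np.isclose(fut.layer("climate_00").mean() - grid.layer("climate_00").mean(), 1.0)

    def test_non_climate_layers_bitwise_equal(self, landscape):
        _, grid, _ = landscape
        fut = lt.generate_future_climate(grid, {n: 2.0 for n in grid.layers_in_group("climate")})
        for name in grid.names:
            if grid.groups[name] != "climate":
                assert np.array_equal(fut.layer(name), grid.layer(name))

    def test_offset_on_soil_layer_rejected(self, landscape):
        _, grid, _ = landscape
        with pytest.raises(ValueError, match="soil_00"):
            lt.generate_future_climate(grid, {"soil_00": 1.0})
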