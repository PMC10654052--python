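import numpy as np
import pytest

import leaftypes as lt


@pytest.fixture(scope="session")
def landscape():
    """A small deterministic landscape shared across tests."""
    cfg = lt.LandscapeConfig(rows=16, cols=16, seed=11)
    grid = lt.generate_covariate_grid(cfg)
    truth = lt.generate_true_composition(grid, lt.ResponseConfig())
    return cfg, grid, truth


@pytest.fixture(scope="session")
def pools():
    return lt.species_pools()


@pytest.fixture(scope="session")
def clean_catalog(pools):
    """Perfect trait catalog: no missing species, no conflicts."""
    return lt.generate_trait_catalog(pools, missing_rate=0.0, conflict_rate=0.0, seed=0)


@pytest.fixture(scope="session")
def sampled_plots(landscape, pools, clean_catalog):
    _, grid, truth = landscape
    plots = lt.sample_plots(grid, truth, n_plots=60, seed=21, pools=pools)
    return lt.filter_inventory(plots, clean_catalog)


def make_plot(types_dbh, plot_id="p0", lat=0.0, lon=0.0, biome="tropical", year=2005,
              pools=None):
    """Build a plot from (leaf_type, dbh) pairs using the synthetic pools."""
    pools = pools or lt.species_pools()
    counters = {t: 0 for t in lt.LEAF_TYPES}
    trees = []
    for t, dbh in types_dbh:
        sp = pools[t][counters[t] % len(pools[t])]
        counters[t] += 1
        trees.append(lt.TreeRecord(species=sp, genus=sp.split()[0], dbh_cm=dbh))
    return lt.InventoryPlot(id=plot_id, lat=lat, lon=lon, biome=biome, year=year,
                            trees=tuple(trees))
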