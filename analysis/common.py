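"""Shared world definition for the numbered analysis scripts.

Every script rebuilds what it needs deterministically from SEED, so the
steps can be run independently (or in order, sharing the files under
results/analysis/). Scale is desk-sized; raise SIZES for slower, tighter
runs.
"""

from pathlib import Path

import numpy as np

import leaftypes as lt

SEED = 20240901
OUT = Path(__file__).resolve().parents[1] / "results" / "analysis"

# 48 x 48 pixels at correlation length 2.5 gives each smoothed field enough
# independent spatial patches that 21 predictors are not collinear by
# construction (the VIF screen is meaningful, as on real ~1 km global grids)
LANDSCAPE = dict(rows=48, cols=48, correlation_length=2.5, between_group_correlation=0.3)
N_PLOTS = 500
N_DRAWS = 10
PER_PLOT = 10
MODE = "area"
PARAMS = lt.Hyperparameters(n_trees=100, mtry=4, min_node=5)


def build_world():
    """Landscape, truth, filtered plots and trait catalog for SEED."""
    cfg = lt.LandscapeConfig(seed=SEED, **LANDSCAPE)
    grid = lt.generate_covariate_grid(cfg)
    truth = lt.generate_true_composition(grid, lt.ResponseConfig())
    pools = lt.species_pools()
    catalog = lt.generate_trait_catalog(pools, missing_rate=0.1, conflict_rate=0.1,
                                        seed=SEED + 1)
    plots = lt.sample_plots(grid, truth, N_PLOTS, seed=SEED + 2, pools=pools)
    plots = lt.filter_inventory(plots, catalog)
    return cfg, grid, truth, plots, catalog


def fit_model(grid, plots, catalog):
    training = lt.build_training_sets(plots, catalog, grid, n_draws=N_DRAWS,
                                      per_plot=PER_PLOT, mode=MODE, seed=SEED + 3)
    model = lt.train_ensemble(training, PARAMS, seed=SEED + 4)
    model.mode = MODE
    return model


def observed_compositions(plots, catalog, mode=MODE):
    return np.array([lt.plot_composition(p, catalog, mode) for p in plots])
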