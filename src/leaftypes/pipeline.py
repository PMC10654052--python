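"""End-to-end pipeline runner with a reproducibility manifest.

Stages (simulate, fit, evaluate, importance, account, risk) are executed
in dependency order on one landscape; every output file is hashed into a
JSON manifest together with the per-stage seeds, so a rerun with the
same configuration reproduces identical hashes for the deterministic
stages. The numbered scripts under ``analysis/`` drive the same stage
functions individually.
"""

from __future__ import annotations

import hashlib
import json
import platform
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .accounting import partition_biomass, partition_density, pixel_areas_km2
from .climate_risk import latitudinal_summary, project_future, risk_assessment
from .composition import LEAF_TYPES, broadleaf_share, evergreen_share
from .drivers import convex_hull_coverage, group_pca, importance_ranking, vif
from .ensemble import (
    Hyperparameters, build_training_sets, grid_search, predict_raster, train_ensemble,
)
from .evaluation import kfold_cv, pseudo_r2
from .inventory import filter_inventory, plot_composition
from .landscape import (
    GROUPS, LandscapeConfig, ResponseConfig, biome_raster, generate_covariate_grid,
    generate_forest_rasters, generate_future_climate, generate_trait_catalog,
    generate_true_composition, sample_plots, species_pools,
)
from . import io as ltio

STAGES = ("simulate", "fit", "evaluate", "importance", "account", "risk")

DEFAULT_CONFIG: dict = {
    "out_dir": "results/pipeline",
    "seed": 0,
    "landscape": {"rows": 24, "cols": 24, "correlation_length": 3.0,
                  "between_group_correlation": 0.3},
    "n_plots": 200,
    "mode": "area",
    "n_draws": 8,
    "per_plot": 10,
    "hyperparameters": {"n_trees": 100, "mtry": 4, "min_node": 5},
    "grid_search": False,
    "cv_folds": 5,
    "threshold": 0.60,
    "climate_shift_sd": 1.0,
    "n_climate_models": 2,
    "scenario": "high-emission",
}


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: dict | None = None) -> dict:
    """Run all stages and return the manifest (also written to disk)."""
    cfg = dict(DEFAULT_CONFIG)
    cfg.update(config or {})
    out = Path(cfg["out_dir"])
    out.mkdir(parents=True, exist_ok=True)
    root = np.random.SeedSequence(cfg["seed"])
    stage_seeds = {s: int(ss.generate_state(1)[0] % (2**31)) for s, ss in
                   zip(STAGES, root.spawn(len(STAGES)))}

    manifest = {
        "version": __version__,
        "python": platform.python_version(),
        "config": {k: v for k, v in cfg.items()},
        "stage_seeds": stage_seeds,
        "outputs": {},
        "completed": [],
    }

    def record(stage, path: Path):
        manifest["outputs"][str(path.relative_to(out))] = {"stage": stage, "sha256": _sha256(path)}

    try:
        # --- simulate -----------------------------------------------------
        lc = LandscapeConfig(seed=stage_seeds["simulate"], **cfg["landscape"])
        grid = generate_covariate_grid(lc)
        response = ResponseConfig()
        truth = generate_true_composition(grid, response, seed=stage_seeds["simulate"])
        pools = species_pools()
        plots = sample_plots(grid, truth, cfg["n_plots"], seed=stage_seeds["simulate"], pools=pools)
        catalog = generate_trait_catalog(pools, missing_rate=0.1, conflict_rate=0.1,
                                         seed=stage_seeds["simulate"])
        plots = filter_inventory(plots, catalog)
        rasters = generate_forest_rasters(grid, seed=stage_seeds["simulate"])

        ltio.write_grid(grid, out / "covariates.nc")
        ltio.write_plot_table(plots, out / "plots.csv")
        ltio.write_trait_catalog(catalog, out / "traits.csv")
        for name in ("covariates.nc", "plots.csv", "traits.csv"):
            record("simulate", out / name)
        manifest["completed"].append("simulate")

        # --- fit ----------------------------------------------------------
        observed = np.array([plot_composition(p, catalog, cfg["mode"]) for p in plots])
        training = build_training_sets(plots, catalog, grid, n_draws=cfg["n_draws"],
                                       per_plot=cfg["per_plot"], mode=cfg["mode"],
                                       seed=stage_seeds["fit"])
        if cfg["grid_search"]:
            params, table = grid_search(training[0], k=min(cfg["cv_folds"], len(plots)),
                                        seed=stage_seeds["fit"])
            table.to_csv(out / "grid_search.csv", index=False)
            record("fit", out / "grid_search.csv")
        else:
            params = Hyperparameters(**cfg["hyperparameters"])
        model = train_ensemble(training, params, seed=stage_seeds["fit"])
        model.mode = cfg["mode"]
        mean_map, member_maps = predict_raster(model, grid, keep_members=True)
        np.savetxt(out / "map_mean.csv",
                   mean_map.reshape(len(LEAF_TYPES), -1).T, delimiter=",",
                   header=",".join(LEAF_TYPES), comments="")
        record("fit", out / "map_mean.csv")
        manifest["completed"].append("fit")

        # --- evaluate -----------------------------------------------------
        def factory(train_plots, train_obs):
            ts = build_training_sets(train_plots, catalog, grid, n_draws=cfg["n_draws"],
                                     per_plot=cfg["per_plot"], mode=cfg["mode"],
                                     seed=stage_seeds["evaluate"])
            m = train_ensemble(ts, params, seed=stage_seeds["evaluate"])
            return lambda test_plots: _predict_at(m, grid, test_plots)

        report = kfold_cv(plots, observed, factory, k=min(cfg["cv_folds"], len(plots)),
                          seed=stage_seeds["evaluate"])
        ltio.write_report(report, out / "evaluation.json")
        record("evaluate", out / "evaluation.json")
        manifest["completed"].append("evaluate")

        # --- importance ---------------------------------------------------
        X = pd.DataFrame(np.vstack([grid.at(p.lat, p.lon) for p in plots]), columns=grid.names)
        pcs = []
        for g in GROUPS:
            cols = grid.layers_in_group(g)
            if not cols:
                continue
            res = group_pca(X[cols], g)
            pcs.append(pd.DataFrame(res.scores, columns=res.component_names))
        predictors = pd.concat(pcs, axis=1)
        vifs = vif(predictors)
        vifs.to_csv(out / "vif.csv", header=["vif"])
        imp = importance_ranking(predictors, evergreen_share(observed), "habit",
                                 grid_spec={"mtry": (2, 4), "min_node": (2, 5)},
                                 seed=stage_seeds["importance"])
        imp_form = importance_ranking(predictors, broadleaf_share(observed), "form",
                                      grid_spec={"mtry": (2, 4), "min_node": (2, 5)},
                                      seed=stage_seeds["importance"])
        pd.concat([imp, imp_form]).to_csv(out / "importance.csv", index=False)
        hull = convex_hull_coverage(X.to_numpy(), grid.table(), n_components=4)
        (out / "hull_coverage.json").write_text(json.dumps(
            {k: v for k, v in hull.items() if not isinstance(v, np.ndarray)}, indent=2))
        for name in ("vif.csv", "importance.csv", "hull_coverage.json"):
            record("importance", out / name)
        manifest["completed"].append("importance")

        # --- account ------------------------------------------------------
        biomes = biome_raster(grid)
        areas = pixel_areas_km2(grid.lats, grid.lons, lc.pixel_size)
        density_totals = partition_density(rasters["density"], mean_map, biomes)
        biomass_totals = partition_biomass(rasters["biomass"], rasters["canopy_cover"],
                                           areas, mean_map, biomes)
        density_totals.to_csv(out / "density_totals.csv", index=False)
        biomass_totals.to_csv(out / "biomass_totals.csv", index=False)
        for name in ("density_totals.csv", "biomass_totals.csv"):
            record("account", out / name)
        manifest["completed"].append("account")

        # --- risk ---------------------------------------------------------
        rng = np.random.default_rng(stage_seeds["risk"])
        climate_layers = grid.layers_in_group("climate")
        futures = []
        for _ in range(cfg["n_climate_models"]):
            shifts = {name: cfg["climate_shift_sd"] * (1 + 0.2 * rng.standard_normal())
                      for name in climate_layers}
            futures.append(generate_future_climate(grid, shifts))
        projection = project_future(model, grid, futures, cfg["scenario"], cfg["threshold"])
        risk = risk_assessment(projection.present_labels, projection.future_labels,
                               rasters["canopy_cover"], areas,
                               projection.threshold, projection.threshold)
        summary = latitudinal_summary(projection.present_composition, grid.lats, areas,
                                      projection.future_composition)
        summary.to_csv(out / "latitudinal_summary.csv", index=False)
        (out / "risk.json").write_text(json.dumps(
            {k: v for k, v in risk.items() if not isinstance(v, np.ndarray)}, indent=2))
        for name in ("latitudinal_summary.csv", "risk.json"):
            record("risk", out / name)
        manifest["completed"].append("risk")
    finally:
        manifest["partial"] = len(manifest["completed"]) < len(STAGES)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest


def _predict_at(model, grid, plots):
    from .ensemble import predict_composition

    return predict_composition(model, grid, at=[(p.lat, p.lon) for p in plots]).mean
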