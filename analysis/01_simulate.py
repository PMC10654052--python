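"""Generate the synthetic landscape: covariates, known-truth composition,
plot inventory and an imperfect trait catalog.

Writes covariates.nc, plots.csv, traits.csv and a summary of the world
under results/analysis/.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))

import numpy as np

import leaftypes as lt
from leaftypes import io as ltio
from common import OUT, SEED, build_world


def main():
    OUT.mkdir(parents=True, exist_ok=True)
    cfg, grid, truth, plots, catalog = build_world()

    ltio.write_grid(grid, OUT / "covariates.nc")
    ltio.write_plot_table(plots, OUT / "plots.csv")
    ltio.write_trait_catalog(catalog, OUT / "traits.csv")
    np.savetxt(OUT / "truth_composition.csv",
               truth.reshape(4, -1).T, delimiter=",",
               header=",".join(lt.LEAF_TYPES), comments="")

    n_trees = sum(len(p.trees) for p in plots)
    print(f"landscape {cfg.rows}x{cfg.cols}, {len(grid.names)} covariate layers "
          f"({dict(cfg.layers_per_group)})")
    print(f"{len(plots)} plots survive filtering with {n_trees} adult trees "
          f"(mean {n_trees / len(plots):.1f} per plot, seed {SEED})")
    print(f"biome mix: "
          f"{ {b: sum(p.biome == b for p in plots) for b in lt.BIOMES} }")
    print(f"outputs in {OUT}")


if __name__ == "__main__":
    main()
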