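"""Cover renormalization and density/biomass partitioning.

Land-cover products report leaf-type fractions over *all* ecosystem
types; restricting to forest means dividing each forest-type fraction by
the total forest fraction. Global stocks are then split by leaf type:
tree density rasters are partitioned with individual-based compositions
(counts of stems), biomass with area-based compositions (large stems
carry the biomass), each summed globally and per biome with exact
conservation.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .composition import LEAF_TYPES, as_composition
from .inventory import BIOMES

#: Mean Earth radius (km); pixel areas use the spherical cosine rule.
_EARTH_RADIUS_KM = 6371.0088


def renormalize_forest_cover(cover: dict[str, float]) -> np.ndarray:
    """Forest leaf-type composition from an all-ecosystem cover vector.

    ``cover`` maps the leaf-type keys (any subset of BE/BD/NE/ND) and
    optionally ``'non_forest'`` to fractions. Each forest fraction is
    divided by the total forest fraction; non-forest cover is discarded.
    Idempotent and invariant to uniform scaling of the forest fractions.
    """
    forest = np.array([max(float(cover.get(t, 0.0)), 0.0) for t in LEAF_TYPES])
    if any(float(cover.get(t, 0.0)) < 0 for t in LEAF_TYPES):
        raise ValueError("cover fractions must be non-negative")
    total = forest.sum()
    if total <= 0:
        raise ValueError("no forest cover to renormalize")
    return as_composition(forest / total)


def pixel_areas_km2(lats: np.ndarray, lons: np.ndarray, pixel_size_deg: float) -> np.ndarray:
    """Per-pixel spherical surface area (km²) on a geographic grid.

    Cosine-of-latitude weighting of the equatorial cell area; returns a
    (rows, cols) raster matching the coordinate vectors.
    """
    km_per_deg = 2 * np.pi * _EARTH_RADIUS_KM / 360.0
    cell = (pixel_size_deg * km_per_deg) ** 2 * np.cos(np.radians(np.asarray(lats)))
    return np.tile(cell[:, None], (1, len(lons)))


def _check_aligned(*rasters):
    shapes = {r.shape[-2:] for r in rasters}
    if len(shapes) != 1:
        raise ValueError(f"rasters are not aligned on one grid: shapes {sorted(shapes)}")


def _totals_frame(per_pixel: np.ndarray, biomes: np.ndarray) -> pd.DataFrame:
    """Sum a (4, rows, cols) per-pixel stack globally and per biome."""
    rows = []
    for t_idx, lt in enumerate(LEAF_TYPES):
        row = {"leaf_type": lt, "global": float(per_pixel[t_idx].sum())}
        for b_idx, biome in enumerate(BIOMES):
            row[biome] = float(per_pixel[t_idx][biomes == b_idx].sum())
        rows.append(row)
    return pd.DataFrame(rows)


def partition_density(
    density: np.ndarray, composition: np.ndarray, biomes: np.ndarray
) -> pd.DataFrame:
    """Stem counts per leaf type, globally and per biome.

    ``density`` is trees per pixel; ``composition`` an individual-based
    (4, rows, cols) raster. Per-type totals conserve the grand total
    exactly.
    """
    _check_aligned(density, composition, biomes)
    if np.any(density < 0):
        raise ValueError("tree density must be non-negative")
    return _totals_frame(density[None] * composition, biomes)


def partition_biomass(
    biomass_density: np.ndarray,
    canopy_cover: np.ndarray,
    areas: np.ndarray,
    composition: np.ndarray,
    biomes: np.ndarray,
    area_units_m2_per_cell: float = 1e6,
) -> pd.DataFrame:
    """Aboveground biomass per leaf type, globally and per biome.

    Absolute biomass per pixel = density (kg/m²) x canopy cover x pixel
    area; ``areas`` is in km² and converted with
    ``area_units_m2_per_cell`` (default 10⁶ m²/km²). The absolute
    biomass is split by the area-based composition raster.
    """
    _check_aligned(biomass_density, canopy_cover, areas, composition, biomes)
    if np.any(biomass_density < 0):
        raise ValueError("biomass density must be non-negative")
    if np.any((canopy_cover < 0) | (canopy_cover > 1)):
        raise ValueError("canopy cover must be in [0, 1]")
    absolute = biomass_density * canopy_cover * areas * area_units_m2_per_cell
    return _totals_frame(absolute[None] * composition, biomes)


def aggregate_blocks(member_rasters: np.ndarray, block: int) -> dict:
    """Coarsen member prediction rasters to blocks and recompute CI widths.

    ``member_rasters`` has shape (n_members, 4, rows, cols); rows/cols
    are cropped to a multiple of ``block``. Member predictions are
    averaged within each block and the 95% percentile interval is
    recomputed across members per block, showing how prediction
    uncertainty shrinks when the map is read at coarser scales.
    """
    if block < 1:
        raise ValueError("block size must be >= 1")
    m, k, rows, cols = member_rasters.shape
    r2, c2 = (rows // block) * block, (cols // block) * block
    x = member_rasters[:, :, :r2, :c2]
    x = x.reshape(m, k, r2 // block, block, c2 // block, block).mean(axis=(3, 5))
    lower = np.percentile(x, 2.5, axis=0)
    upper = np.percentile(x, 97.5, axis=0)
    return {
        "block_mean": x.mean(axis=0),
        "ci_lower": lower,
        "ci_upper": upper,
        "mean_ci_width": float((upper - lower).mean()),
    }
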