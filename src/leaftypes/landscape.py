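"""Synthetic landscapes with known leaf-type truth.

Everything downstream (composition mapping, evaluation, driver
attribution, accounting, climate-envelope risk) is exercised offline on
landscapes generated here: spatially autocorrelated, group-structured
covariate rasters; a known 4-class composition surface driven by
designated layers; multinomial plot/tree samples; trait catalogs with
missing and conflicting entries; and perturbed future climates.

The stated world the defaults encode: leaf *form* (broadleaf vs
needleleaf) responds to a cold-season-temperature analog
(``climate_00``); leaf *habit* (evergreen vs deciduous) responds to an
isothermality analog (``climate_01``) and a soil-pH analog
(``soil_00``). Covariates are standardized Gaussian fields, so link
coefficients are in units of standard deviations of the driver.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .composition import LEAF_TYPES, LEAF_TYPE_INDEX
from .inventory import BIOMES, InventoryPlot, TraitCatalog, TraitEntry, TreeRecord

GROUPS: tuple[str, ...] = ("climate", "soil", "topography", "vegetation")

#: Designated driver layers, mirroring the finding the synthetic world encodes:
#: habit <- isothermality + soil pH analogs, form <- cold-season temperature analog.
DEFAULT_DRIVERS: dict[str, tuple[str, float]] = {
    "climate_00": ("form", 2.0),  # cold-season temperature analog
    "climate_01": ("habit", 1.5),  # isothermality analog
    "soil_00": ("habit", -1.5),  # soil pH analog
}


@dataclass(frozen=True)
class LandscapeConfig:
    """Dimensions, registration and covariance structure of a landscape.

    The grid is north-up with pixel-center registration; ``origin`` is
    the center of the top-left (northernmost, westernmost) pixel.
    """

    rows: int = 32
    cols: int = 32
    pixel_size: float = 0.5  # degrees
    origin: tuple[float, float] = (20.0, -60.0)  # (lat, lon) of first pixel center
    # mirrors the driver-analysis covariate set: three big groups that get
    # reduced to six principal components each, plus a small vegetation
    # group that passes through untouched
    layers_per_group: dict[str, int] = field(
        default_factory=lambda: {"climate": 10, "soil": 8, "topography": 7, "vegetation": 3}
    )
    correlation_length: float = 4.0  # pixels
    between_group_correlation: float = 0.3
    seed: int = 0

    def __post_init__(self):
        if self.rows < 8 or self.cols < 8:
            raise ValueError("grid must be at least 8 x 8")
        if self.correlation_length <= 0:
            raise ValueError("correlation length must be positive")
        if not 0 <= self.between_group_correlation <= 1:
            raise ValueError("between-group correlation must be in [0, 1]")
        for g in self.layers_per_group:
            if g not in GROUPS:
                raise ValueError(f"unknown covariate group {g!r}")


@dataclass(frozen=True)
class ResponseConfig:
    """Links from driver layers to the leaf-type truth surface.

    ``drivers`` maps layer name -> (target, coefficient) with target
    'habit' or 'form'; the per-pixel broadleaf log-odds is the linear
    score of the form drivers and the evergreen log-odds that of the
    habit drivers. ``noise_scale`` adds a smoothed Gaussian field of
    that standard deviation to each log-odds.
    """

    drivers: dict[str, tuple[str, float]] = field(default_factory=lambda: dict(DEFAULT_DRIVERS))
    noise_scale: float = 0.0
    noise_correlation_length: float = 4.0

    def __post_init__(self):
        targets = {t for t, _ in self.drivers.values()}
        if "habit" not in targets or "form" not in targets:
            raise ValueError("need at least one habit driver and one form driver")
        if self.noise_scale < 0:
            raise ValueError("noise scale must be non-negative")


@dataclass
class CovariateGrid:
    """A named raster stack on a common geographic grid.

    ``values`` has shape (n_layers, rows, cols); ``lats``/``lons`` give
    pixel-center coordinates (lats descending: north-up).
    """

    values: np.ndarray
    names: list[str]
    groups: dict[str, str]  # layer name -> group
    lats: np.ndarray
    lons: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape[0] != len(self.names):
            raise ValueError("one raster required per layer name")
        if self.values.shape[1:] != (len(self.lats), len(self.lons)):
            raise ValueError("raster shape must match coordinate vectors")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape[1:]

    def layer(self, name: str) -> np.ndarray:
        try:
            return self.values[self.names.index(name)]
        except ValueError:
            raise KeyError(f"no covariate layer named {name!r}") from None

    def layers_in_group(self, group: str) -> list[str]:
        return [n for n in self.names if self.groups[n] == group]

    def pixel_of(self, lat: float, lon: float) -> tuple[int, int]:
        """Row/col of the pixel whose cell contains (lat, lon)."""
        step_lat = self.lats[1] - self.lats[0] if len(self.lats) > 1 else -1.0
        step_lon = self.lons[1] - self.lons[0] if len(self.lons) > 1 else 1.0
        r = int(np.floor((lat - (self.lats[0] - step_lat / 2)) / step_lat))
        c = int(np.floor((lon - (self.lons[0] - step_lon / 2)) / step_lon))
        if not (0 <= r < len(self.lats) and 0 <= c < len(self.lons)):
            raise ValueError(f"location ({lat}, {lon}) outside the grid")
        return r, c

    def at(self, lat: float, lon: float) -> np.ndarray:
        """Covariate vector at the containing pixel."""
        r, c = self.pixel_of(lat, lon)
        return self.values[:, r, c]

    def table(self) -> np.ndarray:
        """Pixels-by-layers matrix (row-major pixel order)."""
        return self.values.reshape(len(self.names), -1).T

    def copy(self) -> "CovariateGrid":
        return CovariateGrid(
            self.values.copy(), list(self.names), dict(self.groups), self.lats.copy(), self.lons.copy()
        )


def smoothed_field(rng: np.random.Generator, shape: tuple[int, int], length: float) -> np.ndarray:
    """White noise smoothed with a Gaussian kernel of scale ``length`` pixels.

    Not re-standardized: smoothing shrinks the field's standard deviation
    below the unit noise sd, increasingly so as ``length`` grows.
    """
    noise = rng.standard_normal(shape)
    return ndimage.gaussian_filter(noise, sigma=length, mode="wrap")


def _standardize(field2d: np.ndarray) -> np.ndarray:
    sd = field2d.std()
    if sd == 0:
        return field2d - field2d.mean()
    return (field2d - field2d.mean()) / sd


def generate_covariate_grid(config: LandscapeConfig) -> CovariateGrid:
    """Correlated, standardized covariate rasters.

    Each layer is a weighted sum of a shared global field (weight
    ``sqrt(rho_b)`` with ``rho_b`` the between-group correlation), a
    per-group field and an independent field, all Gaussian-smoothed at
    the configured correlation length, then standardized per layer.
    Within-group correlation is ``0.5 + 0.5 * rho_b`` so it always
    dominates the cross-group correlation.
    """
    rng = np.random.default_rng(config.seed)
    shape = (config.rows, config.cols)
    rho_b = config.between_group_correlation
    rho_w = 0.5 + 0.5 * rho_b
    a, b, c = np.sqrt(rho_b), np.sqrt(rho_w - rho_b), np.sqrt(1 - rho_w)

    global_field = _standardize(smoothed_field(rng, shape, config.correlation_length))
    values, names, groups = [], [], {}
    for group in GROUPS:
        n_layers = config.layers_per_group.get(group, 0)
        if n_layers == 0:
            continue
        group_field = _standardize(smoothed_field(rng, shape, config.correlation_length))
        for i in range(n_layers):
            own = _standardize(smoothed_field(rng, shape, config.correlation_length))
            layer = _standardize(a * global_field + b * group_field + c * own)
            name = f"{group}_{i:02d}"
            values.append(layer)
            names.append(name)
            groups[name] = group

    lats = config.origin[0] - config.pixel_size * np.arange(config.rows)
    lons = config.origin[1] + config.pixel_size * np.arange(config.cols)
    return CovariateGrid(np.stack(values), names, groups, lats, lons)


def generate_true_composition(
    grid: CovariateGrid, response: ResponseConfig, seed: int | None = None
) -> np.ndarray:
    """Known-truth composition raster of shape (4, rows, cols).

    Per pixel the composition is a softmax of additive class scores:
    broadleaf-vs-needleleaf log-odds come only from the form drivers,
    evergreen-vs-deciduous log-odds only from the habit drivers, so the
    two margins are independently controlled. Rows sum to one exactly.
    """
    form_score = np.zeros(grid.shape)
    habit_score = np.zeros(grid.shape)
    for name, (target, coef) in response.drivers.items():
        if name not in grid.names:
            raise ValueError(f"driver layer {name!r} not present in the covariate grid")
        if target == "form":
            form_score += coef * grid.layer(name)
        elif target == "habit":
            habit_score += coef * grid.layer(name)
        else:
            raise ValueError(f"driver target must be 'habit' or 'form', got {target!r}")
    if response.noise_scale > 0:
        rng = np.random.default_rng(seed)
        for score in (form_score, habit_score):
            raw = smoothed_field(rng, grid.shape, response.noise_correlation_length)
            score += response.noise_scale * _standardize(raw)

    from scipy.special import expit

    p_broadleaf = expit(form_score)
    p_evergreen = expit(habit_score)
    comp = np.empty((len(LEAF_TYPES),) + grid.shape)
    comp[LEAF_TYPE_INDEX["BE"]] = p_broadleaf * p_evergreen
    comp[LEAF_TYPE_INDEX["BD"]] = p_broadleaf * (1 - p_evergreen)
    comp[LEAF_TYPE_INDEX["NE"]] = (1 - p_broadleaf) * p_evergreen
    comp[LEAF_TYPE_INDEX["ND"]] = (1 - p_broadleaf) * (1 - p_evergreen)
    comp /= comp.sum(axis=0, keepdims=True)  # exact normalization
    return comp


def biome_raster(grid: CovariateGrid) -> np.ndarray:
    """Synthetic biome codes as four latitudinal bands.

    South to north: tropical, arid, temperate, boreal; codes index
    :data:`leaftypes.inventory.BIOMES`. Stands in for the biome polygon
    layer real analyses would use.
    """
    rows = len(grid.lats)
    band_order = ["boreal", "temperate", "arid", "tropical"]  # north-up rows
    codes = np.empty((rows, len(grid.lons)), dtype=int)
    for r in range(rows):
        band = band_order[min(r * 4 // rows, 3)]
        codes[r, :] = BIOMES.index(band)
    return codes


def species_pools(n_species_per_type: int = 30, n_genera_per_type: int = 6) -> dict[str, list[str]]:
    """Disjoint species pools per leaf type.

    Species binomials are ``"<Genus> sp<k>"`` with genera private to one
    leaf type, so each species' true leaf type is unambiguous and the
    genus is derivable as the first name token.
    """
    pools: dict[str, list[str]] = {}
    for lt in LEAF_TYPES:
        pool = []
        for k in range(n_species_per_type):
            genus = f"{lt.capitalize()}gen{k % n_genera_per_type:02d}"
            pool.append(f"{genus} sp{k:02d}")
        pools[lt] = pool
    return pools


def _truncated_lognormal_dbh(rng: np.random.Generator, n: int, mean_log=3.2, sd_log=0.45) -> np.ndarray:
    """Lognormal DBH (cm) left-truncated at 10 cm by inverse-CDF sampling."""
    from scipy import stats

    lo = stats.norm.cdf((np.log(10.0) - mean_log) / sd_log)
    u = rng.uniform(lo, 1.0, size=n)
    return np.exp(mean_log + sd_log * stats.norm.ppf(u))


def sample_plots(
    grid: CovariateGrid,
    comp_raster: np.ndarray,
    n_plots: int,
    trees_per_plot=None,
    seed: int = 0,
    pools: dict[str, list[str]] | None = None,
    year: int = 2005,
) -> list[InventoryPlot]:
    """Multinomial plot samples from the truth surface.

    Plot locations are uniform over pixels (jittered within the cell);
    each tree's leaf type is a multinomial draw from the pixel
    composition, its species a uniform draw from that type's pool, and
    its DBH lognormal left-truncated at 10 cm. Every plot has at least
    10 trees; the biome label comes from the synthetic latitudinal-band
    biome raster.
    """
    if n_plots < 1:
        raise ValueError("n_plots must be >= 1")
    if comp_raster.shape[1:] != grid.shape:
        raise ValueError("composition raster does not match the grid")
    rng = np.random.default_rng(seed)
    if trees_per_plot is None:
        # mean ~84 trees per plot, matching the source inventory's
        # 817,091 individuals over 9,781 plots
        trees_per_plot = lambda rng: 10 + rng.poisson(74)
    pools = pools or species_pools()
    biomes = biome_raster(grid)
    half = abs(grid.lats[1] - grid.lats[0]) / 2 if len(grid.lats) > 1 else 0.25

    plots: list[InventoryPlot] = []
    rows, cols = grid.shape
    for i in range(n_plots):
        r = int(rng.integers(rows))
        c = int(rng.integers(cols))
        lat = float(grid.lats[r] + rng.uniform(-half, half) * 0.99)
        lon = float(grid.lons[c] + rng.uniform(-half, half) * 0.99)
        n_trees = max(10, int(trees_per_plot(rng)))
        type_counts = rng.multinomial(n_trees, comp_raster[:, r, c])
        dbhs = _truncated_lognormal_dbh(rng, n_trees)
        trees, k = [], 0
        for t_idx, count in enumerate(type_counts):
            pool = pools[LEAF_TYPES[t_idx]]
            for _ in range(count):
                sp = pool[int(rng.integers(len(pool)))]
                trees.append(TreeRecord(species=sp, genus=sp.split()[0], dbh_cm=float(dbhs[k])))
                k += 1
        plots.append(
            InventoryPlot(
                id=f"plot{i:05d}",
                lat=lat,
                lon=lon,
                biome=BIOMES[biomes[r, c]],
                year=year,
                trees=tuple(trees),
            )
        )
    return plots


def generate_trait_catalog(
    pools: dict[str, list[str]],
    missing_rate: float = 0.0,
    conflict_rate: float = 0.0,
    seed: int = 0,
) -> TraitCatalog:
    """Trait catalog with controlled imperfections.

    Species entries are dropped at ``missing_rate`` (their genus entry is
    always retained, so genus fallback is exercised); at
    ``conflict_rate`` a species entry carries multiple raw observations
    whose strict majority still equals its true habit/form.
    """
    if not (0 <= missing_rate < 1) or not (0 <= conflict_rate < 1):
        raise ValueError("missing_rate and conflict_rate must be in [0, 1)")
    rng = np.random.default_rng(seed)
    habit_of = {"BE": "evergreen", "NE": "evergreen", "BD": "deciduous", "ND": "deciduous"}
    form_of = {"BE": "broadleaf", "BD": "broadleaf", "NE": "needleleaf", "ND": "needleleaf"}
    other_habit = {"evergreen": "deciduous", "deciduous": "evergreen"}

    catalog = TraitCatalog()
    for lt, species in pools.items():
        habit, form = habit_of[lt], form_of[lt]
        genera = sorted({s.split()[0] for s in species})
        for g in genera:
            catalog.add(
                TraitEntry(taxon=g, rank="genus", habit=habit, form=form,
                           habit_observations=(habit,), form_observations=(form,))
            )
        for sp in species:
            if rng.uniform() < missing_rate:
                continue  # genus entry above still resolves it
            if rng.uniform() < conflict_rate:
                habit_obs = (habit, habit, other_habit[habit])
            else:
                habit_obs = (habit,)
            catalog.add(
                TraitEntry(taxon=sp, rank="species", habit=habit, form=form,
                           habit_observations=habit_obs, form_observations=(form,))
            )
    return catalog


def generate_future_climate(grid: CovariateGrid, shifts: dict[str, float]) -> CovariateGrid:
    """Future covariates: climate layers shifted, everything else bit-identical.

    Mirrors the scenario construction in which projected climate layers
    replace the present ones while soil, topographic and vegetative
    characteristics are held constant.
    """
    for name in shifts:
        if name not in grid.names:
            raise ValueError(f"unknown layer {name!r}")
        if grid.groups[name] != "climate":
            raise ValueError(f"layer {name!r} is in group {grid.groups[name]!r}; only climate layers may shift")
    future = grid.copy()
    for name, offset in shifts.items():
        future.values[future.names.index(name)] += offset
    return future


def generate_forest_rasters(grid: CovariateGrid, seed: int = 0) -> dict[str, np.ndarray]:
    """Synthetic stand structure rasters: tree density (stems/pixel),
    aboveground biomass density (kg/m^2) and canopy cover fraction.

    Stand-ins for the external density/biomass/cover products real
    analyses consume; positive, spatially smooth, seed-deterministic.
    """
    rng = np.random.default_rng(seed)
    base = {
        "density": np.exp(5 + 0.8 * _standardize(smoothed_field(rng, grid.shape, 4.0))),
        "biomass": np.exp(2 + 0.6 * _standardize(smoothed_field(rng, grid.shape, 4.0))),
    }
    cover_f = _standardize(smoothed_field(rng, grid.shape, 4.0))
    base["canopy_cover"] = np.clip(0.6 + 0.25 * cover_f, 0.05, 1.0)
    return base
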