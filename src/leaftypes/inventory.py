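"""Tree and plot data model, trait resolution and plot-level compositions.

The inventory holds georeferenced plots of individually measured trees
(species identity, stem diameter at breast height). Leaf type per tree is
resolved through a trait catalog mapping taxa to leaf habit (evergreen vs
deciduous) and leaf form (broadleaf vs needleleaf), with species-level
entries preferred and genus-level entries as fallback. Plot filtering,
individual- vs basal-area-based composition, and biome-proportional
downsampling live here.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np

from .composition import LEAF_TYPES, LEAF_TYPE_INDEX, as_composition, leaf_type_of

logger = logging.getLogger(__name__)

BIOMES: tuple[str, ...] = ("tropical", "temperate", "boreal", "arid")

#: Minimum stem diameter (cm) for an adult tree.
ADULT_DBH_CM = 10.0
#: Minimum adult trees per plot after filtering.
MIN_TREES_PER_PLOT = 10
#: Minimum fraction of individuals with a resolved leaf-type record.
MIN_RESOLVED_FRACTION = 0.5

#: Fixed tie-break priority for modal trait resolution (configurable per call).
HABIT_PRIORITY: tuple[str, ...] = ("evergreen", "deciduous")
FORM_PRIORITY: tuple[str, ...] = ("broadleaf", "needleleaf")


@dataclass(frozen=True)
class TreeRecord:
    """A single measured tree: species binomial, genus and DBH in cm."""

    species: str
    genus: str
    dbh_cm: float

    def __post_init__(self):
        if not self.dbh_cm > 0:
            raise ValueError(f"DBH must be positive, got {self.dbh_cm}")


@dataclass(frozen=True)
class InventoryPlot:
    """A georeferenced forest inventory plot with its tree records."""

    id: str
    lat: float
    lon: float
    biome: str
    year: int
    trees: tuple[TreeRecord, ...] = ()
    resolved_fraction: float | None = None

    def __post_init__(self):
        if not -90 <= self.lat <= 90:
            raise ValueError(f"latitude {self.lat} outside [-90, 90]")
        if not -180 <= self.lon <= 180:
            raise ValueError(f"longitude {self.lon} outside [-180, 180]")
        object.__setattr__(self, "trees", tuple(self.trees))


@dataclass(frozen=True)
class TraitEntry:
    """Resolved habit/form for one taxon, with raw observations retained."""

    taxon: str
    rank: str  # "species" | "genus"
    habit: str  # "evergreen" | "deciduous"
    form: str  # "broadleaf" | "needleleaf"
    habit_observations: tuple[str, ...] = ()
    form_observations: tuple[str, ...] = ()

    @property
    def leaf_type(self) -> str:
        return leaf_type_of(self.habit, self.form)


@dataclass
class TraitCatalog:
    """Taxon -> leaf trait lookup with species priority and genus fallback."""

    entries: dict[str, TraitEntry] = field(default_factory=dict)

    def add(self, entry: TraitEntry) -> None:
        self.entries[entry.taxon] = entry

    def lookup(self, taxon: str) -> TraitEntry | None:
        return self.entries.get(taxon)

    def __len__(self) -> int:
        return len(self.entries)


def basal_area(dbh_cm) -> float | np.ndarray:
    """Basal area A = pi * DBH^2 / 4 in cm^2 for DBH in cm."""
    dbh = np.asarray(dbh_cm, dtype=float)
    if np.any(dbh <= 0):
        raise ValueError("DBH must be positive")
    out = math.pi * dbh**2 / 4.0
    return float(out) if np.isscalar(dbh_cm) else out


def majority_trait(observations, priority=None) -> str:
    """Modal label over raw trait observations.

    Ties are broken by position in ``priority`` (first wins); default
    priority is evergreen > deciduous and broadleaf > needleleaf.
    """
    obs = list(observations)
    if not obs:
        raise ValueError("majority_trait requires at least one observation")
    if priority is None:
        priority = HABIT_PRIORITY if obs[0] in HABIT_PRIORITY else FORM_PRIORITY
    counts: dict[str, int] = {}
    for o in obs:
        counts[o] = counts.get(o, 0) + 1
    best = max(counts.values())
    winners = [label for label, c in counts.items() if c == best]
    if len(winners) == 1:
        return winners[0]
    order = {label: i for i, label in enumerate(priority)}
    return min(winners, key=lambda lab: order.get(lab, len(order)))


def resolve_leaf_type(tree: TreeRecord, catalog: TraitCatalog) -> str | None:
    """Leaf-type class for a tree, or None when unresolved.

    Species-level catalog entries take precedence over genus-level ones,
    even when the two disagree.
    """
    entry = catalog.lookup(tree.species)
    if entry is not None and entry.rank == "species":
        return entry.leaf_type
    entry = catalog.lookup(tree.genus)
    if entry is not None:
        return entry.leaf_type
    return None


def _latest_year_only(plots: list[InventoryPlot]) -> list[InventoryPlot]:
    """Keep only the most recent observation year per plot id."""
    latest: dict[str, int] = {}
    for p in plots:
        if p.id not in latest or p.year > latest[p.id]:
            latest[p.id] = p.year
    return [p for p in plots if p.year == latest[p.id]]


def filter_inventory(plots, catalog: TraitCatalog) -> list[InventoryPlot]:
    """Apply the inventory inclusion rules.

    In order: keep only the latest observation year per plot id; drop
    trees with DBH < 10 cm; drop plots with fewer than 10 remaining
    adults; drop plots where fewer than 50% of adults have a resolvable
    leaf-type record. Surviving plots are annotated with the resolved
    fraction. The operation is idempotent.
    """
    out: list[InventoryPlot] = []
    for plot in _latest_year_only(list(plots)):
        adults = tuple(t for t in plot.trees if t.dbh_cm >= ADULT_DBH_CM)
        if len(adults) < MIN_TREES_PER_PLOT:
            continue
        resolved = sum(1 for t in adults if resolve_leaf_type(t, catalog) is not None)
        frac = resolved / len(adults)
        if frac < MIN_RESOLVED_FRACTION:
            continue
        out.append(replace(plot, trees=adults, resolved_fraction=frac))
    return out


def plot_composition(plot: InventoryPlot, catalog: TraitCatalog, mode: str = "individual") -> np.ndarray:
    """Leaf-type composition of one plot over its resolved trees.

    ``mode='individual'`` counts trees; ``mode='area'`` weights each tree
    by its basal area, so the composition reflects the leaf types of the
    largest stems.
    """
    if mode not in ("individual", "area"):
        raise ValueError(f"mode must be 'individual' or 'area', got {mode!r}")
    weights = np.zeros(len(LEAF_TYPES))
    for tree in plot.trees:
        lt = resolve_leaf_type(tree, catalog)
        if lt is None:
            continue
        w = basal_area(tree.dbh_cm) if mode == "area" else 1.0
        weights[LEAF_TYPE_INDEX[lt]] += w
    total = weights.sum()
    if total <= 0:
        raise ValueError(f"plot {plot.id} has no resolved trees; run filter_inventory first")
    return as_composition(weights / total)


def downsample_by_biome(plots, biome_area_shares: dict[str, float], seed: int) -> list[InventoryPlot]:
    """Biome-proportional downsampling anchored on the tropical plots.

    All tropical plots are retained; every other biome is randomly
    subsampled to ``n_tropical * share_b / share_tropical`` plots so the
    resulting biome mix matches the forested-area shares. A biome with
    fewer plots than its target keeps all of them (with a warning).
    """
    if biome_area_shares.get("tropical", 0.0) <= 0:
        raise ValueError("tropical share must be positive")
    plots = list(plots)
    rng = np.random.default_rng(seed)
    tropical = [p for p in plots if p.biome == "tropical"]
    out = list(tropical)
    s_trop = biome_area_shares["tropical"]
    for biome in sorted({p.biome for p in plots} - {"tropical"}):
        pool = [p for p in plots if p.biome == biome]
        target = round(len(tropical) * biome_area_shares.get(biome, 0.0) / s_trop)
        if target >= len(pool):
            if target > len(pool):
                logger.warning(
                    "biome %s has %d plots but target %d; keeping all", biome, len(pool), target
                )
            out.extend(pool)
        else:
            idx = rng.choice(len(pool), size=target, replace=False)
            out.extend(pool[i] for i in sorted(idx))
    return out
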