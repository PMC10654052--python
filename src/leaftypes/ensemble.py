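"""Basal-area-weighted subsample ensembles of multiprobability forests.

The mapping model is an ensemble of random-forest classifiers in
probability-output mode. Training sets are built by repeatedly drawing a
fixed number of individual trees from every plot — with probability
proportional to basal area for the area-based model, uniformly for the
individual-based model — pairing each sampled tree's leaf-type label
with the covariate vector of the plot's pixel. One classifier is fitted
per draw; predictions are summarized by the member mean and 95%
percentile intervals, which propagate the within-plot subsampling
uncertainty into the maps.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.ensemble import RandomForestClassifier

from .composition import LEAF_TYPES, LEAF_TYPE_INDEX
from .evaluation import assign_folds, pseudo_r2
from .inventory import TraitCatalog, basal_area, resolve_leaf_type
from .landscape import CovariateGrid

logger = logging.getLogger(__name__)

#: Default hyperparameter grid: number of trees, variables per split,
#: minimum samples at a terminal node. Subsampling rate is fixed at 0.632.
DEFAULT_GRID: dict[str, tuple] = {
    "n_trees": (10, 20, 50, 100, 250),
    "mtry": (1, 2, 4, 5, 8, 10, 15, 20, 30),
    "min_node": (1, 2, 5, 10, 15, 20, 30),
}
SUBSAMPLE_RATE = 0.632


@dataclass(frozen=True)
class Hyperparameters:
    n_trees: int = 100
    mtry: int = 4
    min_node: int = 5


@dataclass
class TrainingMatrix:
    """One draw's training rows: sampled trees with plot covariates."""

    X: np.ndarray  # (n_rows, n_layers)
    y: np.ndarray  # class indices into LEAF_TYPES
    plot_ids: np.ndarray  # plot id per row
    draw: int
    layer_names: list[str]

    def observed_compositions(self) -> tuple[np.ndarray, list[str]]:
        """Per-plot empirical composition of this draw's sampled rows."""
        ids = sorted(set(self.plot_ids.tolist()))
        comp = np.zeros((len(ids), len(LEAF_TYPES)))
        for i, pid in enumerate(ids):
            mask = self.plot_ids == pid
            counts = np.bincount(self.y[mask], minlength=len(LEAF_TYPES))
            comp[i] = counts / counts.sum()
        return comp, ids


@dataclass
class CompositionPrediction:
    """Ensemble prediction: member mean and 95% percentile bounds."""

    mean: np.ndarray  # (n, 4)
    lower: np.ndarray  # 2.5th percentile across members
    upper: np.ndarray  # 97.5th percentile across members
    members: np.ndarray | None = None  # (n_members, n, 4) if retained


@dataclass
class EnsembleModel:
    """The fitted ensemble: one classifier per training draw."""

    members: list
    member_classes: list[np.ndarray]
    hyperparameters: Hyperparameters
    layer_names: list[str]
    mode: str
    scaler_mean: np.ndarray = field(default=None)
    scaler_sd: np.ndarray = field(default=None)

    def __len__(self) -> int:
        return len(self.members)


def build_training_sets(
    plots,
    catalog: TraitCatalog,
    grid: CovariateGrid,
    n_draws: int = 100,
    per_plot: int = 10,
    mode: str = "area",
    seed: int = 0,
) -> list[TrainingMatrix]:
    """Per-plot subsample training matrices.

    For every draw and plot, ``per_plot`` resolved trees are sampled with
    replacement — probability proportional to basal area in ``'area'``
    mode, uniform in ``'individual'`` mode — and labelled with their
    resolved leaf type; the covariate vector is that of the plot's
    containing pixel. Returns ``n_draws`` matrices of
    ``per_plot * n_plots`` rows each.
    """
    if mode not in ("area", "individual"):
        raise ValueError(f"mode must be 'area' or 'individual', got {mode!r}")
    plots = list(plots)
    rng = np.random.default_rng(seed)

    outside = []
    plot_cov, plot_labels, plot_weights = [], [], []
    for p in plots:
        try:
            cov = grid.at(p.lat, p.lon)
        except ValueError:
            outside.append(p.id)
            continue
        labels, weights = [], []
        for t in p.trees:
            lt = resolve_leaf_type(t, catalog)
            if lt is None:
                continue
            labels.append(LEAF_TYPE_INDEX[lt])
            weights.append(basal_area(t.dbh_cm) if mode == "area" else 1.0)
        if not labels:
            raise ValueError(f"plot {p.id} has no resolved trees; filter the inventory first")
        plot_cov.append(cov)
        plot_labels.append(np.array(labels))
        w = np.array(weights, dtype=float)
        plot_weights.append(w / w.sum())
    if outside:
        raise ValueError(f"plots outside the covariate grid: {outside}")

    usable = [p for p in plots if p.id not in outside]
    matrices = []
    for draw in range(n_draws):
        X, y, ids = [], [], []
        for cov, labels, w, p in zip(plot_cov, plot_labels, plot_weights, usable):
            pick = rng.choice(len(labels), size=per_plot, replace=True, p=w)
            X.append(np.tile(cov, (per_plot, 1)))
            y.append(labels[pick])
            ids.extend([p.id] * per_plot)
        matrices.append(
            TrainingMatrix(
                X=np.vstack(X), y=np.concatenate(y), plot_ids=np.array(ids),
                draw=draw, layer_names=list(grid.names),
            )
        )
    return matrices


def _fit_member(X, y, params: Hyperparameters, seed: int) -> tuple[RandomForestClassifier, np.ndarray]:
    classes = np.unique(y)
    if classes.size == 1:
        logger.warning("training set is single-class (%s)", LEAF_TYPES[int(classes[0])])
    clf = RandomForestClassifier(
        n_estimators=params.n_trees,
        max_features=min(params.mtry, X.shape[1]),
        min_samples_leaf=params.min_node,
        bootstrap=True,
        max_samples=SUBSAMPLE_RATE if X.shape[0] > 1 else None,
        random_state=int(seed),
        n_jobs=1,
    )
    clf.fit(X, y)
    return clf, classes


def _member_proba(clf, classes: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Probability matrix expanded to the full 4-class layout."""
    proba = clf.predict_proba(X)
    out = np.zeros((X.shape[0], len(LEAF_TYPES)))
    out[:, classes] = proba
    return out


def grid_search(
    training: TrainingMatrix,
    grid_spec: dict[str, tuple] | None = None,
    k: int = 10,
    seed: int = 0,
) -> tuple[Hyperparameters, "pd.DataFrame"]:
    """Hyperparameter search scored by plot-level k-fold pseudo-R².

    Each grid point is evaluated on one representative training draw:
    the classifier is fitted on the training folds' rows and its
    predicted compositions for held-out plots are scored against that
    draw's empirical plot compositions. Ties break toward fewer trees,
    then smaller mtry, then smaller node size. Returns the winning
    hyperparameters and the full score table.
    """
    import pandas as pd

    spec = dict(DEFAULT_GRID if grid_spec is None else grid_spec)
    points = list(itertools.product(spec["n_trees"], spec["mtry"], spec["min_node"]))
    if not points:
        raise ValueError("empty hyperparameter grid")

    obs, ids = training.observed_compositions()
    id_index = {pid: i for i, pid in enumerate(ids)}
    folds = assign_folds(len(ids), k, seed)
    row_fold = np.array([folds[id_index[pid]] for pid in training.plot_ids])

    # one covariate row per plot (rows within a plot share the pixel vector)
    plot_X = np.vstack([training.X[training.plot_ids == pid][0] for pid in ids])

    rows = []
    for n_trees, mtry, min_node in points:
        params = Hyperparameters(n_trees, mtry, min_node)
        pred = np.empty_like(obs)
        ok = True
        for fold in range(k):
            train_mask = row_fold != fold
            test_plots = np.flatnonzero(folds == fold)
            if not train_mask.any() or test_plots.size == 0:
                ok = False
                break
            clf, classes = _fit_member(training.X[train_mask], training.y[train_mask], params, seed)
            pred[test_plots] = _member_proba(clf, classes, plot_X[test_plots])
        score = pseudo_r2(obs, pred).r2_bc if ok else float("nan")
        rows.append({"n_trees": n_trees, "mtry": mtry, "min_node": min_node, "r2_bc": score})
    table = pd.DataFrame(rows)
    if table["r2_bc"].isna().all():
        raise ValueError("no grid point could be scored")

    best_score = table["r2_bc"].max()
    contenders = table[np.isclose(table["r2_bc"], best_score)]
    winner = contenders.sort_values(["n_trees", "mtry", "min_node"]).iloc[0]
    return Hyperparameters(int(winner.n_trees), int(winner.mtry), int(winner.min_node)), table


def train_ensemble(
    training_sets: list[TrainingMatrix],
    params: Hyperparameters,
    seed: int = 0,
) -> EnsembleModel:
    """Fit one probability-output classifier per training draw.

    Members are seeded independently but reproducibly from ``seed``.
    Covariates are standardized with statistics pooled over the training
    sets (training-only statistics; harmless for forests but keeps the
    prediction path uniform).
    """
    if not training_sets:
        raise ValueError("need at least one training set")
    all_X = np.vstack([t.X for t in training_sets])
    mean = all_X.mean(axis=0)
    sd = all_X.std(axis=0)
    sd[sd == 0] = 1.0

    ss = np.random.SeedSequence(seed)
    member_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(len(training_sets))]
    members, member_classes = [], []
    for t, mseed in zip(training_sets, member_seeds):
        clf, classes = _fit_member((t.X - mean) / sd, t.y, params, mseed)
        members.append(clf)
        member_classes.append(classes)
    return EnsembleModel(
        members=members, member_classes=member_classes, hyperparameters=params,
        layer_names=list(training_sets[0].layer_names),
        mode="", scaler_mean=mean, scaler_sd=sd,
    )


def _covariates_at(model: EnsembleModel, grid: CovariateGrid, at=None) -> np.ndarray:
    missing = [n for n in model.layer_names if n not in grid.names]
    if missing:
        raise ValueError(f"covariate grid is missing layers: {missing}")
    order = [grid.names.index(n) for n in model.layer_names]
    if at is None:
        X = grid.table()[:, order]
    else:
        X = np.vstack([grid.at(lat, lon)[order] for lat, lon in at])
    return (X - model.scaler_mean) / model.scaler_sd


def predict_composition(
    model: EnsembleModel,
    grid: CovariateGrid,
    at=None,
    keep_members: bool = False,
) -> CompositionPrediction:
    """Ensemble composition prediction with 95% percentile intervals.

    ``at`` is an iterable of (lat, lon) pairs; when omitted, predictions
    cover every grid pixel in row-major order. The interval is the
    2.5th–97.5th percentile of the member predictions, hence bounded in
    [0, 1] by construction and collapsing to the point prediction for a
    single-member ensemble.
    """
    X = _covariates_at(model, grid, at)
    member_preds = np.stack([
        _member_proba(clf, classes, X) for clf, classes in zip(model.members, model.member_classes)
    ])
    mean = member_preds.mean(axis=0)
    mean /= mean.sum(axis=1, keepdims=True)
    lower = np.percentile(member_preds, 2.5, axis=0)
    upper = np.percentile(member_preds, 97.5, axis=0)
    return CompositionPrediction(
        mean=mean, lower=lower, upper=upper,
        members=member_preds if keep_members else None,
    )


def predict_raster(model: EnsembleModel, grid: CovariateGrid, keep_members: bool = False):
    """Like :func:`predict_composition` over all pixels, reshaped to
    (4, rows, cols) rasters (plus member rasters when requested)."""
    pred = predict_composition(model, grid, at=None, keep_members=keep_members)
    rows, cols = grid.shape
    mean = pred.mean.T.reshape(len(LEAF_TYPES), rows, cols)
    members = None
    if keep_members:
        members = pred.members.transpose(0, 2, 1).reshape(len(model.members), len(LEAF_TYPES), rows, cols)
    return mean, members
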