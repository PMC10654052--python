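"""Model evaluation for multinomial composition predictions.

Because the four leaf-type probabilities within a pixel are not
independent, goodness of fit is measured with the Bhattacharyya
coefficient BC(O, P) = sum_i sqrt(O_i * P_i) between the observed and
predicted composition vectors, turned into a pseudo-R²:

    R2_BC = 1 - MAE_model / MAE_mean

where MAE_model averages the per-observation losses E_i = 1 - BC(O_i, P_i)
and MAE_mean averages the losses of the null model that always predicts
the mean observed composition. R2_BC is 1 only for perfect predictions
and <= 0 when the model does no better than the mean.

The module also provides per-class R² on each class's proportions,
plot-level k-fold cross-validation, spatially buffered leave-one-out
cross-validation on great-circle distances, and empirical semivariograms
of model residuals.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .composition import LEAF_TYPES, as_composition

logger = logging.getLogger(__name__)

#: Mean Earth radius (km) used for all great-circle distances.
EARTH_RADIUS_KM = 6371.0088


@dataclass
class EvaluationReport:
    """Summary statistics of one evaluation run."""

    r2_bc: float
    mae_model: float
    mae_mean: float
    per_class_r2: list[float] = field(default_factory=list)
    n_obs: int = 0
    scheme: str = ""

    def __post_init__(self):
        if self.mae_mean > 0:
            implied = 1 - self.mae_model / self.mae_mean
            if not np.isclose(implied, self.r2_bc, atol=1e-9):
                raise ValueError("r2_bc inconsistent with MAE_model / MAE_mean")


def bhattacharyya(observed, predicted) -> float:
    """Bhattacharyya coefficient sum_i sqrt(O_i * P_i) in [0, 1].

    Symmetric; equals 1 iff the vectors coincide and 0 iff their
    supports are disjoint.
    """
    o = as_composition(observed)
    p = as_composition(predicted)
    return float(np.minimum(np.sqrt(o * p).sum(), 1.0))


def _bc_rows(observed: np.ndarray, predicted: np.ndarray) -> np.ndarray:
    return np.minimum(np.sqrt(observed * predicted).sum(axis=1), 1.0)


def pseudo_r2(observed, predicted, scheme: str = "") -> EvaluationReport:
    """Bhattacharyya pseudo-R² over paired observed/predicted compositions.

    The null model predicts the element-wise mean of the observed
    compositions for every observation; order of observations is
    irrelevant.
    """
    obs = as_composition(np.atleast_2d(np.asarray(observed, dtype=float)))
    pred = as_composition(np.atleast_2d(np.asarray(predicted, dtype=float)))
    if obs.shape != pred.shape:
        raise ValueError("observed and predicted must have equal lengths")
    n = obs.shape[0]
    if n < 2:
        raise ValueError("pseudo_r2 requires at least 2 observations")

    mae_model = float(np.mean(1.0 - _bc_rows(obs, pred)))
    mean_comp = obs.mean(axis=0)
    mae_mean = float(np.mean(1.0 - _bc_rows(obs, np.broadcast_to(mean_comp, obs.shape))))
    r2 = 1.0 - mae_model / mae_mean if mae_mean > 0 else (1.0 if mae_model == 0 else -np.inf)

    per_class = [per_class_r2(obs, pred, k) for k in range(len(LEAF_TYPES))]
    return EvaluationReport(
        r2_bc=r2, mae_model=mae_model, mae_mean=mae_mean,
        per_class_r2=per_class, n_obs=n, scheme=scheme,
    )


def per_class_r2(observed, predicted, class_index: int) -> float:
    """Coefficient of determination 1 - SSE/SST on one class's proportions.

    NaN (flagged with a warning) when the observed class proportion has
    zero variance.
    """
    obs = np.atleast_2d(np.asarray(observed, dtype=float))[:, class_index]
    pred = np.atleast_2d(np.asarray(predicted, dtype=float))[:, class_index]
    if obs.shape[0] < 2:
        raise ValueError("per_class_r2 requires at least 2 observations")
    sst = float(np.sum((obs - obs.mean()) ** 2))
    if sst == 0:
        logger.warning("class %s has zero observed variance; R2 undefined", LEAF_TYPES[class_index])
        return float("nan")
    sse = float(np.sum((obs - pred) ** 2))
    return 1.0 - sse / sst


def assign_folds(n: int, k: int, seed: int) -> np.ndarray:
    """Balanced random fold labels in [0, k) for n units."""
    rng = np.random.default_rng(seed)
    labels = np.arange(n) % k
    rng.shuffle(labels)
    return labels


def kfold_cv(plots, observed, model_factory, k: int = 10, seed: int = 0) -> EvaluationReport:
    """Plot-level k-fold cross-validation scored with the pseudo-R².

    ``model_factory(train_plots, train_observed)`` must return a callable
    mapping a list of plots to an (n, 4) composition array. Folds are
    assigned at the plot level so multiple subsamples of a plot can never
    straddle the train/test boundary; out-of-fold predictions are pooled
    and scored once.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    plots = list(plots)
    obs = as_composition(np.asarray(observed, dtype=float))
    if len(plots) < k:
        raise ValueError(f"need at least k={k} plots, got {len(plots)}")
    folds = assign_folds(len(plots), k, seed)

    pred = np.empty_like(obs)
    for fold in range(k):
        test_idx = np.flatnonzero(folds == fold)
        train_idx = np.flatnonzero(folds != fold)
        predict = model_factory([plots[i] for i in train_idx], obs[train_idx])
        pred[test_idx] = predict([plots[i] for i in test_idx])
    return pseudo_r2(obs, pred, scheme=f"{k}-fold CV (plot-level folds, seed={seed})")


def haversine_km(lat1, lon1, lat2, lon2) -> np.ndarray:
    """Great-circle distance (km) on a sphere of radius 6371.0088 km."""
    lat1, lon1, lat2, lon2 = map(np.radians, (lat1, lon1, lat2, lon2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    h = np.sin(dlat / 2) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2) ** 2
    return 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(h))


def buffered_loo_cv(plots, observed, model_factory, radius_km: float = 0.0) -> EvaluationReport:
    """Spatially buffered leave-one-out cross-validation.

    Each plot is predicted by a model trained on all plots farther than
    ``radius_km`` great-circle distance away (at radius 0 this is classic
    leave-one-out). Plots whose buffer excludes every other plot are
    skipped with a warning. All retained predictions are scored jointly.
    """
    if radius_km < 0:
        raise ValueError("radius must be non-negative")
    plots = list(plots)
    obs = as_composition(np.asarray(observed, dtype=float))
    lats = np.array([p.lat for p in plots])
    lons = np.array([p.lon for p in plots])

    kept, preds = [], []
    for i in range(len(plots)):
        dist = haversine_km(lats[i], lons[i], lats, lons)
        train_idx = np.flatnonzero(dist > radius_km)
        train_idx = train_idx[train_idx != i]
        if train_idx.size == 0:
            logger.warning("plot %s: buffer of %.1f km excludes all training data; skipped",
                           plots[i].id, radius_km)
            continue
        predict = model_factory([plots[j] for j in train_idx], obs[train_idx])
        preds.append(np.asarray(predict([plots[i]]))[0])
        kept.append(i)
    if len(kept) < 2:
        raise ValueError("fewer than 2 plots evaluable under this buffer radius")
    return pseudo_r2(obs[kept], np.array(preds),
                     scheme=f"buffered LOO-CV (radius {radius_km:g} km)")


def empirical_semivariogram(residuals, lats, lons, bin_edges_km) -> "pd.DataFrame":
    """Empirical semivariogram of residual vectors over distance bins.

    gamma(h) = mean of squared residual differences / 2 within each
    great-circle distance bin, computed per composition class and then
    averaged across classes. Empty bins yield NaN.
    """
    import pandas as pd

    res = np.asarray(residuals, dtype=float)
    if res.ndim == 1:
        res = res[:, None]
    if res.shape[0] < 2:
        raise ValueError("need at least 2 points")
    lats = np.asarray(lats, dtype=float)
    lons = np.asarray(lons, dtype=float)
    edges = np.asarray(bin_edges_km, dtype=float)

    iu, ju = np.triu_indices(res.shape[0], k=1)
    dist = haversine_km(lats[iu], lons[iu], lats[ju], lons[ju])
    sq = 0.5 * np.mean((res[iu] - res[ju]) ** 2, axis=1)  # per-class average

    which = np.digitize(dist, edges) - 1
    rows = []
    for b in range(len(edges) - 1):
        mask = which == b
        rows.append({
            "lag_lo_km": edges[b],
            "lag_hi_km": edges[b + 1],
            "semivariance": float(np.mean(sq[mask])) if mask.any() else float("nan"),
            "n_pairs": int(mask.sum()),
        })
    return pd.DataFrame(rows)
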