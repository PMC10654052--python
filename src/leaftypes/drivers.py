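"""Environmental driver attribution and extrapolation diagnostics.

To compare the influence of climate, soil, topography and vegetation on
leaf-type variation without drowning in collinearity, each multi-layer
group is reduced to its first principal components (vegetation's few
layers pass through untouched), the combined predictor set is screened
with variance inflation factors (gate: all VIF < 4), and regression
forests on the plot-level habit (evergreen share) and form (broadleaf
share) targets are ranked; the impurity importances of the ten best
models, normalized to sum to one, give the relative importance table
with a 95% CI across those models.

The convex-hull diagnostic checks interpolation vs extrapolation: the
prediction domain is projected into the training PCA space and each
point is tested against the convex hulls of every bivariate principal
component pair.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull, Delaunay, QhullError
from sklearn.decomposition import PCA
from sklearn.ensemble import RandomForestRegressor
from sklearn.linear_model import LinearRegression

logger = logging.getLogger(__name__)

VIF_GATE = 4.0

#: Hyperparameter sub-grid for the importance models: variables per split
#: 1..12 and minimum terminal-node size 1..10.
IMPORTANCE_GRID: dict[str, tuple] = {
    "mtry": tuple(range(1, 13)),
    "min_node": tuple(range(1, 11)),
}


@dataclass
class GroupPCA:
    """Scores and diagnostics for one covariate group's PCA."""

    group: str
    scores: np.ndarray  # (n, n_components) or passthrough
    component_names: list[str]
    explained_variance_ratio: np.ndarray | None  # None for passthrough
    passthrough: bool
    meets_min_variance: bool


def group_pca(
    features: pd.DataFrame,
    group: str,
    min_variance: float = 0.90,
    n_components: int = 6,
) -> GroupPCA:
    """First principal components of one covariate group.

    Features are centered and scaled before the decomposition. Groups
    with at most ``n_components`` members are passed through unchanged —
    the treatment given to the small vegetation group. Constant columns
    are dropped with a warning; a cumulative explained variance below
    ``min_variance`` raises a warning, not an error.
    """
    X = features.to_numpy(dtype=float)
    keep = X.std(axis=0) > 0
    if not keep.all():
        dropped = [c for c, k in zip(features.columns, keep) if not k]
        logger.warning("dropping constant features in group %s: %s", group, dropped)
        X = X[:, keep]
        features = features.loc[:, keep]
    if X.shape[1] == 0:
        raise ValueError(f"group {group} has no non-constant features")

    if X.shape[1] <= n_components:
        return GroupPCA(
            group=group, scores=X.copy(), component_names=list(features.columns),
            explained_variance_ratio=None, passthrough=True, meets_min_variance=True,
        )

    Xs = (X - X.mean(axis=0)) / X.std(axis=0)
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(Xs)
    evr = pca.explained_variance_ratio_
    meets = bool(evr.sum() >= min_variance)
    if not meets:
        logger.warning(
            "group %s: first %d PCs explain %.1f%% < %.0f%%",
            group, n_components, 100 * evr.sum(), 100 * min_variance,
        )
    names = [f"{group}_PC{i + 1}" for i in range(n_components)]
    return GroupPCA(group=group, scores=scores, component_names=names,
                    explained_variance_ratio=evr, passthrough=False, meets_min_variance=meets)


def vif(features: pd.DataFrame) -> pd.Series:
    """Variance inflation factor of every feature.

    VIF_i = 1 / (1 - R_i^2) from regressing feature i on all the others;
    perfect collinearity yields ``inf``. Use :func:`vif_gate_passes` for
    the <4 screening decision.
    """
    X = features.to_numpy(dtype=float)
    if X.shape[1] < 2:
        raise ValueError("VIF requires at least 2 features")
    if np.any(X.std(axis=0) == 0):
        raise ValueError("constant columns have undefined VIF; drop them first")
    out = {}
    for i, col in enumerate(features.columns):
        other = np.delete(X, i, axis=1)
        r2 = LinearRegression().fit(other, X[:, i]).score(other, X[:, i])
        out[col] = float("inf") if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return pd.Series(out, name="vif")


def vif_gate_passes(features: pd.DataFrame, threshold: float = VIF_GATE) -> bool:
    """True when every feature's VIF is below the collinearity gate."""
    return bool((vif(features) < threshold).all())


def importance_ranking(
    predictors: pd.DataFrame,
    target: np.ndarray,
    target_name: str = "habit",
    grid_spec: dict[str, tuple] | None = None,
    n_best: int = 10,
    n_trees: int = 100,
    seed: int = 0,
) -> pd.DataFrame:
    """Relative variable importance from the ten best regression forests.

    One forest per hyperparameter combination is fitted on the
    continuous plot-level target (evergreen share for habit, broadleaf
    share for form), ranked by out-of-bag R²; impurity
    (squared-error-reduction) importances of the ``n_best`` top models
    are normalized to sum to one per model, then summarized by their
    mean, 95% CI and rank. Column order of ``predictors`` is irrelevant.
    """
    spec = dict(IMPORTANCE_GRID if grid_spec is None else grid_spec)
    y = np.asarray(target, dtype=float)
    # canonical column order: forests sample features positionally, so this
    # makes the ranking exactly invariant to the caller's column order
    predictors = predictors[sorted(predictors.columns)]
    X = predictors.to_numpy(dtype=float)
    p = X.shape[1]

    combos = [
        (mtry, node) for mtry, node in itertools.product(spec["mtry"], spec["min_node"])
        if mtry <= p
    ]
    fits = []
    for i, (mtry, node) in enumerate(combos):
        rf = RandomForestRegressor(
            n_estimators=n_trees, max_features=mtry, min_samples_leaf=node,
            oob_score=True, bootstrap=True, random_state=seed + i, n_jobs=1,
        )
        rf.fit(X, y)
        fits.append((rf.oob_score_, rf.feature_importances_))
    if len(fits) < n_best:
        logger.warning("only %d fitted models available for top-%d selection", len(fits), n_best)
    fits.sort(key=lambda t: t[0], reverse=True)
    best = fits[: min(n_best, len(fits))]

    imp = np.vstack([im / im.sum() for _, im in best])  # each model normalized
    mean_imp = imp.mean(axis=0)
    mean_imp = mean_imp / mean_imp.sum()
    lo = np.percentile(imp, 2.5, axis=0)
    hi = np.percentile(imp, 97.5, axis=0)

    table = pd.DataFrame({
        "predictor": list(predictors.columns),
        "target": target_name,
        "importance": mean_imp,
        "ci_lower": lo,
        "ci_upper": hi,
    }).sort_values("importance", ascending=False, kind="stable").reset_index(drop=True)
    table["rank"] = np.arange(1, len(table) + 1)
    return table


def convex_hull_coverage(
    train: np.ndarray,
    predict: np.ndarray,
    n_components: int = 6,
    coverage_threshold: float = 0.90,
) -> dict:
    """Interpolation diagnostic over bivariate principal-component hulls.

    A PCA is fitted on the (centered, scaled) training covariates; both
    sets are projected with the training statistics and eigenvectors.
    For each of the C(n_components, 2) PC pairs, each prediction point
    is tested against the convex hull of the training points (boundary
    counts as inside). Returns the per-point fraction of hulls covering
    it and the share of points inside at least ``coverage_threshold`` of
    the hulls.
    """
    train = np.asarray(train, dtype=float)
    predict = np.asarray(predict, dtype=float)
    if n_components < 2:
        raise ValueError("need at least 2 principal components")
    if train.shape[0] < 3:
        raise ValueError("convex hulls require at least 3 training points")

    mean = train.mean(axis=0)
    sd = train.std(axis=0)
    sd[sd == 0] = 1.0
    n_components = min(n_components, train.shape[1])
    pca = PCA(n_components=n_components, svd_solver="full")
    train_pc = pca.fit_transform((train - mean) / sd)
    pred_pc = pca.transform((predict - mean) / sd)

    pairs = list(itertools.combinations(range(n_components), 2))
    inside = np.zeros((predict.shape[0], len(pairs)), dtype=bool)
    for k, (i, j) in enumerate(pairs):
        pts = train_pc[:, [i, j]]
        try:
            hull = ConvexHull(pts)
            tri = Delaunay(pts[hull.vertices])
            inside[:, k] = tri.find_simplex(pred_pc[:, [i, j]]) >= 0
        except QhullError:  # degenerate (collinear) training cloud
            logger.warning("degenerate hull for PC pair (%d, %d); counted as not covering", i + 1, j + 1)
    frac = inside.mean(axis=1)
    return {
        "n_pairs": len(pairs),
        "point_coverage": frac,
        "fraction_covered": float(np.mean(frac >= coverage_threshold)),
        "coverage_threshold": coverage_threshold,
    }
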