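"""Forest-type classification and climate-envelope risk assessment.

A pixel is labelled with a leaf type when that type's share of the
forest area strictly exceeds a dominance threshold (default 60%),
otherwise "mixed". Projecting the fitted composition model onto future
climate layers — soil, topography and vegetation held constant — and
re-labelling identifies pixels whose *future climate* matches conditions
that *currently* support a different forest type. This is a risk screen,
not a projection of actual vegetation change.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .composition import LEAF_TYPES, broadleaf_share, evergreen_share
from .ensemble import EnsembleModel, predict_raster
from .landscape import CovariateGrid

#: Integer palette for label rasters.
MIXED = 0
LABEL_CODES: dict[str, int] = {"mixed": MIXED, "BE": 1, "BD": 2, "NE": 3, "ND": 4}
CODE_LABELS: dict[int, str] = {v: k for k, v in LABEL_CODES.items()}


@dataclass
class ScenarioProjection:
    """Present vs future compositions and labels for one emission scenario."""

    scenario: str
    per_model_compositions: list[np.ndarray]  # one (4, rows, cols) raster per climate model
    future_composition: np.ndarray  # mean over climate models
    present_composition: np.ndarray
    present_labels: np.ndarray
    future_labels: np.ndarray
    threshold: float


def classify_forest_type(composition: np.ndarray, threshold: float = 0.60) -> np.ndarray:
    """Dominance labels for a composition raster or vector.

    Returns integer codes (see :data:`LABEL_CODES`): the unique leaf
    type whose share strictly exceeds ``threshold``, else mixed. A
    threshold at or below 0.25 could crown two winners and is rejected.
    """
    if not 0.25 < threshold <= 1.0:
        raise ValueError("threshold must be in (0.25, 1]")
    comp = np.asarray(composition, dtype=float)
    vec = comp.ndim == 1
    if vec:
        comp = comp[:, None]
    if comp.shape[0] != len(LEAF_TYPES):
        raise ValueError("composition stack must have 4 leading classes")
    winner = comp.argmax(axis=0)
    dominant = np.take_along_axis(comp, winner[None], axis=0)[0] > threshold
    labels = np.where(dominant, winner + 1, MIXED)
    return int(labels[0]) if vec else labels


def project_future(
    model: EnsembleModel,
    present: CovariateGrid,
    future_grids: list[CovariateGrid],
    scenario: str,
    threshold: float = 0.60,
) -> ScenarioProjection:
    """Project the composition model under future climate layers.

    Each future grid must differ from the present only in climate-group
    layers (verified). Per climate model the ensemble members are
    averaged; the scenario composition is the mean over climate models.
    Labels are computed from the present prediction and the aggregated
    future prediction at the same threshold.
    """
    for fg in future_grids:
        if fg.names != present.names:
            raise ValueError("future grid layers must match the present grid")
        for name in fg.names:
            if present.groups[name] != "climate":
                if not np.array_equal(fg.layer(name), present.layer(name)):
                    raise ValueError(
                        f"non-climate layer {name!r} was altered in a future grid"
                    )
    present_comp, _ = predict_raster(model, present)
    per_model = [predict_raster(model, fg)[0] for fg in future_grids]
    future_comp = np.mean(per_model, axis=0) if per_model else present_comp.copy()
    return ScenarioProjection(
        scenario=scenario,
        per_model_compositions=per_model,
        future_composition=future_comp,
        present_composition=present_comp,
        present_labels=classify_forest_type(present_comp, threshold),
        future_labels=classify_forest_type(future_comp, threshold),
        threshold=threshold,
    )


def risk_assessment(
    present_labels: np.ndarray,
    future_labels: np.ndarray,
    canopy_cover: np.ndarray,
    areas: np.ndarray,
    present_threshold: float | None = None,
    future_threshold: float | None = None,
) -> dict:
    """Canopy-scaled area whose future climate supports a different type.

    Forested pixels are those with canopy cover > 0. The shifted area is
    the canopy-cover-weighted area where the present and future labels
    differ; the fraction normalizes by the total canopy-scaled forest
    area. Label rasters classified at different thresholds are rejected.
    """
    if present_threshold is not None and future_threshold is not None:
        if present_threshold != future_threshold:
            raise ValueError("present and future labels use different dominance thresholds")
    for r in (future_labels, canopy_cover, areas):
        if r.shape != present_labels.shape:
            raise ValueError("rasters are not aligned on one grid")
    forest = canopy_cover > 0
    weight = canopy_cover * areas
    total = float(weight[forest].sum())
    shifted_mask = forest & (present_labels != future_labels)
    shifted = float(weight[shifted_mask].sum())
    return {
        "shifted_area_km2": shifted,
        "forest_area_km2": total,
        "shifted_fraction": shifted / total if total > 0 else 0.0,
        "shifted_mask": shifted_mask,
    }


def latitudinal_summary(
    composition: np.ndarray,
    lats: np.ndarray,
    areas: np.ndarray,
    future_composition: np.ndarray | None = None,
    band_width: float = 0.5,
) -> pd.DataFrame:
    """Area-weighted habit/form marginals per latitudinal band.

    Bands are ``band_width``-degree bins of pixel-center latitude. Each
    band reports the mean evergreen share (habit margin) and broadleaf
    share (form margin); when a future composition is supplied, the
    future-minus-present deltas are included. Empty bands are absent
    from the output.
    """
    comp = np.asarray(composition, dtype=float)
    lat_r = np.repeat(np.asarray(lats, dtype=float)[:, None], comp.shape[2], axis=1)
    band = np.floor(lat_r / band_width) * band_width

    def _marginals(c):
        per_pixel = c.reshape(len(LEAF_TYPES), -1).T
        return evergreen_share(per_pixel), broadleaf_share(per_pixel)

    ever, broad = _marginals(comp)
    w = np.asarray(areas, dtype=float).ravel()
    b = band.ravel()
    rows = []
    for bv in np.unique(b):
        mask = b == bv
        ww = w[mask]
        if ww.sum() <= 0:
            continue
        row = {
            "band_lat": float(bv),
            "evergreen_share": float(np.average(ever[mask], weights=ww)),
            "broadleaf_share": float(np.average(broad[mask], weights=ww)),
            "area_km2": float(ww.sum()),
        }
        if future_composition is not None:
            fe, fb = _marginals(np.asarray(future_composition, dtype=float))
            row["delta_evergreen"] = float(np.average(fe[mask], weights=ww)) - row["evergreen_share"]
            row["delta_broadleaf"] = float(np.average(fb[mask], weights=ww)) - row["broadleaf_share"]
        rows.append(row)
    return pd.DataFrame(rows).sort_values("band_lat").reset_index(drop=True)
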