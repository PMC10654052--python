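"""Leaf-type composition vectors.

A composition is a length-4 probability vector over the four leaf-type
classes — broadleaved evergreen (BE), broadleaved deciduous (BD),
needle-leaved evergreen (NE) and needle-leaved deciduous (ND) — the
universal response object of the pipeline: plot-level observed
proportions, model predictions and per-pixel map values all share it.

Compositions are plain ``numpy`` arrays (single vectors of shape ``(4,)``
or stacks of shape ``(n, 4)``); this module owns the class order, the
validation rules and the habit/form marginals.
"""

from __future__ import annotations

import numpy as np

#: Canonical class order used everywhere: (BE, BD, NE, ND).
LEAF_TYPES: tuple[str, ...] = ("BE", "BD", "NE", "ND")

#: Index lookup for a single class label.
LEAF_TYPE_INDEX: dict[str, int] = {t: i for i, t in enumerate(LEAF_TYPES)}

_SUM_TOL = 1e-9


def as_composition(values, *, tol: float = _SUM_TOL) -> np.ndarray:
    """Coerce ``values`` to a valid composition array.

    Accepts a single 4-vector or an ``(n, 4)`` stack. Components must be
    non-negative and each row must sum to 1 within ``tol``.

    Raises
    ------
    ValueError
        If the shape is wrong, any component is negative, or a row does
        not sum to one.
    """
    arr = np.asarray(values, dtype=float)
    if arr.shape[-1] != len(LEAF_TYPES):
        raise ValueError(f"composition must have {len(LEAF_TYPES)} classes, got shape {arr.shape}")
    if np.any(arr < 0):
        raise ValueError("composition components must be non-negative")
    sums = arr.sum(axis=-1)
    if not np.allclose(sums, 1.0, rtol=0, atol=tol):
        bad = np.abs(sums - 1.0).max()
        raise ValueError(f"composition rows must sum to 1 (max deviation {bad:.3g})")
    return arr


def is_valid_composition(values, *, tol: float = _SUM_TOL) -> bool:
    """True if ``values`` passes :func:`as_composition` validation."""
    try:
        as_composition(values, tol=tol)
    except ValueError:
        return False
    return True


def evergreen_share(comp: np.ndarray) -> np.ndarray:
    """Leaf-habit marginal: BE + NE (evergreen fraction)."""
    comp = np.asarray(comp, dtype=float)
    return comp[..., LEAF_TYPE_INDEX["BE"]] + comp[..., LEAF_TYPE_INDEX["NE"]]


def broadleaf_share(comp: np.ndarray) -> np.ndarray:
    """Leaf-form marginal: BE + BD (broadleaf fraction)."""
    comp = np.asarray(comp, dtype=float)
    return comp[..., LEAF_TYPE_INDEX["BE"]] + comp[..., LEAF_TYPE_INDEX["BD"]]


def leaf_type_of(habit: str, form: str) -> str:
    """Combine a habit ('evergreen'|'deciduous') and a form
    ('broadleaf'|'needleleaf') into a class label."""
    f = {"broadleaf": "B", "needleleaf": "N"}[form]
    h = {"evergreen": "E", "deciduous": "D"}[habit]
    return f + h
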