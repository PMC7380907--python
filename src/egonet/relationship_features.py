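"""Pairwise relationship signatures and the padded 18x20 feature grid.

For every unordered pair of the 15 calibrated SIS items three signatures
are computed: the interaction term I = s_i * s_j, the harmonic mean
H = 2*s_i*s_j / (s_i + s_j), and the tangent of the angle difference
T = (s_i - s_j) / (1 + s_i*s_j) = tan(arctan s_i - arctan s_j), which is
antisymmetric and so distinguishes the two orderings of a pair.

The 105 pairs x 3 types give 315 relationship features per subject; the
per-subject model input is an 18x20 grid filled row-major with the 15
calibrated items, the 14 confounders, 7 structural zeros, the 315
relationship features and 9 trailing structural zeros.
"""

from __future__ import annotations

import numpy as np

from .io_cohort import CohortTable

__all__ = [
    "N_ITEMS",
    "N_PAIRS",
    "N_RELATIONSHIP",
    "GRID_SHAPE",
    "PAIRS",
    "pair_index",
    "interaction",
    "harmonic",
    "tangent_diff",
    "build_relationship_vector",
    "assemble_grid",
    "flatten_grid",
    "grid_layout",
    "cohort_to_grids",
]

N_ITEMS = 15
#: unordered item pairs (1-based, i < j), lexicographic
PAIRS = [(i, j) for i in range(1, N_ITEMS + 1) for j in range(i + 1, N_ITEMS + 1)]
N_PAIRS = len(PAIRS)  # 105
TYPES = ("I", "H", "T")
N_RELATIONSHIP = N_PAIRS * len(TYPES)  # 315

GRID_SHAPE = (18, 20)
_BASE_SLICE = slice(0, 29)  # 15 SIS + 14 confounders
_PAD1_SLICE = slice(29, 36)  # 7 structural zeros
_REL_SLICE = slice(36, 351)  # 315 relationship features
_PAD2_SLICE = slice(351, 360)  # 9 structural zeros
STRUCTURAL_ZERO_POSITIONS = tuple(range(29, 36)) + tuple(range(351, 360))

_PAIR_POS = {pair: 3 * k for k, pair in enumerate(PAIRS)}


def pair_index(i: int, j: int, kind: str) -> int:
    """Flat position of signature ``kind`` for item pair (i, j), 1-based.

    Pairs are ordered lexicographically with the three types I, H, T
    consecutive per pair, so (1, 2, 'I') sits at 0 and (14, 15, 'T')
    at 314.
    """
    if not (1 <= i < j <= N_ITEMS):
        raise ValueError(f"invalid item pair ({i}, {j}); need 1 <= i < j <= 15")
    return _PAIR_POS[(i, j)] + TYPES.index(kind)


def _check_domain(*scores) -> None:
    for s in scores:
        arr = np.asarray(s, dtype=float)
        if ((arr < 1) | (arr > 3)).any():
            raise ValueError(f"calibrated score {s!r} outside [1, 3]")


def interaction(s_i, s_j):
    """Interaction term: the product of two calibrated scores."""
    _check_domain(s_i, s_j)
    return s_i * s_j


def harmonic(s_i, s_j):
    """Harmonic mean of two calibrated scores."""
    _check_domain(s_i, s_j)
    return 2.0 * s_i * s_j / (s_i + s_j)


def tangent_diff(s_i, s_j):
    """Tangent of the angle difference: tan(arctan s_i - arctan s_j)."""
    _check_domain(s_i, s_j)
    return (s_i - s_j) / (1.0 + s_i * s_j)


def build_relationship_vector(sis_cal) -> np.ndarray:
    """All 315 relationship signatures for one subject, canonical order."""
    s = np.asarray(sis_cal, dtype=float)
    if s.shape != (N_ITEMS,):
        raise ValueError(f"expected {N_ITEMS} calibrated scores, got shape {s.shape}")
    _check_domain(s)
    iu, ju = np.triu_indices(N_ITEMS, k=1)  # lexicographic (i, j) pairs
    a, b = s[iu], s[ju]
    out = np.empty(N_RELATIONSHIP)
    out[0::3] = a * b
    out[1::3] = 2.0 * a * b / (a + b)
    out[2::3] = (a - b) / (1.0 + a * b)
    return out


def assemble_grid(sis_cal, confounders, rel) -> np.ndarray:
    """Fill the 18x20 grid row-major: [SIS | confounders | 0x7 | rel | 0x9]."""
    sis_cal = np.asarray(sis_cal, dtype=float)
    confounders = np.asarray(confounders, dtype=float)
    rel = np.asarray(rel, dtype=float)
    if sis_cal.shape != (15,) or confounders.shape != (14,) or rel.shape != (315,):
        raise ValueError(
            "expected 15 SIS scores, 14 confounders and 315 relationship "
            f"features; got {sis_cal.shape}, {confounders.shape}, {rel.shape}"
        )
    flat = np.zeros(GRID_SHAPE[0] * GRID_SHAPE[1])
    flat[0:15] = sis_cal
    flat[15:29] = confounders
    flat[_REL_SLICE] = rel
    return flat.reshape(GRID_SHAPE)


def flatten_grid(grid: np.ndarray) -> np.ndarray:
    """Row-major flattening, the inverse of the grid layout."""
    grid = np.asarray(grid, dtype=float)
    if grid.shape != GRID_SHAPE:
        raise ValueError(f"expected grid of shape {GRID_SHAPE}, got {grid.shape}")
    return grid.reshape(-1)


def grid_layout() -> list[dict]:
    """Per-cell description of the grid (for layout JSON sidecars)."""
    cells = []
    for pos in range(GRID_SHAPE[0] * GRID_SHAPE[1]):
        row, col = divmod(pos, GRID_SHAPE[1])
        if pos < 15:
            meaning = {"kind": "sis", "item": pos + 1}
        elif pos < 29:
            meaning = {"kind": "confounder", "index": pos - 15}
        elif pos < 36 or pos >= 351:
            meaning = {"kind": "structural_zero"}
        else:
            k, t = divmod(pos - 36, 3)
            i, j = PAIRS[k]
            meaning = {"kind": "relationship", "pair": [i, j], "type": TYPES[t]}
        cells.append({"position": pos, "row": row, "col": col, **meaning})
    return cells


def cohort_to_grids(table: CohortTable, with_relationships: bool = True):
    """Per-subject grids and labels for a fully imputed, labelled cohort.

    Returns ``(grids, labels)`` with grids of shape (n, 18, 20).  With
    ``with_relationships=False`` the relationship block is left at zero
    (the ablation input), keeping the grid shape unchanged.
    """
    sis_cal = table.sis_cal
    conf = table.confounders
    labels = table.lethal
    if np.isnan(sis_cal).any() or np.isnan(conf).any() or np.isnan(labels).any():
        raise ValueError("cohort must be imputed and labelled before gridding")
    n = table.n
    grids = np.zeros((n,) + GRID_SHAPE)
    for s in range(n):
        rel = (
            build_relationship_vector(sis_cal[s])
            if with_relationships
            else np.zeros(N_RELATIONSHIP)
        )
        grids[s] = assemble_grid(sis_cal[s], conf[s], rel)
    return grids, labels.astype(int)
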