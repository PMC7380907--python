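"""Gradient*input feature-importance maps for the CNN classifier.

Each cell's importance is the product of its input value with the gradient
of the target-class pre-softmax logit with respect to that cell, computed
on the scaled grid the network actually sees.  Class maps are averaged in
two stages: within each cross-validation fold over the class members, then
across folds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .models import TrainedModel, apply_scaler
from .relationship_features import GRID_SHAPE

__all__ = ["ImportanceMap", "gradient_x_input", "class_averaged_importance"]


@dataclass
class ImportanceMap:
    """Per-class mean importance grids with averaging provenance."""

    nonlethal: np.ndarray  # 18x20
    lethal: np.ndarray  # 18x20
    folds_used: dict


def gradient_x_input(model: TrainedModel, grids: np.ndarray,
                     target: np.ndarray | None = None) -> np.ndarray:
    """Gradient*input attribution per subject, shape (n, 18, 20).

    ``target`` selects the logit differentiated per subject (default: the
    predicted class).  Zero-valued input cells — in particular the
    structural zeros — always receive importance exactly 0.
    """
    if model.kind != "egonet":
        raise TypeError(f"gradient_x_input needs a differentiable model, "
                        f"got kind {model.kind!r}")
    g = np.asarray(grids, dtype=float)
    if g.ndim == 2:
        g = g[None]
    x = apply_scaler(g, model.scaler)
    if target is None:
        target = model.estimator.predict_proba(x).argmax(axis=1)
    grad = model.estimator.input_gradient(x, np.asarray(target))
    return grad * x


def class_averaged_importance(fold_models: list, grids: np.ndarray,
                              labels: np.ndarray,
                              folds: np.ndarray) -> ImportanceMap:
    """Two-stage class-mean importance over cross-validation folds.

    For each fold, the gradient*input maps of that fold's test subjects
    are averaged per class (targeting each subject's true class); the
    fold means are then averaged.  Folds with no members of a class are
    skipped for that class and recorded in ``folds_used``.
    """
    labels = np.asarray(labels).astype(int)
    folds = np.asarray(folds).astype(int)
    per_class_fold_means = {0: [], 1: []}
    folds_used = {0: [], 1: []}
    for fold, model in enumerate(fold_models):
        test_idx = np.flatnonzero(folds == fold)
        if test_idx.size == 0:
            continue
        maps = gradient_x_input(model, grids[test_idx], target=labels[test_idx])
        for cls in (0, 1):
            members = labels[test_idx] == cls
            if not members.any():
                continue
            per_class_fold_means[cls].append(maps[members].mean(axis=0))
            folds_used[cls].append(fold)
    out = {}
    for cls in (0, 1):
        if per_class_fold_means[cls]:
            out[cls] = np.mean(per_class_fold_means[cls], axis=0)
        else:
            out[cls] = np.full(GRID_SHAPE, np.nan)
    return ImportanceMap(
        nonlethal=out[0], lethal=out[1],
        folds_used={"nonlethal": folds_used[0], "lethal": folds_used[1]},
    )
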