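"""Cross-validation harness and the imbalance-aware metric suite.

Includes stratified k-fold assignment, confusion-matrix metrics (PPV, NPV,
sensitivity, specificity, accuracy, weighted F1) and a from-scratch
precision-recall-gain curve with its area (AUPRG): precision and recall
are rescaled against the prevalence baseline, so a no-skill classifier
gains 0 and a perfect one 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .models import (
    EGONetConfig,
    apply_scaler,
    fit_scaler,
    predict,
    train_baseline,
    train_egonet,
)

__all__ = [
    "PRGCurve",
    "CVReport",
    "stratified_folds",
    "confusion_metrics",
    "prg_curve",
    "auprg",
    "proportion_pct",
    "run_cv",
    "METRIC_NAMES",
]

METRIC_NAMES = ("weighted_f1", "ppv", "npv", "sensitivity", "specificity",
                "accuracy", "auprg")


def stratified_folds(labels, k: int, seed: int = 0) -> np.ndarray:
    """Assign each subject to one of ``k`` stratified folds.

    Within each class, subjects are shuffled and dealt round-robin, so
    every fold's class count is within one subject of the global ratio.
    Returns an integer fold index per subject.
    """
    y = np.asarray(labels).astype(int)
    if k < 2:
        raise ValueError("k must be at least 2")
    for cls in np.unique(y):
        if (y == cls).sum() < k:
            raise ValueError(
                f"class {cls} has {(y == cls).sum()} members < k={k}; use a smaller k"
            )
    rng = np.random.default_rng(seed)
    folds = np.empty(len(y), dtype=int)
    for cls in np.unique(y):
        idx = rng.permutation(np.flatnonzero(y == cls))
        folds[idx] = np.arange(idx.size) % k
    return folds


def confusion_metrics(y_true, y_pred) -> dict:
    """Standard confusion-matrix metrics for a binary task.

    The positive class is 1 (lethal).  Weighted F1 is the class-support
    weighted mean of the two per-class F1 scores.  Ratios with a zero
    denominator are reported as 0.0 and listed under ``"degenerate"``.
    """
    t = np.asarray(y_true).astype(int)
    p = np.asarray(y_pred).astype(int)
    if t.shape != p.shape:
        raise ValueError(f"length mismatch: {t.shape} vs {p.shape}")
    tp = int(((t == 1) & (p == 1)).sum())
    fp = int(((t == 0) & (p == 1)).sum())
    fn = int(((t == 1) & (p == 0)).sum())
    tn = int(((t == 0) & (p == 0)).sum())
    degenerate = []

    def ratio(num, den, name):
        if den == 0:
            degenerate.append(name)
            return 0.0
        return num / den

    ppv = ratio(tp, tp + fp, "ppv")
    npv = ratio(tn, tn + fn, "npv")
    sens = ratio(tp, tp + fn, "sensitivity")
    spec = ratio(tn, tn + fp, "specificity")
    acc = (tp + tn) / t.size
    f1_pos = ratio(2 * tp, 2 * tp + fp + fn, "f1_pos")
    f1_neg = ratio(2 * tn, 2 * tn + fn + fp, "f1_neg")
    n_pos, n_neg = tp + fn, tn + fp
    weighted_f1 = (n_pos * f1_pos + n_neg * f1_neg) / t.size
    return {
        "ppv": ppv, "npv": npv, "sensitivity": sens, "specificity": spec,
        "accuracy": acc, "weighted_f1": weighted_f1,
        "tp": tp, "fp": fp, "fn": fn, "tn": tn, "degenerate": degenerate,
    }


@dataclass
class PRGCurve:
    """Precision-recall-gain operating points, sorted by recall gain."""

    recall_gain: np.ndarray
    precision_gain: np.ndarray
    prevalence: float


def prg_curve(y_true, scores) -> PRGCurve:
    """Precision-recall-gain curve over all score thresholds.

    For each threshold (predict positive when score >= t, tied scores
    collapsed to one operating point): precision gain
    (prec - pi) / ((1 - pi) * prec) and recall gain
    (rec - pi) / ((1 - pi) * rec), with pi the prevalence.  Points with
    negative recall gain are dropped; negative precision gains are kept.
    The curve is extended flat to recall gain 0 and always reaches the
    all-positive point (recall gain 1, precision gain 0).
    """
    y = np.asarray(y_true).astype(int)
    s = np.asarray(scores, dtype=float)
    if y.shape != s.shape:
        raise ValueError("labels and scores differ in length")
    n_pos = int(y.sum())
    if n_pos == 0 or n_pos == y.size:
        raise ValueError("prevalence is degenerate (one-class truth)")
    pi = n_pos / y.size

    order = np.argsort(-s, kind="stable")
    y_sorted = y[order]
    s_sorted = s[order]
    tp_cum = np.cumsum(y_sorted)
    pred_pos = np.arange(1, y.size + 1)
    # keep only the last index of each tied score block (one operating point)
    keep = np.flatnonzero(np.r_[s_sorted[1:] != s_sorted[:-1], True])
    prec = tp_cum[keep] / pred_pos[keep]
    rec = tp_cum[keep] / n_pos

    with np.errstate(divide="ignore", invalid="ignore"):
        pg = (prec - pi) / ((1 - pi) * prec)
        rg = (rec - pi) / ((1 - pi) * rec)
    rg = np.where(rec == 0, -np.inf, rg)
    ok = rg >= 0
    rg, pg = rg[ok], pg[ok]
    if rg.size == 0 or rg[0] > 0:  # flat extension down to recall gain 0
        first_pg = pg[0] if pg.size else 0.0
        rg = np.r_[0.0, rg]
        pg = np.r_[first_pg, pg]
    order = np.argsort(rg, kind="stable")
    return PRGCurve(rg[order], pg[order], pi)


def auprg(curve: PRGCurve) -> float:
    """Trapezoidal area under the PRG curve over recall gain in [0, 1]."""
    return float(np.trapezoid(curve.precision_gain, curve.recall_gain))


def proportion_pct(numerator: float, denominator: float, decimals: int = 1) -> float:
    """Percentage ``100 * numerator / denominator`` rounded to ``decimals``."""
    if denominator == 0:
        raise ZeroDivisionError("denominator is zero")
    return round(100.0 * numerator / denominator, decimals)


@dataclass
class CVReport:
    """Per-fold and aggregate cross-validation metrics for one model."""

    kind: str
    per_fold: list  # one metric dict per (trial, fold)
    mean: dict
    sd: dict
    sd_across_trials: dict
    n_folds: int
    n_trials: int
    seeds: dict
    flags: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "per_fold": self.per_fold,
            "mean": self.mean,
            "sd": self.sd,
            "sd_across_trials": self.sd_across_trials,
            "n_folds": self.n_folds,
            "n_trials": self.n_trials,
            "seeds": self.seeds,
            "flags": self.flags,
        }


def _fit_and_score(grids, labels, train_idx, test_idx, kind, seed,
                   egonet_config, n_trees, flags, trial, fold):
    scaler = fit_scaler(grids[train_idx])
    if kind == "egonet":
        cfg_kwargs = {**(egonet_config.__dict__ if egonet_config else {}),
                      "seed": seed}
        model = train_egonet(grids[train_idx], labels[train_idx],
                             EGONetConfig(**cfg_kwargs), scaler=scaler)
    else:
        model = train_baseline(grids[train_idx], labels[train_idx], kind,
                               seed=seed, scaler=scaler, n_trees=n_trees)
    prob, pred = predict(model, grids[test_idx])
    metrics = confusion_metrics(labels[test_idx], pred)
    y_test = labels[test_idx]
    if 0 < y_test.sum() < y_test.size:
        metrics["auprg"] = auprg(prg_curve(y_test, prob))
    else:
        metrics["auprg"] = np.nan
        flags.append(f"trial {trial} fold {fold}: one-class test fold, AUPRG skipped")
    return metrics, model


def run_cv(grids, labels, kinds=("egonet", "linreg", "rf"), k: int = 10,
           n_trials: int = 1, seed: int = 0,
           egonet_config: EGONetConfig | None = None,
           n_trees: int = 500, return_models: bool = False):
    """Repeated stratified k-fold cross-validation for each model kind.

    Per fold, the scaler and model are fitted on the training portion
    only.  Returns a dict mapping kind to :class:`CVReport` (and, with
    ``return_models=True``, also kind -> list of (fold_models, folds) per
    trial, for downstream saliency averaging).
    """
    grids = np.asarray(grids, dtype=float)
    labels = np.asarray(labels).astype(int)
    reports: dict[str, CVReport] = {}
    all_models: dict[str, list] = {}
    for kind in kinds:
        per_fold, flags = [], []
        trial_means = []
        fold_records = []
        for trial in range(n_trials):
            trial_seed = seed + 1000 * trial
            folds = stratified_folds(labels, k, seed=trial_seed)
            trial_metrics = []
            fold_models = []
            for fold in range(k):
                test_idx = np.flatnonzero(folds == fold)
                train_idx = np.flatnonzero(folds != fold)
                metrics, model = _fit_and_score(
                    grids, labels, train_idx, test_idx, kind, trial_seed,
                    egonet_config, n_trees, flags, trial, fold,
                )
                metrics.update({"trial": trial, "fold": fold})
                per_fold.append(metrics)
                trial_metrics.append(metrics)
                fold_models.append(model)
            trial_means.append({
                m: float(np.nanmean([tm[m] for tm in trial_metrics]))
                for m in METRIC_NAMES
            })
            fold_records.append((fold_models, folds))
        mean = {m: float(np.nanmean([pf[m] for pf in per_fold]))
                for m in METRIC_NAMES}
        sd = {m: float(np.nanstd([pf[m] for pf in per_fold]))
              for m in METRIC_NAMES}
        sd_trials = {m: float(np.std([tm[m] for tm in trial_means]))
                     for m in METRIC_NAMES}
        reports[kind] = CVReport(
            kind=kind, per_fold=per_fold, mean=mean, sd=sd,
            sd_across_trials=sd_trials, n_folds=k, n_trials=n_trials,
            seeds={"master": seed,
                   "trials": [seed + 1000 * t for t in range(n_trials)]},
            flags=flags,
        )
        all_models[kind] = fold_records
    if return_models:
        return reports, all_models
    return reports
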