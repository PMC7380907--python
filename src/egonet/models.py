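"""E-GONet convolutional classifier and the comparison baselines.

E-GONet consumes the 18x20 feature grid: three 3x3 convolutional layers
(16, 32 and 64 channels, ReLU, same padding) with 2x2 max-pooling after
the first two, followed by a 128-unit fully connected layer with dropout
and a 2-way softmax output.  The baselines — least-squares "linear
regression" thresholded at 0.5, and a 500-tree random forest — consume the
same flattened grid so the comparison isolates the architecture.

All models share a preprocessing contract: a per-cell min-max scaler
fitted on training data only, with structural-zero cells passing through
unchanged and unseen values clipped to [0, 1].
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression

from . import _nn
from .relationship_features import GRID_SHAPE

__all__ = [
    "EGONetConfig",
    "MinMaxScaler",
    "TrainedModel",
    "TrainingError",
    "fit_scaler",
    "apply_scaler",
    "train_egonet",
    "train_baseline",
    "predict",
]

_N_CELLS = GRID_SHAPE[0] * GRID_SHAPE[1]


class TrainingError(RuntimeError):
    """Non-finite loss encountered during training."""


@dataclass
class EGONetConfig:
    """Hyperparameters of the E-GONet CNN."""

    conv_channels: tuple = (16, 32, 64)
    fc_width: int = 128
    dropout_rate: float = 0.25
    optimizer: str = "adam"  # "adam" | "sgd"
    learning_rate: float = 1e-3
    batch_size: int = 64
    epochs: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.conv_channels) != 3 or any(c <= 0 for c in self.conv_channels):
            raise ValueError("conv_channels must be three positive widths")
        if self.fc_width <= 0:
            raise ValueError("fc_width must be positive")
        if not (0 <= self.dropout_rate < 1):
            raise ValueError("dropout_rate must lie in [0, 1)")


@dataclass
class MinMaxScaler:
    """Per-cell min-max bounds fitted on training grids only."""

    lo: np.ndarray
    hi: np.ndarray


def _as_grids(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.ndim == 2 and x.shape[1] == _N_CELLS:
        return x.reshape(-1, *GRID_SHAPE)
    if x.ndim == 3 and x.shape[1:] == GRID_SHAPE:
        return x
    raise ValueError(f"expected (n, 18, 20) grids or (n, 360) rows, got {x.shape}")


def fit_scaler(train_grids: np.ndarray) -> MinMaxScaler:
    """Learn per-cell min-max bounds; constant cells map to 0 by convention."""
    g = _as_grids(train_grids)
    if g.shape[0] == 0:
        raise ValueError("training set is empty")
    return MinMaxScaler(lo=g.min(axis=0), hi=g.max(axis=0))


def apply_scaler(grids: np.ndarray, scaler: MinMaxScaler) -> np.ndarray:
    """Map each cell to [0, 1]; out-of-range unseen values are clipped.

    Cells constant in training (including the structural zeros) map to 0,
    so zero cells pass through unchanged.
    """
    g = _as_grids(grids)
    span = scaler.hi - scaler.lo
    out = np.zeros_like(g)
    varying = span > 0
    out[:, varying] = (g[:, varying] - scaler.lo[varying]) / span[varying]
    return np.clip(out, 0.0, 1.0)


class _EGONet:
    """The fitted network: layers, parameters and loss trace."""

    def __init__(self, config: EGONetConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        c1, c2, c3 = config.conv_channels
        h, w = GRID_SHAPE  # 18x20 -> pool 9x10 -> pool 4x5
        flat = (h // 2 // 2) * (w // 2 // 2) * c3
        self.net = _nn.Sequential([
            _nn.Conv3x3(1, c1, rng), _nn.ReLU(), _nn.MaxPool2(),
            _nn.Conv3x3(c1, c2, rng), _nn.ReLU(), _nn.MaxPool2(),
            _nn.Conv3x3(c2, c3, rng), _nn.ReLU(),
            _nn.Flatten(),
            _nn.Dense(flat, config.fc_width, rng), _nn.ReLU(),
            _nn.Dropout(config.dropout_rate, rng),
            _nn.Dense(config.fc_width, 2, rng),
        ])
        self.rng = rng
        self.loss_trace: list[float] = []

    def fit(self, grids: np.ndarray, labels: np.ndarray) -> None:
        cfg = self.config
        opt_cls = {"adam": _nn.Adam, "sgd": _nn.SGD}[cfg.optimizer]
        opt = opt_cls(self.net.params, lr=cfg.learning_rate)
        x = grids[:, None, :, :]
        y = labels.astype(int)
        n = x.shape[0]
        bs = min(cfg.batch_size, n)
        for epoch in range(cfg.epochs):
            order = self.rng.permutation(n)
            epoch_loss = 0.0
            for start in range(0, n, bs):
                idx = order[start:start + bs]
                logits = self.net.forward(x[idx], train=True)
                loss, dlogits = _nn.cross_entropy(logits, y[idx])
                if not np.isfinite(loss):
                    raise TrainingError(f"non-finite loss at epoch {epoch}")
                self.net.backward(dlogits)
                opt.step()
                epoch_loss += loss * idx.size
            self.loss_trace.append(epoch_loss / n)

    def logits(self, grids: np.ndarray) -> np.ndarray:
        return self.net.forward(grids[:, None, :, :], train=False)

    def predict_proba(self, grids: np.ndarray) -> np.ndarray:
        return _nn.softmax(self.logits(grids))

    def input_gradient(self, grids: np.ndarray, target: np.ndarray) -> np.ndarray:
        """d(logit of the target class) / d(input grid), per subject."""
        logits = self.net.forward(grids[:, None, :, :], train=False)
        seed = np.zeros_like(logits)
        seed[np.arange(logits.shape[0]), target.astype(int)] = 1.0
        return self.net.backward(seed)[:, 0, :, :]


@dataclass
class TrainedModel:
    """A fitted classifier bundled with its preprocessing state."""

    kind: str  # "egonet" | "linreg" | "rf"
    estimator: object
    scaler: MinMaxScaler
    uses_relationship_features: bool = True
    config: EGONetConfig | None = field(default=None, repr=False)


def train_egonet(grids: np.ndarray, labels: np.ndarray,
                 config: EGONetConfig | None = None,
                 scaler: MinMaxScaler | None = None,
                 uses_relationship_features: bool = True) -> TrainedModel:
    """Fit E-GONet; the scaler is fitted on ``grids`` unless provided."""
    config = config or EGONetConfig()
    g = _as_grids(grids)
    y = np.asarray(labels).astype(int)
    if scaler is None:
        scaler = fit_scaler(g)
    net = _EGONet(config)
    net.fit(apply_scaler(g, scaler), y)
    return TrainedModel("egonet", net, scaler, uses_relationship_features, config)


class _LeastSquares:
    """Least-squares fit of a 0/1 target, thresholded at 0.5."""

    def __init__(self, coef: np.ndarray, intercept: float):
        self.coef = coef
        self.intercept = intercept

    def decision(self, X: np.ndarray) -> np.ndarray:
        return X @ self.coef + self.intercept


def _fit_least_squares(X: np.ndarray, y: np.ndarray) -> _LeastSquares:
    A = np.column_stack([np.ones(X.shape[0]), X])
    sol, _, rank, _ = np.linalg.lstsq(A, y.astype(float), rcond=None)
    if rank < A.shape[1]:
        warnings.warn("singular design; solving with ridge jitter 1e-8",
                      stacklevel=3)
        sol = np.linalg.solve(A.T @ A + 1e-8 * np.eye(A.shape[1]), A.T @ y)
    return _LeastSquares(sol[1:], float(sol[0]))


def train_baseline(features: np.ndarray, labels: np.ndarray, kind: str,
                   seed: int = 0, scaler: MinMaxScaler | None = None,
                   uses_relationship_features: bool = True,
                   n_trees: int = 500) -> TrainedModel:
    """Fit a comparison model on flattened (scaled) grids.

    ``kind`` is ``"linreg"`` (least squares on the 0/1 target, class at
    score >= 0.5; pass ``kind="logistic"`` for the logistic variant) or
    ``"rf"`` (seeded random forest, 500 trees by default).
    """
    g = _as_grids(features)
    y = np.asarray(labels).astype(int)
    if scaler is None:
        scaler = fit_scaler(g)
    X = apply_scaler(g, scaler).reshape(g.shape[0], -1)
    if kind == "linreg":
        est = _fit_least_squares(X, y)
    elif kind == "logistic":
        est = LogisticRegression(max_iter=1000, random_state=seed).fit(X, y)
    elif kind == "rf":
        est = RandomForestClassifier(
            n_estimators=n_trees, random_state=seed, n_jobs=1
        ).fit(X, y)
    else:
        raise ValueError(f"unknown baseline kind {kind!r}")
    return TrainedModel(kind, est, scaler, uses_relationship_features)


def predict(model: TrainedModel, grids: np.ndarray):
    """Lethal-class probability and class at threshold 0.5 per subject.

    Returns ``(prob, label)``; empty input gives empty output.
    """
    g = _as_grids(grids)
    if g.shape[0] == 0:
        return np.empty(0), np.empty(0, dtype=int)
    scaled = apply_scaler(g, model.scaler)
    if model.kind == "egonet":
        prob = model.estimator.predict_proba(scaled)[:, 1]
    elif model.kind == "linreg":
        X = scaled.reshape(g.shape[0], -1)
        prob = np.clip(model.estimator.decision(X), 0.0, 1.0)
    elif model.kind in ("rf", "logistic"):
        X = scaled.reshape(g.shape[0], -1)
        classes = list(model.estimator.classes_)
        proba = model.estimator.predict_proba(X)
        prob = proba[:, classes.index(1)] if 1 in classes else np.zeros(g.shape[0])
    else:  # pragma: no cover
        raise ValueError(f"unknown model kind {model.kind!r}")
    return prob, (prob >= 0.5).astype(int)
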