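"""Fully-connected binary classifier with standardization, early stopping and
a coordinate-wise hyper-parameter search.

The network is a stack of equal-width ReLU hidden layers with a logistic
output unit, trained with cross-entropy loss and the Adam optimizer at its
default step size.  The early-stopping monitor is the epoch's training
accuracy: when it fails to rise for ``early_stop_patience`` (10) consecutive
epochs training stops and the last weights are kept (the convention of
framework-default accuracy monitors; a small held-out monitor saturates too
coarsely to be informative at the balanced-training sizes this model sees).
All randomness is controlled by a single seed; identical seed + data gives
identical predictions.

The hyper-parameter search sweeps, in order, the number of hidden layers,
the hidden-layer width and the batch size, holding the others fixed
(coordinate-wise exhaustive search over the default grids of 8, 7 and 7
values), maximizing mean Matthews correlation over stratified validation
folds and breaking ties toward the smaller value.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
from sklearn.model_selection import StratifiedKFold
from sklearn.neural_network import MLPClassifier

GRID_HIDDEN_LAYERS: tuple[int, ...] = (1, 2, 3, 4, 5, 6, 7, 8)
GRID_HIDDEN_NEURONS: tuple[int, ...] = (2, 4, 8, 16, 32, 64, 128)
GRID_BATCH_SIZE: tuple[int, ...] = (2, 4, 8, 16, 32, 64, 128)


@dataclass(frozen=True)
class ModelConfig:
    """Architecture and training settings for the classifier.

    Defaults (2 layers x 16 neurons, batch 32) are the tuned balanced-protocol
    settings; run :func:`coordinate_search` to re-tune on new data.
    """

    hidden_layers: int = 2
    hidden_neurons: int = 16
    batch_size: int = 32
    max_epochs: int = 200
    early_stop_patience: int = 10
    threshold: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if self.hidden_layers < 1 or self.hidden_neurons < 1 or self.batch_size < 1:
            raise ValueError("hidden_layers, hidden_neurons and batch_size must be >= 1")
        if not 0.0 < self.threshold < 1.0:
            raise ValueError("threshold must lie in (0, 1)")


class Standardizer:
    """Per-feature zero-mean unit-scale transform fitted on training rows only.

    Zero-variance training columns are mapped to a constant 0 regardless of
    the value seen at predict time, so a feature that carried no information
    during training can never perturb predictions.
    """

    def fit(self, X: np.ndarray) -> "Standardizer":
        X = np.asarray(X, dtype=float)
        self.mean_ = X.mean(axis=0)
        std = X.std(axis=0)
        self.zero_var_ = std == 0.0
        self.scale_ = np.where(self.zero_var_, 1.0, std)
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        Z = (X - self.mean_) / self.scale_
        if Z.size:
            Z[:, self.zero_var_] = 0.0
        return Z


@dataclass
class TrainedModel:
    config: ModelConfig
    standardizer: Standardizer
    net: MLPClassifier
    n_epochs: int = 0

    @property
    def n_features(self) -> int:
        return len(self.standardizer.mean_)


def train(X: np.ndarray, y: np.ndarray, config: ModelConfig | None = None) -> TrainedModel:
    """Fit the classifier; requires at least one example of each class.

    Runs an explicit epoch loop so the early-stopping rule is exactly "stop
    when the epoch's accuracy has not risen for `early_stop_patience`
    consecutive epochs", keeping the last weights.
    """
    config = config or ModelConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if X.shape[0] != y.shape[0]:
        raise ValueError(f"{X.shape[0]} rows but {y.shape[0]} labels")
    if len(np.unique(y)) < 2:
        raise ValueError("training labels contain a single class")
    scaler = Standardizer().fit(X)
    Z = scaler.transform(X)
    net = MLPClassifier(
        hidden_layer_sizes=(config.hidden_neurons,) * config.hidden_layers,
        activation="relu",
        solver="adam",
        batch_size=min(config.batch_size, X.shape[0]),
        random_state=config.seed,
    )
    classes = np.unique(y)
    best_acc, wait, n_epochs = -np.inf, 0, 0
    for _ in range(config.max_epochs):
        net.partial_fit(Z, y, classes=classes)
        n_epochs += 1
        acc = net.score(Z, y)
        if acc > best_acc:
            best_acc, wait = acc, 0
        else:
            wait += 1
            if wait >= config.early_stop_patience:
                break
    return TrainedModel(config=config, standardizer=scaler, net=net, n_epochs=n_epochs)


def predict(model: TrainedModel, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Probabilities and binary calls; a probability equal to the threshold is a positive call."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or (X.size and X.shape[1] != model.n_features):
        if X.shape[0] == 0:
            return np.empty(0), np.empty(0, dtype=bool)
        raise ValueError(f"expected {model.n_features} features, got {X.shape[1] if X.ndim == 2 else X.ndim}")
    if X.shape[0] == 0:
        return np.empty(0), np.empty(0, dtype=bool)
    proba = model.net.predict_proba(model.standardizer.transform(X))[:, 1]
    return proba, apply_threshold(proba, model.config.threshold)


def apply_threshold(proba: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Binary calls from probabilities; the boundary probability is positive."""
    return np.asarray(proba) >= threshold


@dataclass
class SearchTrace:
    """Every configuration evaluated by the coordinate search, with its score."""

    evaluations: list[tuple[ModelConfig, float]] = field(default_factory=list)

    @property
    def n_evaluations(self) -> int:
        return len(self.evaluations)


def _cv_mcc_objective(X, y, cv: int, seed: int) -> Callable[[ModelConfig], float]:
    from .evaluate import from_predictions  # local import avoids a cycle

    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    skf = StratifiedKFold(n_splits=cv, shuffle=True, random_state=seed)
    splits = list(skf.split(X, y))

    def objective(config: ModelConfig) -> float:
        scores = []
        for tr, te in splits:
            fitted = train(X[tr], y[tr], config)
            _, calls = predict(fitted, X[te])
            scores.append(from_predictions(y[te], calls).mcc)
        return float(np.mean(scores))

    return objective


def _sweep(objective, base: ModelConfig, param: str, grid: Sequence[int],
           trace: SearchTrace) -> int:
    """Evaluate ``grid`` ascending for one parameter; first (smallest) best wins ties."""
    best_val, best_score = None, -np.inf
    for value in sorted(grid):
        cfg = replace(base, **{param: value})
        score = objective(cfg)
        trace.evaluations.append((cfg, score))
        if score > best_score:
            best_val, best_score = value, score
    return best_val


def coordinate_search(
    X: np.ndarray | None = None,
    y: np.ndarray | None = None,
    grid_layers: Sequence[int] = GRID_HIDDEN_LAYERS,
    grid_neurons: Sequence[int] = GRID_HIDDEN_NEURONS,
    grid_batch: Sequence[int] = GRID_BATCH_SIZE,
    cv: int = 3,
    seed: int = 0,
    base_config: ModelConfig | None = None,
    objective: Callable[[ModelConfig], float] | None = None,
) -> tuple[ModelConfig, SearchTrace]:
    """Coordinate-wise exhaustive search over the three architecture knobs.

    Optimizes hidden_layers, then hidden_neurons, then batch_size; while a
    knob is being swept the not-yet-optimized knobs are held at 32 (or at the
    middle of their grid when 32 is not offered).  Exactly
    ``len(grid_layers) + len(grid_neurons) + len(grid_batch)`` configurations
    are evaluated.  The default objective is mean MCC over ``cv`` stratified
    validation folds; a custom ``objective(config) -> score`` may replace it.
    """
    if not (grid_layers and grid_neurons and grid_batch):
        raise ValueError("every grid must be non-empty")
    if objective is None:
        if X is None or y is None:
            raise ValueError("X and y are required unless a custom objective is given")
        objective = _cv_mcc_objective(X, y, cv=cv, seed=seed)

    def start(grid):
        grid = sorted(grid)
        return 32 if 32 in grid else grid[len(grid) // 2]

    base = base_config or ModelConfig(seed=seed)
    base = replace(base, hidden_neurons=start(grid_neurons), batch_size=start(grid_batch))
    trace = SearchTrace()

    best_layers = _sweep(objective, base, "hidden_layers", grid_layers, trace)
    base = replace(base, hidden_layers=best_layers)
    best_neurons = _sweep(objective, base, "hidden_neurons", grid_neurons, trace)
    base = replace(base, hidden_neurons=best_neurons)
    best_batch = _sweep(objective, base, "batch_size", grid_batch, trace)
    base = replace(base, batch_size=best_batch)
    return base, trace


def save_model(model: TrainedModel, path) -> None:
    """Serialize config, standardizer statistics and network weights to JSON."""
    payload = {
        "config": model.config.__dict__,
        "standardizer": {
            "mean": model.standardizer.mean_.tolist(),
            "scale": model.standardizer.scale_.tolist(),
            "zero_var": model.standardizer.zero_var_.tolist(),
        },
        "coefs": [w.tolist() for w in model.net.coefs_],
        "intercepts": [b.tolist() for b in model.net.intercepts_],
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)


def load_model(path) -> TrainedModel:
    with open(path) as fh:
        payload = json.load(fh)
    config = ModelConfig(**payload["config"])
    scaler = Standardizer()
    scaler.mean_ = np.array(payload["standardizer"]["mean"])
    scaler.scale_ = np.array(payload["standardizer"]["scale"])
    scaler.zero_var_ = np.array(payload["standardizer"]["zero_var"], dtype=bool)
    net = MLPClassifier(
        hidden_layer_sizes=(config.hidden_neurons,) * config.hidden_layers,
        activation="relu",
    )
    net.coefs_ = [np.array(w) for w in payload["coefs"]]
    net.intercepts_ = [np.array(b) for b in payload["intercepts"]]
    net.n_layers_ = len(net.coefs_) + 1
    net.n_outputs_ = 1
    net.out_activation_ = "logistic"
    net.classes_ = np.array([0, 1])
    from sklearn.preprocessing import LabelBinarizer

    net._label_binarizer = LabelBinarizer().fit([0, 1])
    net.n_features_in_ = len(scaler.mean_)
    return TrainedModel(config=config, standardizer=scaler, net=net)
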