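"""Comparison models: random forest, KNN, logistic regression, dense-only net.

All baselines consume the same per-modality pair vectors as the fused
convolutional model, concatenated into one flat feature vector (the only
representation a flat classifier can use), and the same fold assignments, so
cross-model comparisons are internally valid.  Hyperparameters follow the
comparison convention: 100 trees for the random forest, 4 neighbors for KNN,
default-regularized multinomial logistic regression.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.neighbors import KNeighborsClassifier

from .model import ModelConfig, MultimodalConvNet, SubmodelSpec

BASELINE_KINDS = ("random_forest", "knn", "logistic_regression", "dnn_ablation")


@dataclass
class BaselineConfig:
    kind: str
    rf_trees: int = 100
    knn_neighbors: int = 4
    seed: int = 0
    # dnn_ablation training knobs (mirrors the main model minus the conv front)
    epochs: int = 50
    batch_size: int = 256
    learning_rate: float = 1e-3

    def __post_init__(self) -> None:
        if self.kind not in BASELINE_KINDS:
            raise ValueError(f"unknown baseline kind {self.kind!r}; choose from {BASELINE_KINDS}")
        if self.rf_trees <= 0 or self.knn_neighbors <= 0:
            raise ValueError("tree and neighbor counts must be positive")


class _FlatWrapper:
    """Adapts a sklearn classifier to the multi-input (list of matrices) API."""

    def __init__(self, estimator, n_events: int):
        self.estimator = estimator
        self.n_events = n_events

    @staticmethod
    def _flatten(xs: Sequence[np.ndarray]) -> np.ndarray:
        return np.concatenate([np.asarray(x) for x in xs], axis=1)

    def fit(self, xs: Sequence[np.ndarray], y: np.ndarray) -> "_FlatWrapper":
        self._classes_seen = np.unique(y)
        self.estimator.fit(self._flatten(xs), y)
        return self

    def predict_proba(self, xs: Sequence[np.ndarray]) -> np.ndarray:
        """(n, n_events) probabilities; classes unseen in training get 0."""
        x = self._flatten(xs)
        raw = self.estimator.predict_proba(x)
        out = np.zeros((x.shape[0], self.n_events), dtype=np.float64)
        out[:, self.estimator.classes_.astype(int)] = raw
        return out

    def predict(self, xs: Sequence[np.ndarray]) -> np.ndarray:
        return self.predict_proba(xs).argmax(axis=1)


def build_baseline(config: BaselineConfig, input_lengths: dict[str, int], n_events: int):
    """Construct an unfitted baseline exposing fit / predict_proba on input lists."""
    if config.kind == "random_forest":
        est = RandomForestClassifier(n_estimators=config.rf_trees, random_state=config.seed)
        return _FlatWrapper(est, n_events)
    if config.kind == "knn":
        est = KNeighborsClassifier(n_neighbors=config.knn_neighbors)
        return _FlatWrapper(est, n_events)
    if config.kind == "logistic_regression":
        est = LogisticRegression(max_iter=1000, random_state=config.seed)
        return _FlatWrapper(est, n_events)
    # dense-only ablation: the fused model with the conv+flatten front removed
    submodels = {
        m: SubmodelSpec(input_length=length, use_conv=False)
        for m, length in input_lengths.items()
    }
    model_config = ModelConfig(
        submodels=submodels,
        n_events=n_events,
        epochs=config.epochs,
        batch_size=config.batch_size,
        learning_rate=config.learning_rate,
        seed=config.seed,
    )
    return MultimodalConvNet(model_config)


def fit_baseline(config: BaselineConfig, xs: Sequence[np.ndarray], y: np.ndarray, n_events: int):
    """Fit a baseline on training inputs (list of per-modality matrices)."""
    lengths = {f"m{i}": x.shape[1] for i, x in enumerate(xs)}
    model = build_baseline(config, lengths, n_events)
    return model.fit(xs, y)
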