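"""Clip-level call classification: CART pre-selection -> neural net -> threshold.

For each call kind (aerial chatter, ground purr) a tree-based feature
pre-selection ranks the 610 candidate features by impurity importance and a
grid search over the subset size picks the count maximizing validation
sensitivity at the operating threshold; the selected features feed a small
fully-connected network (2 hidden layers, 64/32) producing a per-clip call
probability. A detection is accepted when the probability clears the
kind-specific threshold — 0.99 for aerial calls, 0.50 for ground calls.

Evaluation follows the monitoring convention: accuracy is
TP / (TP + FP) among accepted detections (a precision), and sensitivity is
accepted-TP / condition-positives (a recall at threshold).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.neural_network import MLPClassifier
from sklearn.tree import DecisionTreeClassifier

__all__ = [
    "LabeledClipSet",
    "TrainConfig",
    "CallClassifier",
    "DetectionEvent",
    "EvalReport",
    "cart_select",
    "train_dnn",
    "predict",
    "evaluate",
    "detections_to_csv",
]

DEFAULT_THRESHOLDS = {"aerial": 0.99, "ground": 0.50}


@dataclass
class LabeledClipSet:
    """Feature matrix with binary labels for one call kind and split role."""

    features: np.ndarray          # (n_clips, n_features)
    labels: np.ndarray            # bool
    role: str = "training"        # training | model-selection | test
    clip_starts: list | None = None

    def __post_init__(self):
        self.features = np.asarray(self.features, dtype=float)
        self.labels = np.asarray(self.labels, dtype=bool)
        if self.features.shape[0] != len(self.labels):
            raise ValueError("features/labels length mismatch")


@dataclass
class TrainConfig:
    call_kind: str = "aerial"
    n_features_grid: tuple[int, ...] = (10, 25, 50, 100)
    hidden_layers: tuple[int, ...] = (64, 32)
    max_epochs: int = 500
    early_stopping: bool = False
    rng_seed: int = 0
    probability_threshold: float | None = None  # default by call kind
    positive_weight: float = 1.0  # >1 inflates the positive class in training

    def __post_init__(self):
        if self.probability_threshold is None:
            self.probability_threshold = DEFAULT_THRESHOLDS.get(self.call_kind, 0.5)
        if not (0.0 < self.probability_threshold < 1.0):
            raise ValueError("threshold must lie in (0, 1)")


@dataclass(frozen=True)
class DetectionEvent:
    clip_start: object
    call_kind: str
    probability: float
    accepted: bool


@dataclass(frozen=True)
class EvalReport:
    accuracy: float | None    # TP/(TP+FP) over accepted; None if none accepted
    sensitivity: float        # accepted TP / condition positives
    threshold: float
    tp: int
    fp: int
    condition_positives: int


@dataclass
class CallClassifier:
    """Trained model bundle: feature subset + network + operating threshold."""

    call_kind: str
    feature_indices: np.ndarray
    mlp: MLPClassifier = field(repr=False)
    threshold: float = 0.5
    scaler_mean: np.ndarray = field(default=None, repr=False)
    scaler_std: np.ndarray = field(default=None, repr=False)

    def predict_proba(self, features: np.ndarray) -> np.ndarray:
        X = np.asarray(features, dtype=float)
        if X.ndim != 2:
            raise ValueError("features must be 2-D (clips x features)")
        Xs = (X[:, self.feature_indices] - self.scaler_mean) / self.scaler_std
        return self.mlp.predict_proba(Xs)[:, 1]

    def save(self, path) -> None:
        meta = {
            "call_kind": self.call_kind,
            "threshold": self.threshold,
            "hidden_layer_sizes": list(self.mlp.hidden_layer_sizes),
        }
        np.savez(
            path,
            meta=json.dumps(meta),
            feature_indices=self.feature_indices,
            scaler_mean=self.scaler_mean,
            scaler_std=self.scaler_std,
            **{f"coef_{i}": c for i, c in enumerate(self.mlp.coefs_)},
            **{f"int_{i}": b for i, b in enumerate(self.mlp.intercepts_)},
        )

    @classmethod
    def load(cls, path) -> "CallClassifier":
        with np.load(path, allow_pickle=False) as z:
            meta = json.loads(str(z["meta"]))
            coefs = []
            i = 0
            while f"coef_{i}" in z:
                coefs.append(z[f"coef_{i}"])
                i += 1
            ints = [z[f"int_{j}"] for j in range(i)]
            # early_stopping must be off for partial_fit to initialize the shell
            mlp = MLPClassifier(hidden_layer_sizes=tuple(meta["hidden_layer_sizes"]),
                                activation="relu", solver="adam", random_state=0)
            n_in = coefs[0].shape[0]
            mlp.partial_fit(np.zeros((2, n_in)), [0, 1], classes=[0, 1])
            mlp.coefs_ = [np.array(c) for c in coefs]
            mlp.intercepts_ = [np.array(b) for b in ints]
            return cls(
                call_kind=meta["call_kind"],
                feature_indices=z["feature_indices"],
                mlp=mlp,
                threshold=float(meta["threshold"]),
                scaler_mean=z["scaler_mean"],
                scaler_std=z["scaler_std"],
            )


def _blank_mlp(hidden: tuple[int, ...], seed: int, max_iter: int = 500,
               early_stopping: bool = False) -> MLPClassifier:
    # trained to convergence by default: early stopping leaves the output
    # layer under-saturated, which matters at the 0.99 operating threshold
    return MLPClassifier(
        hidden_layer_sizes=hidden,
        activation="relu",
        solver="adam",
        alpha=1e-5,
        max_iter=max_iter,
        early_stopping=early_stopping,
        n_iter_no_change=20,
        validation_fraction=0.15,
        random_state=seed,
    )


def cart_select(train: LabeledClipSet, cfg: TrainConfig,
                validation: LabeledClipSet | None = None) -> np.ndarray:
    """Rank features with a CART tree; pick the subset size by validation.

    Returns the indices of the selected features (importance-ranked). When
    no validation set is given, the largest grid entry is used.
    """
    y = train.labels
    if y.all() or not y.any():
        raise ValueError("training set must contain both classes")
    tree = DecisionTreeClassifier(random_state=cfg.rng_seed)
    tree.fit(train.features, y)
    order = np.argsort(tree.feature_importances_)[::-1]
    grid = [min(g, train.features.shape[1]) for g in cfg.n_features_grid]
    if validation is None:
        return order[: max(grid)]
    best_n, best_score = grid[0], -1.0
    for n_feat in grid:
        idx = order[:n_feat]
        model = _fit_mlp(train, idx, cfg)
        events = predict(model, validation.features)
        report = evaluate(events, validation.labels, model.threshold)
        if report.sensitivity > best_score:
            best_n, best_score = n_feat, report.sensitivity
    return order[:best_n]


def _fit_mlp(train: LabeledClipSet, idx: np.ndarray, cfg: TrainConfig) -> CallClassifier:
    X = train.features[:, idx]
    y = train.labels.astype(int)
    if cfg.positive_weight != 1.0:
        reps = int(round(cfg.positive_weight))
        pos = np.flatnonzero(y == 1)
        X = np.vstack([X, np.repeat(X[pos], reps - 1, axis=0)])
        y = np.concatenate([y, np.ones((reps - 1) * len(pos), dtype=int)])
    mean = X.mean(axis=0)
    std = X.std(axis=0)
    std[std == 0] = 1.0
    mlp = _blank_mlp(cfg.hidden_layers, cfg.rng_seed, cfg.max_epochs, cfg.early_stopping)
    mlp.fit((X - mean) / std, y)
    return CallClassifier(
        call_kind=cfg.call_kind,
        feature_indices=np.asarray(idx),
        mlp=mlp,
        threshold=cfg.probability_threshold,
        scaler_mean=mean,
        scaler_std=std,
    )


def train_dnn(train: LabeledClipSet, subset: np.ndarray, cfg: TrainConfig) -> CallClassifier:
    """Train the feed-forward network on the selected feature subset."""
    if len(subset) == 0:
        raise ValueError("empty feature subset")
    if not np.isfinite(train.features).all():
        raise ValueError("non-finite features")
    return _fit_mlp(train, np.asarray(subset), cfg)


def predict(model: CallClassifier, features: np.ndarray,
            threshold: float | None = None,
            clip_starts: Sequence | None = None) -> list[DetectionEvent]:
    """One DetectionEvent per clip; accepted iff probability >= threshold."""
    thr = model.threshold if threshold is None else threshold
    probs = model.predict_proba(features)
    if clip_starts is None:
        clip_starts = [None] * len(probs)
    return [
        DetectionEvent(clip_start=s, call_kind=model.call_kind,
                       probability=float(p), accepted=bool(p >= thr))
        for s, p in zip(clip_starts, probs)
    ]


def evaluate(events: Sequence[DetectionEvent], labels: Sequence[bool],
             threshold: float | None = None) -> EvalReport:
    """Accuracy (precision among accepted) and sensitivity at the threshold."""
    if len(events) != len(labels):
        raise ValueError("events and labels must align by clip")
    labels = np.asarray(labels, dtype=bool)
    if threshold is None:
        accepted = np.array([e.accepted for e in events])
        thr = float("nan")
    else:
        thr = threshold
        accepted = np.array([e.probability >= thr for e in events])
    tp = int((accepted & labels).sum())
    fp = int((accepted & ~labels).sum())
    pos = int(labels.sum())
    acc = tp / (tp + fp) if (tp + fp) > 0 else None
    sens = tp / pos if pos > 0 else float("nan")
    return EvalReport(accuracy=acc, sensitivity=sens, threshold=thr,
                      tp=tp, fp=fp, condition_positives=pos)


def detections_to_csv(events: Sequence[DetectionEvent], path) -> pd.DataFrame:
    df = pd.DataFrame(
        [
            {"clip_start": e.clip_start, "kind": e.call_kind,
             "probability": e.probability, "accepted": e.accepted}
            for e in events
        ]
    )
    df.to_csv(path, index=False)
    return df
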