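"""Shallow neural-network pre-filter for normal glow curves.

Shape, not dose, decides normality here: the 202-dimensional feature vector
is the max-normalized 200-channel curve plus the skewness and excess
kurtosis of the curve treated as a probability distribution over channel
indices.  A fixed 202 -> 5 -> 15 -> 5 -> 1 network (ReLU hidden layers,
logistic output) maps features to the probability of the curve being
normal; curves above the decision threshold (default 0.91, strict) are
removed before the rule cascade.  The threshold is deliberately high: a
normal curve sent onward costs technician time, an anomalous curve waved
through costs accuracy, so false negatives are preferred.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.exceptions import ConvergenceWarning
from sklearn.metrics import log_loss
from sklearn.model_selection import train_test_split
from sklearn.neural_network import MLPClassifier

from .datamodel import N_CHANNELS, GlowCurve, PipelineConfig

N_FEATURES = N_CHANNELS + 2
HIDDEN_LAYER_SIZES = (5, 15, 5)

SUSPECTED_ANOMALOUS = "suspected_anomalous"
NORMAL_DECISION = "normal"


def extract_features(gc: GlowCurve) -> np.ndarray:
    """202-vector: channels / max, then skewness and excess kurtosis of the
    intensity-weighted channel-index distribution.

    Dividing by the maximum makes the vector invariant to dose scale; a
    perfectly symmetric peak has zero skewness.  All-zero curves are
    rejected (they belong to the low-dose filter, not here).
    """
    y = gc.channels
    mx = y.max()
    if mx <= 0:
        raise ValueError("all-zero glow curve has no shape; should have been low-dose filtered")
    normed = y / mx
    p = y / y.sum()
    idx = np.arange(1, N_CHANNELS + 1, dtype=float)
    mu = float(p @ idx)
    var = float(p @ (idx - mu) ** 2)
    if var > 0:
        sd = var**0.5
        skew = float(p @ ((idx - mu) / sd) ** 3)
        kurt = float(p @ ((idx - mu) / sd) ** 4) - 3.0
    else:  # single-channel curve: moments undefined, report neutral values
        skew, kurt = 0.0, 0.0
    return np.concatenate([normed, [kurt, skew]])


def curves_to_features(curves: Sequence[GlowCurve]) -> np.ndarray:
    return np.vstack([extract_features(gc) for gc in curves])


def _as_feature_matrix(X) -> np.ndarray:
    """Accept raw curves (n, 200 or GlowCurves) or ready features (n, 202)."""
    if len(X) and isinstance(X[0], GlowCurve):
        return curves_to_features(X)
    arr = np.asarray(X, dtype=float)
    if arr.ndim != 2:
        raise ValueError("expected a 2-D array of curves or features")
    if arr.shape[1] == N_FEATURES:
        return arr
    if arr.shape[1] == N_CHANNELS:
        return curves_to_features([GlowCurve(row) for row in arr])
    raise ValueError(f"expected {N_CHANNELS} channel or {N_FEATURES} feature columns, got {arr.shape[1]}")


def _relu(z: np.ndarray) -> np.ndarray:
    return np.maximum(z, 0.0)


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-z))


class NormalCurveFilter(BaseEstimator, ClassifierMixin):
    """Binary filter estimator: 1 = normal glow curve, 0 = suspected anomalous.

    ``fit`` accepts raw curves or precomputed feature matrices; an optional
    ``eval_set`` drives early stopping (best validation cross-entropy, with
    patience).  Inference runs a plain numpy forward pass over the stored
    weights, so persisted models (:func:`save_model`) need nothing beyond
    this module to load.

    Parameters
    ----------
    threshold : decision threshold on P(normal); strictly above -> normal.
    max_epochs, patience : early-stopping schedule.
    learning_rate, batch_size : adam settings.
    random_state : seed for weight initialization and shuffling.
    """

    def __init__(
        self,
        threshold: float = 0.91,
        max_epochs: int = 400,
        patience: int = 25,
        learning_rate: float = 1e-3,
        batch_size: int = 64,
        random_state: int = 0,
    ):
        self.threshold = threshold
        self.max_epochs = max_epochs
        self.patience = patience
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.random_state = random_state

    def fit(self, X, y, eval_set: Optional[tuple] = None) -> "NormalCurveFilter":
        Xf = _as_feature_matrix(X)
        y = np.asarray(y, dtype=int)
        if set(np.unique(y)) - {0, 1}:
            raise ValueError("labels must be 0 (anomalous) or 1 (normal)")
        if len(np.unique(y)) < 2:
            raise ValueError("training data must contain both normal and anomalous curves")
        net = MLPClassifier(
            hidden_layer_sizes=HIDDEN_LAYER_SIZES,
            activation="relu",
            solver="adam",
            learning_rate_init=self.learning_rate,
            batch_size=self.batch_size,
            max_iter=1,
            warm_start=True,
            shuffle=True,
            random_state=self.random_state,
        )
        if eval_set is not None:
            Xv, yv = _as_feature_matrix(eval_set[0]), np.asarray(eval_set[1], dtype=int)
        best_loss = np.inf
        best_weights = None
        stale = 0
        epochs_run = 0
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            for epoch in range(self.max_epochs):
                net.fit(Xf, y)
                epochs_run = epoch + 1
                if eval_set is None:
                    continue
                loss = log_loss(yv, net.predict_proba(Xv), labels=[0, 1])
                if loss < best_loss - 1e-6:
                    best_loss = loss
                    best_weights = ([w.copy() for w in net.coefs_], [b.copy() for b in net.intercepts_])
                    stale = 0
                else:
                    stale += 1
                    if stale >= self.patience:
                        break
        if best_weights is not None:
            coefs, intercepts = best_weights
        else:
            coefs, intercepts = net.coefs_, net.intercepts_
        self.weights_ = [np.asarray(w, dtype=float) for w in coefs]
        self.biases_ = [np.asarray(b, dtype=float) for b in intercepts]
        self.n_epochs_ = epochs_run
        self.validation_loss_ = None if eval_set is None else float(best_loss)
        self.classes_ = np.array([0, 1])
        return self

    def _forward(self, Xf: np.ndarray) -> np.ndarray:
        a = Xf
        for W, b in zip(self.weights_[:-1], self.biases_[:-1]):
            a = _relu(a @ W + b)
        z = (a @ self.weights_[-1] + self.biases_[-1]).ravel()
        return _sigmoid(z)

    def predict_proba_normal(self, X) -> np.ndarray:
        """P(normal) for each curve."""
        if not hasattr(self, "weights_"):
            raise ValueError("model is not fitted")
        return self._forward(_as_feature_matrix(X))

    def predict_proba(self, X) -> np.ndarray:
        p = self.predict_proba_normal(X)
        return np.column_stack([1 - p, p])

    def predict(self, X) -> np.ndarray:
        return (self.predict_proba_normal(X) > self.threshold).astype(int)


def classify_normal(
    gc: GlowCurve, model: NormalCurveFilter, threshold: Optional[float] = None
) -> tuple:
    """Decide one curve; returns ``(decision, probability)``.

    The comparison is strict: probability exactly at the threshold goes to
    the rule cascade (the false-negative-preferring side).
    """
    thr = model.threshold if threshold is None else threshold
    p = float(model.predict_proba_normal([gc])[0])
    return (NORMAL_DECISION if p > thr else SUSPECTED_ANOMALOUS), p


@dataclass
class TrainingReport:
    model: NormalCurveFilter
    split_sizes: tuple  # (train, validation, test)
    test_metrics: dict
    model_path: Optional[str]


def stratified_split(X, y, seed: int) -> tuple:
    """Deterministic stratified 60/20/20 split (train size rounded down)."""
    n = len(y)
    n_train = int(0.6 * n)
    idx = np.arange(n)
    tr, rest = train_test_split(idx, train_size=n_train, stratify=y, random_state=seed)
    va, te = train_test_split(rest, train_size=len(rest) // 2, stratify=np.asarray(y)[rest], random_state=seed)
    return tr, va, te


def train_filter(dataset: Sequence, seed: int = 0, config: Optional[PipelineConfig] = None) -> TrainingReport:
    """Train the filter on a labeled (curve, label) corpus.

    Labels equal to ``"NORMAL"`` map to class 1, everything else to class 0.
    The corpus is split 60/20/20 (train/validation/test, stratified); early
    stopping watches the validation split and test metrics are reported on
    the held-out test split.  The model is persisted to
    ``config.training_model_file`` when a config is given.
    """
    cfg = config
    curves = [gc for gc, _ in dataset]
    labels = np.array([1 if lab == "NORMAL" else 0 for _, lab in dataset])
    if len(np.unique(labels)) < 2:
        raise ValueError("dataset must contain both normal and anomalous curves")
    X = curves_to_features(curves)
    tr, va, te = stratified_split(X, labels, seed)
    model = NormalCurveFilter(
        threshold=(cfg.ai_probability_threshold if cfg else 0.91), random_state=seed
    )
    model.fit(X[tr], labels[tr], eval_set=(X[va], labels[va]))
    p_test = model.predict_proba_normal(X[te])
    y_test = labels[te]
    anom = y_test == 0
    metrics = {
        "n_test": int(len(y_test)),
        "test_log_loss": float(log_loss(y_test, np.column_stack([1 - p_test, p_test]), labels=[0, 1])),
        # anomalous recall: anomalous curves NOT passed as normal
        "anomalous_recall": float(np.mean(p_test[anom] <= model.threshold)) if anom.any() else float("nan"),
        "normal_pass_rate": float(np.mean(p_test[~anom] > model.threshold)) if (~anom).any() else float("nan"),
    }
    path = None
    if cfg is not None and cfg.training_model_file:
        path = cfg.training_model_file
        save_model(model, path, metadata={"seed": seed, "split_sizes": [len(tr), len(va), len(te)]})
    return TrainingReport(
        model=model, split_sizes=(len(tr), len(va), len(te)), test_metrics=metrics, model_path=path
    )


def save_model(model: NormalCurveFilter, path, metadata: Optional[dict] = None) -> None:
    """Persist to a self-describing JSON file (layer sizes, weights, metadata)."""
    payload = {
        "format": "glowcurve-qc-filter-v1",
        "architecture": [N_FEATURES, *HIDDEN_LAYER_SIZES, 1],
        "threshold": model.threshold,
        "weights": [w.tolist() for w in model.weights_],
        "biases": [b.tolist() for b in model.biases_],
        "metadata": {
            "n_epochs": model.n_epochs_,
            "validation_loss": model.validation_loss_,
            **(metadata or {}),
        },
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, sort_keys=True, separators=(",", ":"))


def load_model(path) -> NormalCurveFilter:
    with open(path) as fh:
        payload = json.load(fh)
    if payload.get("format") != "glowcurve-qc-filter-v1":
        raise ValueError(f"{path} is not a glow-curve filter model file")
    model = NormalCurveFilter(threshold=float(payload["threshold"]))
    model.weights_ = [np.asarray(w, dtype=float) for w in payload["weights"]]
    model.biases_ = [np.asarray(b, dtype=float) for b in payload["biases"]]
    model.n_epochs_ = payload["metadata"].get("n_epochs", 0)
    model.validation_loss_ = payload["metadata"].get("validation_loss")
    model.classes_ = np.array([0, 1])
    return model
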