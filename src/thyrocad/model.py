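"""Dataset splitting, feature scaling and the two classifiers.

Two binary classifiers operate on the seven-feature texture vectors:

* a feedforward artificial neural network written from scratch — input layer,
  one or more hidden layers with a configurable activation, and a single
  sigmoid output unit trained by full-batch gradient descent on the binary
  cross-entropy loss;
* a max-margin kernel support vector machine, whose quadratic program is
  delegated to scikit-learn's SVC; the decision function evaluated at predict
  time is the dual form  sum_i alpha_i y_i k(x_i, x) + b  computed from the
  stored support vectors.

Features are z-scored with statistics of the training split only; the scaler
travels inside the trained model so test data can never leak into it.
The positive class is "malignant" throughout: ANN scores live in (0, 1) with
default decision threshold 0.5, SVM scores are signed margins with default
threshold 0.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from sklearn.svm import SVC

from .data_io import BENIGN, MALIGNANT
from .texture import FEATURE_NAMES

__all__ = [
    "SplitSpec",
    "MLPConfig",
    "Scaler",
    "TrainedModel",
    "MLP",
    "split",
    "standardize",
    "train_ann",
    "train_svm",
    "predict",
    "save_model",
    "load_model",
]

MODEL_FORMAT_VERSION = 1


@dataclass
class SplitSpec:
    """Train/test partition protocol.

    ``train_fraction`` defaults to 0.87 (an 87:13 split); stratified mode
    rounds the fraction within each label stratum.  ``unit="case"`` keeps all
    images of one case on the same side of the split.
    """

    train_fraction: float = 0.87
    stratified: bool = True
    seed: int = 0
    unit: str = "case"

    def __post_init__(self) -> None:
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must lie strictly between 0 and 1")
        if self.unit not in ("case", "image"):
            raise ValueError("unit must be 'case' or 'image'")


@dataclass
class MLPConfig:
    """Architecture and optimization settings for the neural network."""

    hidden_sizes: tuple[int, ...] = (10,)
    activation: str = "sigmoid"
    learning_rate: float = 0.1
    max_epochs: int = 2000
    tolerance: float = 1e-6
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.hidden_sizes) < 1:
            raise ValueError("at least one hidden layer is required")
        if self.activation not in ("sigmoid", "tanh", "relu"):
            raise ValueError("activation must be sigmoid, tanh or relu")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")


@dataclass
class Scaler:
    """Per-feature z-scoring statistics (population sd convention).

    Constant features (sd == 0) are flagged and mapped to 0.
    """

    mean: np.ndarray
    sd: np.ndarray
    constant: np.ndarray
    feature_names: tuple[str, ...]

    def transform(self, X: np.ndarray) -> np.ndarray:
        sd = np.where(self.constant, 1.0, self.sd)
        Z = (np.asarray(X, dtype=np.float64) - self.mean) / sd
        Z[:, self.constant] = 0.0
        return Z


@dataclass
class TrainedModel:
    """A fitted classifier plus everything needed to apply it."""

    kind: str  # "ann" | "svm"
    parameters: dict
    scaler: Scaler
    decision_threshold: float
    feature_names: tuple[str, ...] = FEATURE_NAMES
    config: dict = field(default_factory=dict)


def _feature_matrix(table: pd.DataFrame, feature_names: tuple[str, ...]) -> np.ndarray:
    missing = [c for c in feature_names if c not in table.columns]
    extra_ok = True  # extra columns (case_id, label, ...) are simply ignored
    if missing:
        raise ValueError(f"feature table is missing columns: {missing}")
    assert extra_ok
    return table.loc[:, list(feature_names)].to_numpy(dtype=np.float64)


def _labels01(table: pd.DataFrame) -> np.ndarray:
    labels = table["label"].to_numpy()
    bad = set(labels) - {BENIGN, MALIGNANT}
    if bad:
        raise ValueError(f"unknown labels: {sorted(bad)}")
    return (labels == MALIGNANT).astype(np.float64)


def split(table: pd.DataFrame, spec: SplitSpec | None = None) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Deterministic train/test split of a feature table.

    The table needs ``label`` and (for unit="case") ``case_id`` columns.
    Stratified mode preserves label proportions to per-stratum rounding and
    requires both labels to be present.
    """
    spec = spec or SplitSpec()
    rng = np.random.default_rng(spec.seed)

    if spec.unit == "case" and "case_id" in table.columns:
        units = table["case_id"].to_numpy()
    else:
        units = np.arange(len(table)).astype(str)
    unit_ids, first_idx = np.unique(units, return_index=True)
    unit_labels = table["label"].to_numpy()[first_idx]

    if spec.stratified:
        strata = sorted(set(unit_labels))
        if len(strata) < 2:
            raise ValueError("stratified split requires both labels to be present")
    else:
        strata = [None]

    train_units: list[str] = []
    for stratum in strata:
        pool = unit_ids if stratum is None else unit_ids[unit_labels == stratum]
        pool = np.sort(pool)
        n_train = int(round(spec.train_fraction * len(pool)))
        n_train = min(max(n_train, 1), len(pool) - 1) if len(pool) > 1 else n_train
        order = rng.permutation(len(pool))
        train_units.extend(pool[order[:n_train]])

    in_train = np.isin(units, train_units)
    train = table.loc[in_train].reset_index(drop=True)
    test = table.loc[~in_train].reset_index(drop=True)
    return train, test


def standardize(table: pd.DataFrame, feature_names: tuple[str, ...] = FEATURE_NAMES) -> tuple[pd.DataFrame, Scaler]:
    """Z-score each feature column; returns the scaled table and the scaler."""
    if len(table) < 2:
        raise ValueError("need at least 2 rows to standardize")
    X = _feature_matrix(table, feature_names)
    mean = X.mean(axis=0)
    sd = X.std(axis=0)  # population sd (ddof=0)
    constant = sd == 0.0
    scaler = Scaler(mean=mean, sd=sd, constant=constant, feature_names=tuple(feature_names))
    scaled = table.copy()
    scaled.loc[:, list(feature_names)] = scaler.transform(X)
    return scaled, scaler


# ---------------------------------------------------------------------------
# Feedforward neural network
# ---------------------------------------------------------------------------

def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


_ACTIVATIONS = {
    "sigmoid": (_sigmoid, lambda a: a * (1.0 - a)),
    "tanh": (np.tanh, lambda a: 1.0 - a ** 2),
    "relu": (lambda z: np.maximum(z, 0.0), lambda a: (a > 0).astype(np.float64)),
}


class MLP:
    """Minimal feedforward network: hidden layers + single sigmoid output.

    Weights are stored as lists ``W[l]`` (fan_in x fan_out) and ``b[l]``.
    The loss is mean binary cross-entropy; gradients are exact backprop.
    """

    def __init__(self, layer_sizes: list[int], activation: str, seed: int = 0):
        self.layer_sizes = layer_sizes
        self.activation = activation
        rng = np.random.default_rng(seed)
        self.W: list[np.ndarray] = []
        self.b: list[np.ndarray] = []
        for fan_in, fan_out in zip(layer_sizes[:-1], layer_sizes[1:]):
            self.W.append(rng.normal(0.0, np.sqrt(1.0 / fan_in), size=(fan_in, fan_out)))
            self.b.append(np.zeros(fan_out))

    def forward(self, X: np.ndarray) -> np.ndarray:
        """Output probabilities in (0, 1), shape (n,)."""
        act, _ = _ACTIVATIONS[self.activation]
        a = X
        for W, b in zip(self.W[:-1], self.b[:-1]):
            a = act(a @ W + b)
        return _sigmoid(a @ self.W[-1] + self.b[-1]).ravel()

    def loss_and_grads(self, X: np.ndarray, y: np.ndarray) -> tuple[float, list[np.ndarray], list[np.ndarray]]:
        """Mean cross-entropy and its gradients w.r.t. every W and b."""
        act, dact = _ACTIVATIONS[self.activation]
        n = X.shape[0]
        activations = [X]
        a = X
        for W, b in zip(self.W[:-1], self.b[:-1]):
            a = act(a @ W + b)
            activations.append(a)
        out = _sigmoid(a @ self.W[-1] + self.b[-1]).ravel()

        eps = 1e-12
        loss = float(-np.mean(y * np.log(out + eps) + (1.0 - y) * np.log(1.0 - out + eps)))

        gW = [np.zeros_like(W) for W in self.W]
        gb = [np.zeros_like(b) for b in self.b]
        # sigmoid + cross-entropy: delta at the output is (p - y) / n
        delta = ((out - y) / n)[:, None]
        for layer in range(len(self.W) - 1, -1, -1):
            gW[layer] = activations[layer].T @ delta
            gb[layer] = delta.sum(axis=0)
            if layer > 0:
                delta = (delta @ self.W[layer].T) * dact(activations[layer])
        return loss, gW, gb

    def fit(self, X: np.ndarray, y: np.ndarray, learning_rate: float,
            max_epochs: int, tolerance: float) -> list[float]:
        """Full-batch gradient descent; returns the per-epoch loss curve."""
        history: list[float] = []
        prev = np.inf
        for epoch in range(max_epochs):
            loss, gW, gb = self.loss_and_grads(X, y)
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite loss at epoch {epoch} (learning_rate={learning_rate})"
                )
            history.append(loss)
            for layer in range(len(self.W)):
                self.W[layer] -= learning_rate * gW[layer]
                self.b[layer] -= learning_rate * gb[layer]
            if abs(prev - loss) < tolerance:
                break
            prev = loss
        return history


def train_ann(train: pd.DataFrame, config: MLPConfig | None = None,
              scaler: Scaler | None = None) -> TrainedModel:
    """Fit the feedforward network on a (raw or pre-scaled) feature table."""
    config = config or MLPConfig()
    y = _labels01(train)
    if len(set(y)) < 2:
        raise ValueError("training data must contain both classes")
    if scaler is None:
        train, scaler = standardize(train)
    X = _feature_matrix(train, scaler.feature_names)

    layer_sizes = [X.shape[1], *config.hidden_sizes, 1]
    net = MLP(layer_sizes, config.activation, seed=config.seed)
    history = net.fit(X, y, config.learning_rate, config.max_epochs, config.tolerance)

    return TrainedModel(
        kind="ann",
        parameters={
            "layer_sizes": layer_sizes,
            "activation": config.activation,
            "weights": [W.tolist() for W in net.W],
            "biases": [b.tolist() for b in net.b],
            "final_loss": history[-1],
            "epochs_run": len(history),
        },
        scaler=scaler,
        decision_threshold=0.5,
        config={
            "hidden_sizes": list(config.hidden_sizes),
            "activation": config.activation,
            "learning_rate": config.learning_rate,
            "max_epochs": config.max_epochs,
            "tolerance": config.tolerance,
            "seed": config.seed,
        },
    )


# ---------------------------------------------------------------------------
# Support vector machine
# ---------------------------------------------------------------------------

def train_svm(train: pd.DataFrame, kernel: str = "rbf", C: float = 1.0,
              scaler: Scaler | None = None, class_weight: Optional[str] = None) -> TrainedModel:
    """Fit a kernel SVM; the QP solve is delegated to scikit-learn's SVC.

    The stored parameters are the dual solution (support vectors, dual
    coefficients alpha_i y_i, intercept, kernel settings); prediction
    evaluates  sum_i alpha_i y_i k(x_i, x) + b  directly from them.
    """
    if kernel not in ("rbf", "linear", "poly"):
        raise ValueError("kernel must be rbf, linear or poly")
    y = _labels01(train)
    if len(set(y)) < 2:
        raise ValueError("training data must contain both classes")
    if scaler is None:
        train, scaler = standardize(train)
    X = _feature_matrix(train, scaler.feature_names)

    svc = SVC(kernel=kernel, C=C, gamma="scale", class_weight=class_weight)
    svc.fit(X, y)
    return TrainedModel(
        kind="svm",
        parameters={
            "kernel": kernel,
            "gamma": float(svc._gamma),
            "coef0": float(svc.coef0),
            "degree": int(svc.degree),
            "support_vectors": svc.support_vectors_.tolist(),
            "dual_coef": svc.dual_coef_.ravel().tolist(),
            "intercept": float(svc.intercept_[0]),
        },
        scaler=scaler,
        decision_threshold=0.0,
        config={"kernel": kernel, "C": C, "class_weight": class_weight},
    )


def _kernel_matrix(params: dict, A: np.ndarray, B: np.ndarray) -> np.ndarray:
    kind = params["kernel"]
    gamma = params["gamma"]
    if kind == "linear":
        return A @ B.T
    if kind == "poly":
        return (gamma * (A @ B.T) + params["coef0"]) ** params["degree"]
    # rbf
    sq = (A ** 2).sum(axis=1)[:, None] + (B ** 2).sum(axis=1)[None, :] - 2.0 * (A @ B.T)
    return np.exp(-gamma * np.maximum(sq, 0.0))


def _decision_scores(model: TrainedModel, Z: np.ndarray) -> np.ndarray:
    if model.kind == "ann":
        p = model.parameters
        net = MLP(p["layer_sizes"], p["activation"])
        net.W = [np.asarray(W, dtype=np.float64) for W in p["weights"]]
        net.b = [np.asarray(b, dtype=np.float64) for b in p["biases"]]
        return net.forward(Z)
    p = model.parameters
    sv = np.asarray(p["support_vectors"], dtype=np.float64)
    dual = np.asarray(p["dual_coef"], dtype=np.float64)
    K = _kernel_matrix(p, Z, sv)
    return K @ dual + p["intercept"]


def predict(model: TrainedModel, table: pd.DataFrame) -> pd.DataFrame:
    """Apply the stored scaler and decision function to a feature table.

    Returns a frame with ``case_id`` (when present), ``score`` and ``label``;
    label is malignant iff score >= the model's decision threshold.
    """
    extra = [c for c in table.columns
             if c not in model.feature_names and c not in ("case_id", "label")]
    missing = [c for c in model.feature_names if c not in table.columns]
    if missing:
        raise ValueError(f"feature table is missing columns: {missing}; unexpected: {extra}")
    X = _feature_matrix(table, model.feature_names)
    scores = _decision_scores(model, model.scaler.transform(X))
    labels = np.where(scores >= model.decision_threshold, MALIGNANT, BENIGN)
    out = pd.DataFrame({"score": scores, "label": labels})
    if "case_id" in table.columns:
        out.insert(0, "case_id", table["case_id"].to_numpy())
    return out


# ---------------------------------------------------------------------------
# Serialization: one versioned JSON container per model
# ---------------------------------------------------------------------------

def save_model(model: TrainedModel, path: str | Path) -> None:
    payload = {
        "format_version": MODEL_FORMAT_VERSION,
        "kind": model.kind,
        "decision_threshold": model.decision_threshold,
        "feature_names": list(model.feature_names),
        "config": model.config,
        "scaler": {
            "mean": model.scaler.mean.tolist(),
            "sd": model.scaler.sd.tolist(),
            "constant": model.scaler.constant.tolist(),
        },
        "parameters": model.parameters,
    }
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))


def load_model(path: str | Path) -> TrainedModel:
    payload = json.loads(Path(path).read_text())
    if payload.get("format_version") != MODEL_FORMAT_VERSION:
        raise ValueError(f"unsupported model format version: {payload.get('format_version')}")
    names = tuple(payload["feature_names"])
    scaler = Scaler(
        mean=np.asarray(payload["scaler"]["mean"], dtype=np.float64),
        sd=np.asarray(payload["scaler"]["sd"], dtype=np.float64),
        constant=np.asarray(payload["scaler"]["constant"], dtype=bool),
        feature_names=names,
    )
    return TrainedModel(
        kind=payload["kind"],
        parameters=payload["parameters"],
        scaler=scaler,
        decision_threshold=float(payload["decision_threshold"]),
        feature_names=names,
        config=payload.get("config", {}),
    )
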