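"""Feed-forward neural-network species classifier, written from scratch.

The classifier predicts the species of an ant worker from its 21 trait
measurements, its infection status, and the 21 trait-by-infection
product columns (43 predictors in all).  The network has three hidden
layers of ten logistic units; class probabilities are a softmax over
the output pre-activations, trained with full-batch gradient descent on
the multiclass cross-entropy loss.  (A logistic squash on the output
nodes before the softmax would cap every logit difference at 1 —
probability ratios at e — and starves minority classes of gradient; the
linear-output softmax head is the standard multiclass pairing for
cross-entropy and is used here.)

Generalisation is assessed with stratified k-fold cross-validation
(class proportions preserved across folds); per-fold confusion matrices
yield accuracy, macro precision/sensitivity/specificity and the
multiclass Matthews correlation coefficient (the R_k statistic).

Predictor z-scaling is refit on the training rows of every fold — the
held-out fold never influences the scaling parameters.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DivergenceError, StratificationError
from .morphdata import SpecimenTable

__all__ = [
    "NNConfig",
    "NNModel",
    "ColumnScaler",
    "CVReport",
    "build_model_matrix",
    "train_nn",
    "stratified_kfold",
    "cross_validate",
    "confusion_matrix",
    "classification_metrics",
]

METRIC_NAMES = ("accuracy", "precision", "sensitivity", "specificity", "mcc")


def build_model_matrix(table: SpecimenTable):
    """Predictor matrix and class labels for the species classifier.

    Columns are the traits (raw micrometres), the 0/1 infection
    indicator, and one ``trait x infected`` product column per trait —
    43 columns for the 21-trait registry.  Returns ``(X, y, names)``
    with rows aligned to the table.
    """
    traits = table.trait_matrix()
    infected = table.data["infected"].to_numpy(float)[:, None]
    X = np.hstack([traits, infected, traits * infected])
    names = (
        list(table.registry)
        + ["infected"]
        + [f"{t}:infected" for t in table.registry]
    )
    y = table.data["species"].to_numpy(str)
    return X, y, names


@dataclass
class ColumnScaler:
    """Per-column z-scaler whose parameters come from training rows only.

    Constant columns (SD 0, e.g. the infection indicator in an all-
    uninfected fold) are centred but left unscaled.
    """

    mean: np.ndarray | None = None
    sd: np.ndarray | None = None

    def fit(self, X: np.ndarray) -> "ColumnScaler":
        self.mean = X.mean(axis=0)
        sd = X.std(axis=0)
        self.sd = np.where(sd > 0, sd, 1.0)
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        if self.mean is None:
            raise ValueError("scaler is not fitted")
        return (X - self.mean) / self.sd


@dataclass(frozen=True)
class NNConfig:
    """Training hyperparameters (the architecture is fixed at three
    hidden layers of ten units)."""

    hidden: tuple[int, ...] = (10, 10, 10)
    learning_rate: float = 0.05
    epochs: int = 5000
    tol: float = 1e-8  # stop when the loss change falls below this
    seed: int = 0


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def _softmax(a: np.ndarray) -> np.ndarray:
    e = np.exp(a - a.max(axis=1, keepdims=True))
    return e / e.sum(axis=1, keepdims=True)


@dataclass
class NNModel:
    """A trained network: per-layer weights/biases plus the canonical
    class order used for one-hot coding and argmax tie-breaking."""

    weights: list[np.ndarray]
    biases: list[np.ndarray]
    classes: list[str]
    config: NNConfig = field(default_factory=NNConfig)
    loss_history: np.ndarray = field(default_factory=lambda: np.empty(0))

    @property
    def n_inputs(self) -> int:
        return self.weights[0].shape[0]

    def _forward(self, X: np.ndarray):
        activations = [X]
        a = X
        for W, b in zip(self.weights[:-1], self.biases[:-1]):
            a = _sigmoid(a @ W + b)
            activations.append(a)
        logits = a @ self.weights[-1] + self.biases[-1]
        proba = _softmax(logits)
        return activations, proba

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.n_inputs:
            raise ValueError(
                f"expected {self.n_inputs} predictor columns, got {X.shape[1]}"
            )
        return self._forward(X)[1]

    def predict(self, X: np.ndarray) -> np.ndarray:
        proba = self.predict_proba(X)
        idx = proba.argmax(axis=1)  # argmax takes the lowest index on ties
        return np.asarray(self.classes, dtype=object)[idx]

    # -- plain-text serialisation ------------------------------------

    def to_json(self) -> str:
        doc = {
            "classes": list(self.classes),
            "weights": [W.tolist() for W in self.weights],
            "biases": [b.tolist() for b in self.biases],
            "config": {
                "hidden": list(self.config.hidden),
                "learning_rate": self.config.learning_rate,
                "epochs": self.config.epochs,
                "tol": self.config.tol,
                "seed": self.config.seed,
            },
        }
        return json.dumps(doc)

    @classmethod
    def from_json(cls, text: str) -> "NNModel":
        doc = json.loads(text)
        cfg = doc.get("config", {})
        return cls(
            weights=[np.asarray(W, dtype=float) for W in doc["weights"]],
            biases=[np.asarray(b, dtype=float) for b in doc["biases"]],
            classes=list(doc["classes"]),
            config=NNConfig(
                hidden=tuple(cfg.get("hidden", (10, 10, 10))),
                learning_rate=cfg.get("learning_rate", 0.05),
                epochs=cfg.get("epochs", 5000),
                tol=cfg.get("tol", 1e-8),
                seed=cfg.get("seed", 0),
            ),
        )


def _init_model(n_in: int, classes: list[str], config: NNConfig) -> NNModel:
    rng = np.random.default_rng(config.seed)
    sizes = (n_in, *config.hidden, len(classes))
    weights, biases = [], []
    for fan_in, fan_out in zip(sizes[:-1], sizes[1:]):
        limit = np.sqrt(6.0 / (fan_in + fan_out))  # Xavier uniform
        weights.append(rng.uniform(-limit, limit, size=(fan_in, fan_out)))
        biases.append(np.zeros(fan_out))
    return NNModel(weights=weights, biases=biases, classes=classes,
                   config=config)


def cross_entropy(proba: np.ndarray, onehot: np.ndarray) -> float:
    eps = 1e-12
    return float(-(onehot * np.log(proba + eps)).sum(axis=1).mean())


def train_nn(X: np.ndarray, y, config: NNConfig | None = None) -> NNModel:
    """Train the classifier by backpropagation with full-batch gradient
    descent.

    Deterministic given ``config.seed``.  Training stops after
    ``config.epochs`` epochs or when the loss improves by less than
    ``config.tol``.  A non-finite loss raises :class:`DivergenceError`.
    """
    config = config or NNConfig()
    X = np.asarray(X, dtype=float)
    if not np.isfinite(X).all():
        raise ValueError("predictor matrix contains non-finite values")
    classes = sorted(set(map(str, y)))
    if len(classes) < 2:
        raise ValueError("need at least 2 classes to train a classifier")
    index = {c: i for i, c in enumerate(classes)}
    onehot = np.zeros((len(X), len(classes)))
    onehot[np.arange(len(X)), [index[str(label)] for label in y]] = 1.0

    model = _init_model(X.shape[1], classes, config)
    n = len(X)
    losses = []
    prev = np.inf
    for _ in range(config.epochs):
        activations, proba = model._forward(X)
        loss = cross_entropy(proba, onehot)
        if not np.isfinite(loss):
            raise DivergenceError(
                "training loss became non-finite; reduce the learning rate"
            )
        losses.append(loss)
        if prev - loss < config.tol and prev >= loss:
            break
        prev = loss
        # backprop: softmax + cross-entropy gives dL/dz_out = p - y;
        # hidden layers pass through the logistic derivative a(1-a)
        delta = (proba - onehot) / n
        for layer in range(len(model.weights) - 1, -1, -1):
            a_prev = activations[layer]
            grad_W = a_prev.T @ delta
            grad_b = delta.sum(axis=0)
            if layer > 0:
                delta = (delta @ model.weights[layer].T) * a_prev * (
                    1.0 - a_prev
                )
            model.weights[layer] -= config.learning_rate * grad_W
            model.biases[layer] -= config.learning_rate * grad_b
    model.loss_history = np.asarray(losses)
    return model


# -- cross-validation -------------------------------------------------


def stratified_kfold(labels, k: int = 10, seed: int = 0) -> np.ndarray:
    """Assign each row to one of ``k`` folds, stratified by class.

    Each class's members are shuffled (by ``seed``) and dealt to folds
    in round-robin order, so per-class fold counts differ by at most
    one; classes are dealt consecutively so total fold sizes also stay
    balanced.  Deterministic given the seed.
    """
    labels = np.asarray(labels)
    if not 2 <= k <= len(labels):
        raise StratificationError(
            f"k={k} must be between 2 and the number of rows"
        )
    rng = np.random.default_rng(seed)
    folds = np.empty(len(labels), dtype=int)
    pointer = 0
    for cls in sorted(set(map(str, labels))):
        members = np.flatnonzero(labels.astype(str) == cls)
        if len(members) < 2:
            raise StratificationError(
                f"class {cls!r} has {len(members)} member(s); need >= 2 "
                "to stratify"
            )
        rng.shuffle(members)
        for idx in members:
            folds[idx] = pointer % k
            pointer += 1
    return folds


def confusion_matrix(y_true, y_pred, classes: list[str]) -> np.ndarray:
    """k x k count matrix; rows = true class, columns = predicted."""
    index = {c: i for i, c in enumerate(classes)}
    mat = np.zeros((len(classes), len(classes)), dtype=int)
    for t, p in zip(y_true, y_pred):
        mat[index[str(t)], index[str(p)]] += 1
    return mat


def _safe_div(num, den):
    return num / den if den > 0 else 0.0


def classification_metrics(confusion: np.ndarray,
                           averaging: str = "macro") -> dict[str, float]:
    """Metric set from a k x k confusion matrix (rows = truth).

    Precision, sensitivity and specificity are one-vs-rest per class and
    then macro-averaged (``averaging='micro'`` pools the one-vs-rest
    counts instead).  The MCC is the multiclass R_k statistic, which
    reduces to the familiar binary formula on 2 x 2 matrices.
    """
    mat = np.asarray(confusion, dtype=float)
    total = mat.sum()
    if total <= 0:
        raise ValueError("confusion matrix has no counts")
    k = mat.shape[0]
    tp = np.diag(mat)
    row = mat.sum(axis=1)  # true counts t_k
    col = mat.sum(axis=0)  # predicted counts p_k
    fp = col - tp
    fn = row - tp
    tn = total - tp - fp - fn

    if averaging == "macro":
        precision = float(np.mean([_safe_div(tp[i], tp[i] + fp[i])
                                   for i in range(k)]))
        sensitivity = float(np.mean([_safe_div(tp[i], tp[i] + fn[i])
                                     for i in range(k)]))
        specificity = float(np.mean([_safe_div(tn[i], tn[i] + fp[i])
                                     for i in range(k)]))
    elif averaging == "micro":
        precision = _safe_div(tp.sum(), tp.sum() + fp.sum())
        sensitivity = _safe_div(tp.sum(), tp.sum() + fn.sum())
        specificity = _safe_div(tn.sum(), tn.sum() + fp.sum())
    else:
        raise ValueError("averaging must be 'macro' or 'micro'")

    # multiclass MCC (R_k): (c*s - sum p_k t_k) /
    #   sqrt((s^2 - sum p_k^2)(s^2 - sum t_k^2))
    c, s = tp.sum(), total
    cov_xy = c * s - float(col @ row)
    cov_xx = s * s - float(col @ col)
    cov_yy = s * s - float(row @ row)
    denom = np.sqrt(cov_xx) * np.sqrt(cov_yy)
    mcc = cov_xy / denom if denom > 0 else 0.0

    return {
        "accuracy": float(tp.sum() / total),
        "precision": precision,
        "sensitivity": sensitivity,
        "specificity": specificity,
        "mcc": float(mcc),
    }


@dataclass(frozen=True)
class CVReport:
    """Cross-validation outcome: per-fold confusion matrices, a metric
    table with one row per fold plus an ``averaged`` row (arithmetic
    mean of the fold rows), and the canonical class order."""

    confusions: list[np.ndarray]
    metrics: pd.DataFrame
    classes: list[str]

    @property
    def averaged(self) -> pd.Series:
        return self.metrics.loc["averaged"]

    def to_frame(self) -> pd.DataFrame:
        """Report layout: kth Model, Accuracy, Precision, Sensitivity,
        Specificity, MCC (one row per fold plus the averaged row)."""
        out = self.metrics.rename(
            columns={
                "accuracy": "Accuracy", "precision": "Precision",
                "sensitivity": "Sensitivity", "specificity": "Specificity",
                "mcc": "MCC",
            }
        )
        out.index.name = "kth Model"
        return out.reset_index()


def cross_validate(
    table: SpecimenTable,
    k: int = 10,
    config: NNConfig | None = None,
    seed: int = 0,
    averaging: str = "macro",
) -> CVReport:
    """Stratified k-fold cross-validation of the species classifier.

    For every fold: fit the column scaler on the training rows only,
    train the network on the scaled training rows, predict the held-out
    rows, and score the fold's confusion matrix.  ``seed`` drives both
    the fold assignment and (offset per fold) the weight initialisation.
    """
    config = config or NNConfig()
    X, y, _ = build_model_matrix(table)
    classes = sorted(set(map(str, y)))
    folds = stratified_kfold(y, k=k, seed=seed)

    confusions = []
    rows = []
    for fold in range(k):
        test = folds == fold
        train = ~test
        scaler = ColumnScaler().fit(X[train])
        fold_cfg = NNConfig(
            hidden=config.hidden,
            learning_rate=config.learning_rate,
            epochs=config.epochs,
            tol=config.tol,
            seed=config.seed + 1000 * fold + seed,
        )
        model = train_nn(scaler.transform(X[train]), y[train], fold_cfg)
        pred = model.predict(scaler.transform(X[test]))
        mat = confusion_matrix(y[test], pred, classes)
        assert mat.sum() == test.sum()
        confusions.append(mat)
        rows.append(classification_metrics(mat, averaging=averaging))

    metrics = pd.DataFrame(rows, index=[str(i + 1) for i in range(k)])
    metrics.loc["averaged"] = metrics.mean(axis=0)
    return CVReport(confusions=confusions, metrics=metrics, classes=classes)
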