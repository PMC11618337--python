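"""MLP classification protocol: feature selection, min-max normalization,
a four-layer fully connected network with batch normalization and leaky
ReLU, ten-fold cross-validation, and permutation feature importance.

The network is implemented directly on numpy: four linear layers
(9 -> h1 -> h2 -> h3 -> 1), batch normalization after each hidden linear
layer, leaky-ReLU activations, a sigmoid output trained with binary
cross-entropy under ADAM. The learning rate starts at 1e-5 and drops
permanently to 1e-6 once per-epoch training accuracy reaches 95%; training
runs 200 epochs and the model state at the lowest validation loss is kept.
"""

from __future__ import annotations

import copy
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedGroupKFold, StratifiedKFold

#: the nine parameters showing (borderline-)significant child-group contrasts
SELECTED_FEATURES = (
    "reaction_time_s",
    "total_distance_m",
    "avg_velocity_mps",
    "max_velocity_mps",
    "time_to_peak_velocity_s",
    "avg_acceleration_mps2",
    "max_acceleration_mps2",
    "time_to_peak_acceleration_s",
    "mu_type2_rms",
)


def minmax_normalize(
    matrix: np.ndarray, bounds: tuple[np.ndarray, np.ndarray] | None = None
) -> tuple[np.ndarray, tuple[np.ndarray, np.ndarray]]:
    """Scale each column to [0, 1] as (x - min) / (max - min).

    By default the bounds come from the matrix itself (whole-dataset
    normalization, as in the original protocol — note this leaks validation
    statistics into training; pass per-training-fold ``bounds`` to avoid it).
    Constant columns map to all-zeros with a warning.
    """
    X = np.asarray(matrix, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need a 2-D matrix with at least 2 rows")
    if not np.all(np.isfinite(X)):
        raise ValueError("matrix contains non-finite values")
    if bounds is None:
        lo, hi = X.min(axis=0), X.max(axis=0)
    else:
        lo, hi = (np.asarray(b, dtype=float) for b in bounds)
    span = hi - lo
    const = span == 0
    if np.any(const):
        warnings.warn(
            f"{int(const.sum())} constant column(s) mapped to zeros", stacklevel=2
        )
    safe = np.where(const, 1.0, span)
    out = (X - lo) / safe
    out[:, const] = 0.0
    return out, (lo, hi)


@dataclass(frozen=True)
class MLPSpec:
    """Architecture and training schedule."""

    hidden: tuple[int, int, int] = (64, 32, 16)
    leaky_slope: float = 0.01
    lr_initial: float = 1e-5
    lr_reduced: float = 1e-6
    lr_switch_train_accuracy: float = 0.95
    epochs: int = 200
    batch_size: int = 32


class _Linear:
    kind = "linear"

    def __init__(self, fan_in: int, fan_out: int, rng: np.random.Generator):
        bound = 1.0 / np.sqrt(fan_in)
        self.W = rng.uniform(-bound, bound, size=(fan_in, fan_out))
        self.b = rng.uniform(-bound, bound, size=fan_out)
        self.gW = np.zeros_like(self.W)
        self.gb = np.zeros_like(self.b)

    def forward(self, x, training):
        self._x = x
        return x @ self.W + self.b

    def backward(self, grad):
        self.gW = self._x.T @ grad
        self.gb = grad.sum(axis=0)
        return grad @ self.W.T

    def params(self):
        return [("W", self.W, self.gW), ("b", self.b, self.gb)]


class _BatchNorm:
    kind = "batchnorm"
    eps = 1e-5
    momentum = 0.1

    def __init__(self, width: int):
        self.gamma = np.ones(width)
        self.beta = np.zeros(width)
        self.running_mean = np.zeros(width)
        self.running_var = np.ones(width)
        self.ggamma = np.zeros(width)
        self.gbeta = np.zeros(width)

    def forward(self, x, training):
        if training:
            mu = x.mean(axis=0)
            var = x.var(axis=0)
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mu
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var
        else:
            mu, var = self.running_mean, self.running_var
        self._xhat = (x - mu) / np.sqrt(var + self.eps)
        self._var = var
        return self.gamma * self._xhat + self.beta

    def backward(self, grad):
        xhat = self._xhat
        m = xhat.shape[0]
        self.ggamma = (grad * xhat).sum(axis=0)
        self.gbeta = grad.sum(axis=0)
        dxhat = grad * self.gamma
        return (
            (dxhat * m - dxhat.sum(axis=0) - xhat * (dxhat * xhat).sum(axis=0))
            / (m * np.sqrt(self._var + self.eps))
        )

    def params(self):
        return [("gamma", self.gamma, self.ggamma), ("beta", self.beta, self.gbeta)]


class _LeakyReLU:
    kind = "leaky_relu"

    def __init__(self, slope: float):
        self.slope = slope

    def forward(self, x, training):
        self._mask = x > 0
        return np.where(self._mask, x, self.slope * x)

    def backward(self, grad):
        return np.where(self._mask, grad, self.slope * grad)

    def params(self):
        return []


class _Sigmoid:
    kind = "sigmoid"

    def forward(self, x, training):
        return 1.0 / (1.0 + np.exp(-x))

    def backward(self, grad):  # combined with BCE; never called alone
        raise NotImplementedError

    def params(self):
        return []


class MLPModel:
    """Four fully connected layers, three batch norms, three leaky ReLUs,
    one sigmoid output."""

    def __init__(self, n_features: int, spec: MLPSpec, rng: np.random.Generator):
        self.spec = spec
        h1, h2, h3 = spec.hidden
        self.layers = [
            _Linear(n_features, h1, rng),
            _BatchNorm(h1),
            _LeakyReLU(spec.leaky_slope),
            _Linear(h1, h2, rng),
            _BatchNorm(h2),
            _LeakyReLU(spec.leaky_slope),
            _Linear(h2, h3, rng),
            _BatchNorm(h3),
            _LeakyReLU(spec.leaky_slope),
            _Linear(h3, 1, rng),
            _Sigmoid(),
        ]

    def _logits(self, X, training):
        h = X
        for layer in self.layers[:-1]:
            h = layer.forward(h, training)
        return h[:, 0]

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        z = self._logits(np.asarray(X, dtype=float), training=False)
        return 1.0 / (1.0 + np.exp(-z))

    def predict(self, X: np.ndarray, threshold: float = 0.5) -> np.ndarray:
        return (self.predict_proba(X) >= threshold).astype(int)

    def state(self) -> list:
        return copy.deepcopy(
            [
                {
                    name: value.copy()
                    for name, value, _ in getattr(layer, "params", lambda: [])()
                }
                | (
                    {"running_mean": layer.running_mean.copy(),
                     "running_var": layer.running_var.copy()}
                    if layer.kind == "batchnorm"
                    else {}
                )
                for layer in self.layers
            ]
        )

    def load_state(self, state: list) -> None:
        for layer, snap in zip(self.layers, state):
            for name, value in snap.items():
                setattr(layer, name, value.copy())


def bce_loss(p: np.ndarray, y: np.ndarray) -> float:
    p = np.clip(p, 1e-12, 1 - 1e-12)
    return float(-(y * np.log(p) + (1 - y) * np.log(1 - p)).mean())


@dataclass
class TrainResult:
    model: MLPModel
    best_val_loss: float
    best_epoch: int
    train_accuracy: list[float]
    val_loss: list[float]
    lr_history: list[float]


class _Adam:
    def __init__(self, beta1=0.9, beta2=0.999, eps=1e-8):
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m: dict = {}
        self.v: dict = {}
        self.t = 0

    def step(self, model: MLPModel, lr: float) -> None:
        self.t += 1
        for li, layer in enumerate(model.layers):
            for name, value, grad in layer.params():
                key = (li, name)
                m = self.m.setdefault(key, np.zeros_like(value))
                v = self.v.setdefault(key, np.zeros_like(value))
                m *= self.beta1
                m += (1 - self.beta1) * grad
                v *= self.beta2
                v += (1 - self.beta2) * grad * grad
                mhat = m / (1 - self.beta1**self.t)
                vhat = v / (1 - self.beta2**self.t)
                value -= lr * mhat / (np.sqrt(vhat) + self.eps)


def train_mlp(
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_val: np.ndarray,
    y_val: np.ndarray,
    spec: MLPSpec | None = None,
    seed: int = 0,
) -> TrainResult:
    """Train the MLP for the fixed number of epochs; keep the best-loss state.

    Mini-batch ADAM with the two-level learning-rate schedule; the model
    state at the epoch with the lowest validation BCE is restored at the end.
    Deterministic under ``seed``.
    """
    spec = spec or MLPSpec()
    X_train = np.asarray(X_train, dtype=float)
    y_train = np.asarray(y_train, dtype=float)
    X_val = np.asarray(X_val, dtype=float)
    y_val = np.asarray(y_val, dtype=float)
    classes = np.unique(y_train)
    if classes.size < 2:
        raise ValueError("training set must contain both classes")

    rng = np.random.default_rng(seed)
    model = MLPModel(X_train.shape[1], spec, rng)
    opt = _Adam()
    lr = spec.lr_initial
    n = X_train.shape[0]

    best_val_loss = np.inf
    best_epoch = -1
    best_state = model.state()
    train_acc_hist: list[float] = []
    val_loss_hist: list[float] = []
    lr_hist: list[float] = []

    for epoch in range(spec.epochs):
        lr_hist.append(lr)
        order = rng.permutation(n)
        for start in range(0, n, spec.batch_size):
            sel = order[start : start + spec.batch_size]
            if sel.size < 2:  # batch norm needs >= 2 samples
                continue
            Xb, yb = X_train[sel], y_train[sel]
            logits = model._logits(Xb, training=True)
            p = 1.0 / (1.0 + np.exp(-logits))
            grad = ((p - yb) / sel.size)[:, None]  # d(BCE)/d(logit)
            for layer in reversed(model.layers[:-1]):
                grad = layer.backward(grad)
            opt.step(model, lr)

        train_acc = float((model.predict(X_train) == y_train).mean())
        val_loss = bce_loss(model.predict_proba(X_val), y_val)
        train_acc_hist.append(train_acc)
        val_loss_hist.append(val_loss)
        if val_loss < best_val_loss:
            best_val_loss = val_loss
            best_epoch = epoch
            best_state = model.state()
        if train_acc >= spec.lr_switch_train_accuracy:
            lr = spec.lr_reduced  # permanent switch

    model.load_state(best_state)
    return TrainResult(
        model=model,
        best_val_loss=best_val_loss,
        best_epoch=best_epoch,
        train_accuracy=train_acc_hist,
        val_loss=val_loss_hist,
        lr_history=lr_hist,
    )


@dataclass
class CVResult:
    fold_accuracies: list[float]
    fold_val_losses: list[float]
    fold_assignments: np.ndarray  # fold index per row
    seed: int
    k: int
    grouping: str
    sensitivity: float
    specificity: float

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean(self.fold_accuracies))


def cross_validate(
    X: np.ndarray,
    y: np.ndarray,
    spec: MLPSpec | None = None,
    k: int = 10,
    grouping: str = "trial",
    subject_ids=None,
    seed: int = 0,
    normalization: str = "dataset",
    collect_models: bool = False,
) -> CVResult | tuple[CVResult, list[TrainResult], list[np.ndarray]]:
    """Stratified k-fold cross-validation of the MLP.

    ``grouping="trial"`` assigns rows to folds independently (replicating
    the original protocol, which lets trials of one subject straddle folds);
    ``grouping="subject"`` keeps each subject's trials in a single fold.
    ``normalization="dataset"`` min-max scales over all rows before
    splitting (as in the original protocol); ``"fold"`` scales with
    training-fold bounds only.
    """
    spec = spec or MLPSpec()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.shape[0] < k:
        raise ValueError("need at least k rows")
    if normalization == "dataset":
        Xn, _ = minmax_normalize(X)
    elif normalization == "fold":
        Xn = X  # scaled per fold below
    else:
        raise ValueError(f"unknown normalization {normalization!r}")

    if grouping == "trial":
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        splits = splitter.split(Xn, y)
    elif grouping == "subject":
        if subject_ids is None:
            raise ValueError("subject grouping requires subject_ids")
        subject_ids = np.asarray(subject_ids)
        n_groups = np.unique(subject_ids).size
        if n_groups < k:
            warnings.warn(
                f"only {n_groups} subjects; reducing k from {k} to {n_groups}",
                stacklevel=2,
            )
            k = n_groups
        splitter = StratifiedGroupKFold(n_splits=k, shuffle=True, random_state=seed)
        splits = splitter.split(Xn, y, groups=subject_ids)
    else:
        raise ValueError(f"unknown grouping {grouping!r}")

    fold_acc: list[float] = []
    fold_loss: list[float] = []
    assignment = np.full(X.shape[0], -1, dtype=int)
    results: list[TrainResult] = []
    val_indices: list[np.ndarray] = []
    tp = tn = fp = fn = 0
    for fold, (tr, va) in enumerate(splits):
        if normalization == "fold":
            Xtr, bounds = minmax_normalize(X[tr])
            Xva, _ = minmax_normalize(X[va], bounds=bounds)
            Xva = np.clip(Xva, 0.0, 1.0)
        else:
            Xtr, Xva = Xn[tr], Xn[va]
        res = train_mlp(Xtr, y[tr], Xva, y[va], spec, seed=seed + fold)
        pred = res.model.predict(Xva)
        fold_acc.append(float((pred == y[va]).mean()))
        fold_loss.append(res.best_val_loss)
        assignment[va] = fold
        tp += int(((pred == 1) & (y[va] == 1)).sum())
        tn += int(((pred == 0) & (y[va] == 0)).sum())
        fp += int(((pred == 1) & (y[va] == 0)).sum())
        fn += int(((pred == 0) & (y[va] == 1)).sum())
        if collect_models:
            results.append(res)
            val_indices.append(va)
    cv = CVResult(
        fold_accuracies=fold_acc,
        fold_val_losses=fold_loss,
        fold_assignments=assignment,
        seed=seed,
        k=k,
        grouping=grouping,
        sensitivity=tp / (tp + fn) if tp + fn else float("nan"),
        specificity=tn / (tn + fp) if tn + fp else float("nan"),
    )
    if collect_models:
        return cv, results, val_indices
    return cv


def permutation_importance(
    result: TrainResult,
    X_val: np.ndarray,
    y_val: np.ndarray,
    n_repeats: int = 20,
    seed: int = 0,
    feature_names=None,
) -> pd.DataFrame:
    """Permutation feature importance on one validation set.

    Each column is shuffled ``n_repeats`` times within the validation set;
    the importance is mean(permuted loss) - best validation loss of the
    trained model. Returns a DataFrame with columns feature, delta_loss, rank.
    """
    X_val = np.asarray(X_val, dtype=float)
    y_val = np.asarray(y_val, dtype=float)
    rng = np.random.default_rng(seed)
    base = result.best_val_loss
    deltas = []
    for j in range(X_val.shape[1]):
        losses = []
        for _ in range(n_repeats):
            Xp = X_val.copy()
            Xp[:, j] = Xp[rng.permutation(X_val.shape[0]), j]
            losses.append(bce_loss(result.model.predict_proba(Xp), y_val))
        deltas.append(float(np.mean(losses)) - base)
    names = list(feature_names) if feature_names is not None else [
        f"feature_{j}" for j in range(X_val.shape[1])
    ]
    table = pd.DataFrame({"feature": names, "delta_loss": deltas})
    table["rank"] = table["delta_loss"].rank(ascending=False, method="first").astype(int)
    return table.sort_values("rank").reset_index(drop=True)


def cv_permutation_importance(
    X: np.ndarray,
    y: np.ndarray,
    spec: MLPSpec | None = None,
    k: int = 10,
    grouping: str = "trial",
    subject_ids=None,
    seed: int = 0,
    n_repeats: int = 20,
    feature_names=None,
    normalization: str = "dataset",
) -> tuple[CVResult, pd.DataFrame]:
    """Cross-validated permutation importance: per-fold importances averaged
    over folds. Returns (CVResult, importance table)."""
    spec = spec or MLPSpec()
    cv, results, val_indices = cross_validate(
        X, y, spec, k=k, grouping=grouping, subject_ids=subject_ids, seed=seed,
        normalization=normalization, collect_models=True,
    )
    Xn, _ = minmax_normalize(np.asarray(X, dtype=float))
    yarr = np.asarray(y, dtype=float)
    tables = []
    for fold, (res, va) in enumerate(zip(results, val_indices)):
        tables.append(
            permutation_importance(
                res, Xn[va], yarr[va], n_repeats=n_repeats, seed=seed + 1000 + fold,
                feature_names=feature_names,
            )
        )
    merged = (
        pd.concat(tables)
        .groupby("feature", as_index=False)["delta_loss"]
        .mean()
    )
    merged["rank"] = merged["delta_loss"].rank(ascending=False, method="first").astype(int)
    return cv, merged.sort_values("rank").reset_index(drop=True)


def audit_architecture(model: MLPModel) -> dict[str, int]:
    """Count layer kinds for the structural contract check."""
    counts: dict[str, int] = {}
    for layer in model.layers:
        counts[layer.kind] = counts.get(layer.kind, 0) + 1
    return counts


def build_feature_matrix(
    features: pd.DataFrame,
    labels: tuple[str, str] = ("TD", "ASD"),
    feature_names=SELECTED_FEATURES,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Assemble (X, y, subject_ids) for a two-group contrast.

    Label 0 is the first group in ``labels``, label 1 the second. Rows keep
    the feature-table order; column order follows ``feature_names``.
    """
    df = features[features["group"].isin(labels)].reset_index(drop=True)
    if df.empty:
        raise ValueError(f"no rows for groups {labels}")
    X = df[list(feature_names)].to_numpy(dtype=float)
    y = (df["group"] == labels[1]).to_numpy(dtype=int)
    return X, y, df["subject"].to_numpy()
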