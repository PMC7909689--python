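"""Multilayer-perceptron classifiers, the cross-validation protocol, and
architecture selection; plus a logistic-regression baseline on shared folds.

The network is a feed-forward binary classifier written directly on NumPy:
ReLU hidden layers with optional (inverted) dropout, a single sigmoid output
unit, binary cross-entropy loss minimised with ADAM.  Training holds out a
random fraction of the training rows as an internal validation set; weights
are restored from the epoch with the highest internal-validation accuracy
(earliest epoch on ties), not from the final epoch, to limit overfitting.
Writing the network by hand keeps the saliency gradient (``d p / d input``)
analytic and exactly reproducible.

Cross-validation partitions the cohort into ``n_splits`` stratified folds;
each (split, repetition, architecture) triple trains an independent model,
the repetition index perturbing only the training seed.  The winning
architecture is the one whose best-per-split models have the highest mean
test accuracy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import KFold, StratifiedKFold

from .evaluation import MetricsReport, compute_metrics

__all__ = [
    "ArchitectureSpec",
    "TrainParams",
    "TrainingError",
    "TrainedModel",
    "CVConfig",
    "CVEntry",
    "CVResult",
    "DEFAULT_ARCHITECTURES",
    "best_epoch_from_history",
    "train_mlp",
    "predict",
    "make_folds",
    "run_cross_validation",
    "best_entries_per_split",
    "select_architecture",
    "train_logistic_baseline",
]


class TrainingError(RuntimeError):
    pass


@dataclass(frozen=True)
class ArchitectureSpec:
    """Hidden-layer widths and per-layer dropout; ReLU + sigmoid output."""

    id: str
    hidden_widths: tuple[int, ...]
    dropout_rates: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if len(self.hidden_widths) < 1:
            raise ValueError("need at least one hidden layer")
        if not self.dropout_rates:
            object.__setattr__(
                self, "dropout_rates", (0.0,) * len(self.hidden_widths)
            )
        if len(self.dropout_rates) != len(self.hidden_widths):
            raise ValueError("one dropout rate per hidden layer")
        if any(not 0.0 <= r < 1.0 for r in self.dropout_rates):
            raise ValueError("dropout rates must lie in [0, 1)")

    def n_params(self, n_inputs: int) -> int:
        sizes = (n_inputs, *self.hidden_widths, 1)
        return sum(a * b + b for a, b in zip(sizes, sizes[1:]))


#: Default grid: 8 specs (4 width layouts x dropout off/0.5), mirroring the
#: study protocol of 8 candidate architectures per full-text encoding.
DEFAULT_ARCHITECTURES: tuple[ArchitectureSpec, ...] = tuple(
    ArchitectureSpec(
        id=f"w{'x'.join(map(str, widths))}-d{rate}",
        hidden_widths=widths,
        dropout_rates=(rate,) * len(widths),
    )
    for widths in ((64,), (128,), (64, 32), (128, 64))
    for rate in (0.0, 0.5)
)


@dataclass
class TrainParams:
    epochs: int = 25  # study default for BOW/RB; embeddings used 50
    batch_size: int = 32
    learning_rate: float = 1e-3
    internal_val_fraction: float = 0.10
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.internal_val_fraction < 1.0:
            raise ValueError("internal_val_fraction must lie in (0, 1)")


class _MLP:
    """Plain feed-forward net; weights are lists of (W, b) arrays."""

    def __init__(self, arch: ArchitectureSpec, n_inputs: int,
                 rng: np.random.Generator):
        self.arch = arch
        self.n_inputs = n_inputs
        sizes = (n_inputs, *arch.hidden_widths, 1)
        self.W: list[np.ndarray] = []
        self.b: list[np.ndarray] = []
        for fan_in, fan_out in zip(sizes, sizes[1:]):
            limit = math.sqrt(6.0 / (fan_in + fan_out))  # Glorot uniform
            self.W.append(rng.uniform(-limit, limit, size=(fan_in, fan_out)))
            self.b.append(np.zeros(fan_out))

    def snapshot(self) -> list[np.ndarray]:
        return [a.copy() for a in (*self.W, *self.b)]

    def restore(self, snap: list[np.ndarray]) -> None:
        k = len(self.W)
        self.W = [a.copy() for a in snap[:k]]
        self.b = [a.copy() for a in snap[k:]]

    def _forward(
        self, X: np.ndarray, rng: np.random.Generator | None = None
    ) -> tuple[np.ndarray, list[np.ndarray], list[np.ndarray]]:
        """Returns (probabilities, pre-activations, activations); dropout is
        applied only when an rng is supplied (training mode)."""
        zs: list[np.ndarray] = []
        acts: list[np.ndarray] = [X]
        a = X
        for layer, (W, b) in enumerate(zip(self.W[:-1], self.b[:-1])):
            z = a @ W + b
            zs.append(z)
            a = np.maximum(z, 0.0)
            rate = self.arch.dropout_rates[layer]
            if rng is not None and rate > 0.0:
                mask = (rng.random(a.shape) >= rate) / (1.0 - rate)
                a = a * mask
            acts.append(a)
        z_out = a @ self.W[-1] + self.b[-1]
        zs.append(z_out)
        p = expit(z_out)
        return p.ravel(), zs, acts

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        if X.shape[1] != self.n_inputs:
            raise ValueError(
                f"feature width {X.shape[1]} != model input width {self.n_inputs}"
            )
        return self._forward(X)[0]

    def input_gradient(self, x: np.ndarray) -> np.ndarray:
        """Analytic gradient of the positive-class probability w.r.t. the
        input features, evaluated at ``x`` (one row)."""
        x = np.atleast_2d(np.asarray(x, dtype=float))
        if x.shape[1] != self.n_inputs:
            raise ValueError(
                f"feature width {x.shape[1]} != model input width {self.n_inputs}"
            )
        p, zs, _ = self._forward(x)
        g = (p * (1.0 - p)).reshape(-1, 1)  # d p / d z_out
        for layer in range(len(self.W) - 1, 0, -1):
            g = (g @ self.W[layer].T) * (zs[layer - 1] > 0)
        return (g @ self.W[0].T).ravel()

    def _backward(
        self, y: np.ndarray, p: np.ndarray,
        zs: list[np.ndarray], acts: list[np.ndarray],
    ) -> list[np.ndarray]:
        """Gradients of mean BCE loss in snapshot order (W..., b...)."""
        B = len(y)
        delta = ((p - y) / B).reshape(-1, 1)  # dL/dz_out for BCE + sigmoid
        gW: list[np.ndarray] = [None] * len(self.W)  # type: ignore[list-item]
        gb: list[np.ndarray] = [None] * len(self.b)  # type: ignore[list-item]
        for layer in range(len(self.W) - 1, -1, -1):
            gW[layer] = acts[layer].T @ delta
            gb[layer] = delta.sum(axis=0)
            if layer > 0:
                delta = (delta @ self.W[layer].T) * (zs[layer - 1] > 0)
        return [*gW, *gb]


def _bce(p: np.ndarray, y: np.ndarray) -> float:
    p = np.clip(p, 1e-12, 1.0 - 1e-12)
    return float(-np.mean(y * np.log(p) + (1 - y) * np.log(1 - p)))


def best_epoch_from_history(val_accuracy: Sequence[float]) -> int:
    """1-based epoch with the highest validation accuracy, earliest on ties."""
    arr = np.asarray(val_accuracy, dtype=float)
    if len(arr) == 0:
        raise ValueError("empty history")
    return int(np.argmax(arr)) + 1


@dataclass
class TrainedModel:
    net: _MLP
    best_epoch: int
    history: dict[str, list[float]]
    architecture_id: str
    seed: int
    val_indices: np.ndarray

    @property
    def best_val_accuracy(self) -> float:
        return self.history["val_accuracy"][self.best_epoch - 1]


def train_mlp(
    features: np.ndarray,
    labels: Sequence[int],
    arch: ArchitectureSpec,
    params: TrainParams,
) -> TrainedModel:
    """Train one MLP with internal-validation best-epoch weight selection."""
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels, dtype=float)
    if X.shape[0] != len(y):
        raise ValueError("features and labels must align")
    if len(np.unique(y)) < 2:
        raise TrainingError("training data contains a single class")
    rng = np.random.default_rng(params.seed)

    n = len(y)
    n_val = max(1, int(round(n * params.internal_val_fraction)))
    perm = rng.permutation(n)
    val_idx, fit_idx = perm[:n_val], perm[n_val:]
    if len(np.unique(y[fit_idx])) < 2:
        raise TrainingError("internal-validation split left a single class "
                            "in the training portion")
    Xf, yf, Xv, yv = X[fit_idx], y[fit_idx], X[val_idx], y[val_idx]

    net = _MLP(arch, X.shape[1], rng)
    # ADAM state
    m = [np.zeros_like(a) for a in net.snapshot()]
    v = [np.zeros_like(a) for a in net.snapshot()]
    t = 0
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    history: dict[str, list[float]] = {
        "train_loss": [], "train_accuracy": [],
        "val_loss": [], "val_accuracy": [],
    }
    best_acc = -np.inf
    best_snap = net.snapshot()
    best_epoch = 1

    for epoch in range(1, params.epochs + 1):
        order = rng.permutation(len(yf))
        for start in range(0, len(yf), params.batch_size):
            idx = order[start : start + params.batch_size]
            p, zs, acts = net._forward(Xf[idx], rng=rng)
            grads = net._backward(yf[idx], p, zs, acts)
            t += 1
            tensors = [*net.W, *net.b]
            for k, g in enumerate(grads):
                m[k] = beta1 * m[k] + (1 - beta1) * g
                v[k] = beta2 * v[k] + (1 - beta2) * g * g
                m_hat = m[k] / (1 - beta1**t)
                v_hat = v[k] / (1 - beta2**t)
                tensors[k] -= params.learning_rate * m_hat / (np.sqrt(v_hat) + eps)
        p_fit = net.predict_proba(Xf)
        p_val = net.predict_proba(Xv)
        train_loss = _bce(p_fit, yf)
        val_loss = _bce(p_val, yv)
        if not (np.isfinite(train_loss) and np.isfinite(val_loss)):
            raise TrainingError(
                f"non-finite loss at epoch {epoch} "
                f"(train={train_loss}, val={val_loss}, lr={params.learning_rate})"
            )
        val_acc = float(np.mean((p_val >= 0.5) == yv))
        history["train_loss"].append(train_loss)
        history["train_accuracy"].append(float(np.mean((p_fit >= 0.5) == yf)))
        history["val_loss"].append(val_loss)
        history["val_accuracy"].append(val_acc)
        if val_acc > best_acc:  # strict: earliest epoch wins ties
            best_acc = val_acc
            best_snap = net.snapshot()
            best_epoch = epoch

    net.restore(best_snap)
    assert best_epoch == best_epoch_from_history(history["val_accuracy"])
    return TrainedModel(
        net=net, best_epoch=best_epoch, history=history,
        architecture_id=arch.id, seed=params.seed, val_indices=val_idx,
    )


def predict(model: TrainedModel, features: np.ndarray) -> np.ndarray:
    """Positive-class probabilities, one per row; deterministic."""
    return model.net.predict_proba(np.asarray(features, dtype=float))


# ---------------------------------------------------------------------------
# Cross-validation protocol
# ---------------------------------------------------------------------------

@dataclass
class CVConfig:
    n_splits: int = 10
    n_repetitions: int = 10
    stratified: bool = True
    master_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_splits < 2:
            raise ValueError("need at least 2 folds")


@dataclass
class CVEntry:
    split: int
    repetition: int
    architecture_id: str
    model: TrainedModel
    test_indices: np.ndarray
    probabilities: np.ndarray
    metrics: MetricsReport


@dataclass
class CVResult:
    fold_of: np.ndarray  # test-fold index per patient
    entries: list[CVEntry]
    architecture_ids: list[str]
    n_features: int

    def metrics_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "split": e.split,
                "repetition": e.repetition,
                "architecture": e.architecture_id,
                "accuracy": e.metrics.accuracy,
                "auc": e.metrics.auc,
            }
            for e in self.entries
        )


def _repetition_seed(master_seed: int, split: int, repetition: int) -> int:
    # Deterministic, collision-free for protocol-sized grids; < 2**31.
    return (master_seed * 1_000_003 + split * 1009 + repetition) % (2**31 - 1)


def make_folds(labels: Sequence[int], cv: CVConfig) -> np.ndarray:
    """Assign each patient a test-fold index (disjoint, covering)."""
    y = np.asarray(labels)
    if len(y) < cv.n_splits:
        raise ValueError("cohort smaller than the number of folds")
    splitter = (
        StratifiedKFold(cv.n_splits, shuffle=True, random_state=cv.master_seed)
        if cv.stratified
        else KFold(cv.n_splits, shuffle=True, random_state=cv.master_seed)
    )
    fold_of = np.full(len(y), -1, dtype=int)
    for k, (_, test_idx) in enumerate(splitter.split(np.zeros((len(y), 1)), y)):
        fold_of[test_idx] = k
    return fold_of


def run_cross_validation(
    features: np.ndarray,
    labels: Sequence[int],
    archs: Sequence[ArchitectureSpec],
    cv: CVConfig,
    params: TrainParams,
) -> CVResult:
    """Train ``n_splits * n_repetitions * len(archs)`` models.

    The fold table is a function of ``cv.master_seed`` alone; repetition
    ``r`` of split ``s`` reseeds training (validation draw, initialisation,
    shuffling, dropout) with a value derived from ``(master_seed, s, r)``.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    fold_of = make_folds(y, cv)
    entries: list[CVEntry] = []
    for split in range(cv.n_splits):
        test_mask = fold_of == split
        train_idx = np.flatnonzero(~test_mask)
        test_idx = np.flatnonzero(test_mask)
        if len(np.unique(y[train_idx])) < 2 or len(np.unique(y[test_idx])) < 2:
            raise TrainingError(f"fold {split} contains a single class")
        for arch in archs:
            for rep in range(cv.n_repetitions):
                p = replace(params,
                            seed=_repetition_seed(cv.master_seed, split, rep))
                model = train_mlp(X[train_idx], y[train_idx], arch, p)
                probs = predict(model, X[test_idx])
                entries.append(
                    CVEntry(
                        split=split, repetition=rep,
                        architecture_id=arch.id, model=model,
                        test_indices=test_idx, probabilities=probs,
                        metrics=compute_metrics(probs, y[test_idx]),
                    )
                )
    return CVResult(
        fold_of=fold_of, entries=entries,
        architecture_ids=[a.id for a in archs], n_features=X.shape[1],
    )


def best_entries_per_split(
    cv_result: CVResult, architecture_id: str | None = None
) -> dict[str, dict[int, CVEntry]]:
    """Best repetition per (architecture, split) cell.

    "Best" means highest test accuracy, ties broken by higher AUC, then by
    lower repetition index — the protocol under which headline accuracies
    are reported (mean over splits of the best model in each split).
    """
    by_arch: dict[str, dict[int, CVEntry]] = {}
    for e in cv_result.entries:
        if architecture_id is not None and e.architecture_id != architecture_id:
            continue
        cell = by_arch.setdefault(e.architecture_id, {})
        cur = cell.get(e.split)
        if cur is None or (
            (e.metrics.accuracy, e.metrics.auc, -e.repetition)
            > (cur.metrics.accuracy, cur.metrics.auc, -cur.repetition)
        ):
            cell[e.split] = e
    return by_arch


def select_architecture(cv_result: CVResult) -> tuple[str, pd.DataFrame]:
    """Pick the architecture with the highest mean best-per-split accuracy.

    Within each (architecture, split) cell the best repetition is the one
    with the highest test accuracy (ties: higher AUC, then lower repetition
    index).  Architecture ties go to fewer parameters, then lexicographic id.
    """
    if not cv_result.entries:
        raise ValueError("empty cross-validation result")
    by_arch = best_entries_per_split(cv_result)
    n_params = {
        e.architecture_id: e.model.net.arch.n_params(cv_result.n_features)
        for e in cv_result.entries
    }
    rows = []
    for arch_id, cell in by_arch.items():
        best = list(cell.values())
        rows.append(
            {
                "architecture": arch_id,
                "mean_best_accuracy": float(np.mean([e.metrics.accuracy for e in best])),
                "mean_best_auc": float(np.mean([e.metrics.auc for e in best])),
                "n_params": n_params[arch_id],
            }
        )
    table = pd.DataFrame(rows).sort_values(
        ["mean_best_accuracy", "n_params", "architecture"],
        ascending=[False, True, True],
    ).reset_index(drop=True)
    winner = min(
        rows,
        key=lambda r: (-r["mean_best_accuracy"], r["n_params"], r["architecture"]),
    )
    return winner["architecture"], table


def train_logistic_baseline(
    features: np.ndarray,
    labels: Sequence[int],
    cv: CVConfig,
    mlp_result: CVResult | None = None,
) -> tuple[pd.DataFrame, list[LogisticRegression]]:
    """L2-regularised logistic regression on the same folds as the MLP runs.

    Folds are rebuilt from ``cv.master_seed`` with :func:`make_folds`, so
    they are identical to those used by :func:`run_cross_validation` under
    the same config.  When ``mlp_result`` is given, each row also carries
    the MLP's best-per-split accuracy and AUC for a side-by-side reading.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    fold_of = make_folds(y, cv)
    if mlp_result is not None and not np.array_equal(fold_of, mlp_result.fold_of):
        raise ValueError("cross-validation folds do not match the MLP run")
    best_mlp: dict[int, CVEntry] = {}
    if mlp_result is not None:
        for cell in best_entries_per_split(mlp_result).values():
            for split, e in cell.items():
                cur = best_mlp.get(split)
                if cur is None or (
                    (e.metrics.accuracy, e.metrics.auc, -e.repetition)
                    > (cur.metrics.accuracy, cur.metrics.auc, -cur.repetition)
                ):
                    best_mlp[split] = e
    rows = []
    models: list[LogisticRegression] = []
    for split in range(cv.n_splits):
        train_idx = np.flatnonzero(fold_of != split)
        test_idx = np.flatnonzero(fold_of == split)
        if len(np.unique(y[train_idx])) < 2:
            raise TrainingError(f"fold {split} contains a single class")
        clf = LogisticRegression(max_iter=1000)
        clf.fit(X[train_idx], y[train_idx])
        probs = clf.predict_proba(X[test_idx])[:, 1]
        metrics = compute_metrics(probs, y[test_idx])
        row = {"split": split,
               "logistic_accuracy": metrics.accuracy,
               "logistic_auc": metrics.auc}
        if split in best_mlp:
            row["mlp_accuracy"] = best_mlp[split].metrics.accuracy
            row["mlp_auc"] = best_mlp[split].metrics.auc
        rows.append(row)
        models.append(clf)
    return pd.DataFrame(rows), models
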