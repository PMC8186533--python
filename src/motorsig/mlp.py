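"""Feedforward classifier, training protocol and cross-validation.

Architecture: 17 inputs -> H tanh units -> 2 softmax outputs, Xavier-uniform
weight init, zero biases. Training: full-batch Adam (lr 0.01, beta1 0.9,
beta2 0.999, eps 1e-8) minimising categorical cross-entropy on integer
labels, 500 epochs. Evaluation: argmax prediction, confusion matrix,
sensitivity = recall of the ASD class, specificity = recall of the TD
class, ROC swept over the ASD-probability threshold, AUC by trapezoid.

Model selection follows the protocol of k-fold cross-validation (default
10-fold, 5 repetitions) and a descending grid search over hidden-layer
sizes that returns the smallest size within tolerance of the best.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import (
    DivergenceError,
    LabelError,
    LayerSizeError,
    SplitError,
)
from .features import (
    ALL_FEATURES,
    FeatureTable,
    ScalerParams,
    standardize,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ModelSpec:
    """Layer sizes of the feedforward network (activations are fixed)."""

    n_inputs: int = 17
    n_hidden: int = 5
    n_outputs: int = 2

    def __post_init__(self) -> None:
        for name in ("n_inputs", "n_hidden", "n_outputs"):
            v = getattr(self, name)
            if not isinstance(v, int) or v < 1:
                raise LayerSizeError(f"{name} must be a positive integer, got {v!r}")

    @property
    def n_params(self) -> int:
        return (self.n_inputs * self.n_hidden + self.n_hidden
                + self.n_hidden * self.n_outputs + self.n_outputs)


@dataclass(frozen=True)
class TrainConfig:
    """Optimisation hyperparameters (defaults follow the study protocol)."""

    learning_rate: float = 0.01
    epochs: int = 500
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-8
    batch_size: int | None = None  # None = full batch
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


@dataclass
class TrainedModel:
    """Network weights plus the scaler its inputs were standardized with."""

    spec: ModelSpec
    W1: np.ndarray
    b1: np.ndarray
    W2: np.ndarray
    b2: np.ndarray
    scaler: ScalerParams | None = None
    loss_trace: list[float] = field(default_factory=list)
    accuracy_trace: list[float] = field(default_factory=list)

    def hidden(self, X: np.ndarray) -> np.ndarray:
        return np.tanh(X @ self.W1 + self.b1)

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """Class-membership probabilities, columns ordered (ASD, TD)."""
        return _softmax(self.hidden(X) @ self.W2 + self.b2)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.argmax(self.predict_proba(X), axis=1)

    def copy(self) -> "TrainedModel":
        return TrainedModel(
            spec=self.spec,
            W1=self.W1.copy(), b1=self.b1.copy(),
            W2=self.W2.copy(), b2=self.b2.copy(),
            scaler=self.scaler,
            loss_trace=list(self.loss_trace),
            accuracy_trace=list(self.accuracy_trace),
        )

    def weights_dict(self) -> dict:
        return {
            "n_inputs": self.spec.n_inputs,
            "n_hidden": self.spec.n_hidden,
            "n_outputs": self.spec.n_outputs,
            "W1": self.W1.tolist(), "b1": self.b1.tolist(),
            "W2": self.W2.tolist(), "b2": self.b2.tolist(),
        }

    @classmethod
    def from_weights_dict(cls, d: dict,
                          scaler: ScalerParams | None = None) -> "TrainedModel":
        spec = ModelSpec(d["n_inputs"], d["n_hidden"], d["n_outputs"])
        return cls(
            spec=spec,
            W1=np.asarray(d["W1"], dtype=float),
            b1=np.asarray(d["b1"], dtype=float),
            W2=np.asarray(d["W2"], dtype=float),
            b2=np.asarray(d["b2"], dtype=float),
            scaler=scaler,
        )


def build_model(spec: ModelSpec, seed) -> TrainedModel:
    """Initialise a network: Xavier-uniform weights, zero biases."""
    rng = np.random.default_rng(seed)
    lim1 = np.sqrt(6.0 / (spec.n_inputs + spec.n_hidden))
    lim2 = np.sqrt(6.0 / (spec.n_hidden + spec.n_outputs))
    return TrainedModel(
        spec=spec,
        W1=rng.uniform(-lim1, lim1, (spec.n_inputs, spec.n_hidden)),
        b1=np.zeros(spec.n_hidden),
        W2=rng.uniform(-lim2, lim2, (spec.n_hidden, spec.n_outputs)),
        b2=np.zeros(spec.n_outputs),
    )


def train(
    model: TrainedModel,
    X: np.ndarray,
    y: np.ndarray,
    cfg: TrainConfig,
    eval_set: tuple[np.ndarray, np.ndarray] | None = None,
) -> TrainedModel:
    """Fit the network with Adam on cross-entropy; returns a new model.

    The per-epoch training loss is recorded in ``loss_trace``; when
    ``eval_set`` is given, per-epoch evaluation accuracy is recorded in
    ``accuracy_trace``. A non-finite loss raises :class:`DivergenceError`
    carrying the epoch index. Deterministic given ``cfg.seed``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if not np.isin(y, (0, 1)).all():
        raise LabelError("labels must be integers in {0, 1}")
    m = model.copy()
    n = len(X)
    rng = np.random.default_rng(cfg.seed)
    params = [m.W1, m.b1, m.W2, m.b2]
    mom = [np.zeros_like(p) for p in params]
    vel = [np.zeros_like(p) for p in params]
    t_step = 0
    onehot_full = np.eye(2)[y]
    m.loss_trace = []
    m.accuracy_trace = []

    for epoch in range(cfg.epochs):
        if cfg.batch_size is None:
            batches = [np.arange(n)]
        else:
            order = rng.permutation(n)
            batches = [order[i:i + cfg.batch_size]
                       for i in range(0, n, cfg.batch_size)]
        epoch_loss = 0.0
        for idx in batches:
            Xb, Yb = X[idx], onehot_full[idx]
            A1 = np.tanh(Xb @ m.W1 + m.b1)
            P = _softmax(A1 @ m.W2 + m.b2)
            nb = len(idx)
            loss = -np.mean(np.sum(Yb * np.log(np.clip(P, 1e-300, None)), axis=1))
            epoch_loss += loss * nb / n
            # backprop: softmax + cross-entropy
            dZ2 = (P - Yb) / nb
            dW2 = A1.T @ dZ2
            db2 = dZ2.sum(axis=0)
            dA1 = dZ2 @ m.W2.T
            dZ1 = dA1 * (1.0 - A1 * A1)
            dW1 = Xb.T @ dZ1
            db1 = dZ1.sum(axis=0)
            t_step += 1
            for p, g, mo, ve in zip(params, [dW1, db1, dW2, db2], mom, vel):
                mo *= cfg.beta1
                mo += (1.0 - cfg.beta1) * g
                ve *= cfg.beta2
                ve += (1.0 - cfg.beta2) * g * g
                mhat = mo / (1.0 - cfg.beta1 ** t_step)
                vhat = ve / (1.0 - cfg.beta2 ** t_step)
                p -= cfg.learning_rate * mhat / (np.sqrt(vhat) + cfg.eps)
        if not np.isfinite(epoch_loss):
            raise DivergenceError(f"non-finite loss at epoch {epoch}", epoch=epoch)
        m.loss_trace.append(float(epoch_loss))
        if eval_set is not None:
            Xe, ye = eval_set
            m.accuracy_trace.append(float(np.mean(m.predict(Xe) == ye)))
    return m


@dataclass(frozen=True)
class Metrics:
    """Binary classification metrics; ASD is the positive class."""

    confusion: np.ndarray  # rows true (ASD, TD), cols predicted (ASD, TD)
    accuracy: float
    sensitivity: float
    specificity: float
    roc_fpr: np.ndarray
    roc_tpr: np.ndarray
    auc: float

    def to_dict(self) -> dict:
        return {
            "confusion": self.confusion.tolist(),
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "auc": self.auc,
        }


def _roc(p_pos: np.ndarray, is_pos: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """ROC over the positive-class probability threshold; AUC by trapezoid."""
    order = np.argsort(-p_pos, kind="stable")
    is_pos = is_pos[order].astype(float)
    n_pos = is_pos.sum()
    n_neg = len(is_pos) - n_pos
    tp = np.cumsum(is_pos)
    fp = np.cumsum(1.0 - is_pos)
    # collapse ties: keep the last point of each distinct threshold
    distinct = np.r_[np.diff(p_pos[order]) != 0, True]
    tpr = np.r_[0.0, tp[distinct] / max(n_pos, 1)]
    fpr = np.r_[0.0, fp[distinct] / max(n_neg, 1)]
    auc = float(np.trapezoid(tpr, fpr))
    return fpr, tpr, auc


def evaluate(model: TrainedModel, X: np.ndarray, y: np.ndarray) -> Metrics:
    """Confusion matrix, accuracy, sensitivity/specificity, ROC and AUC."""
    y = np.asarray(y, dtype=int)
    if not np.isin(y, (0, 1)).all():
        raise LabelError("labels must be integers in {0, 1} (ASD=0, TD=1)")
    proba = model.predict_proba(X)
    pred = np.argmax(proba, axis=1)
    cm = np.zeros((2, 2), dtype=int)
    for true_c in (0, 1):
        for pred_c in (0, 1):
            cm[true_c, pred_c] = int(np.sum((y == true_c) & (pred == pred_c)))
    acc = float((pred == y).mean())
    n_asd, n_td = cm[0].sum(), cm[1].sum()
    sens = float(cm[0, 0] / n_asd) if n_asd else float("nan")
    spec = float(cm[1, 1] / n_td) if n_td else float("nan")
    fpr, tpr, auc = _roc(proba[:, 0], y == 0)
    return Metrics(confusion=cm, accuracy=acc, sensitivity=sens,
                   specificity=spec, roc_fpr=fpr, roc_tpr=tpr, auc=auc)


def metrics_from_confusion(cm: np.ndarray) -> tuple[float, float, float]:
    """(accuracy, sensitivity, specificity) from a 2x2 confusion matrix."""
    cm = np.asarray(cm, dtype=float)
    acc = (cm[0, 0] + cm[1, 1]) / cm.sum()
    return float(acc), float(cm[0, 0] / cm[0].sum()), float(cm[1, 1] / cm[1].sum())


@dataclass(frozen=True)
class FoldResult:
    repetition: int
    fold: int
    metrics: Metrics
    test_idx: np.ndarray


@dataclass
class CVResult:
    """Bookkeeping of a k-fold x repetitions cross-validation run."""

    k: int
    repetitions: int
    folds: list[FoldResult]
    mean_accuracy: float        # mean of per-repetition average accuracies
    sd_accuracy_reps: float     # SD across the per-repetition averages
    sd_accuracy_folds: float    # SD across all k*repetitions fold accuracies
    best_model: TrainedModel
    best_fold: tuple[int, int]  # (repetition, fold) of the best model
    best_test_idx: np.ndarray
    epoch_accuracy_trace: np.ndarray  # mean test accuracy per epoch

    def to_dict(self) -> dict:
        return {
            "k": self.k,
            "repetitions": self.repetitions,
            "mean_accuracy": self.mean_accuracy,
            "sd_accuracy_reps": self.sd_accuracy_reps,
            "sd_accuracy_folds": self.sd_accuracy_folds,
            "best_fold": list(self.best_fold),
            "best_metrics": self.best_metrics.to_dict(),
            "fold_accuracies": [f.metrics.accuracy for f in self.folds],
        }

    @property
    def best_metrics(self) -> Metrics:
        rep, fold = self.best_fold
        for f in self.folds:
            if (f.repetition, f.fold) == (rep, fold):
                return f.metrics
        raise LookupError("best fold not found")


def _fold_indices(
    table: FeatureTable, k: int, split_mode: str, rng: np.random.Generator
) -> list[np.ndarray]:
    """Partition sample indices into k near-equal folds."""
    n = len(table)
    if split_mode == "sample":
        return np.array_split(rng.permutation(n), k)
    if split_mode == "subject":
        subjects = np.array(sorted(set(table.subject_ids)))
        if len(subjects) < k:
            raise SplitError(f"k={k} folds but only {len(subjects)} subjects")
        groups = np.array_split(rng.permutation(len(subjects)), k)
        sid = table.subject_ids
        return [np.flatnonzero(np.isin(sid, subjects[g])) for g in groups]
    raise SplitError(f"unknown split_mode {split_mode!r}")


def cross_validate(
    table: FeatureTable,
    k: int = 10,
    repetitions: int = 5,
    split_mode: str = "sample",
    seed: int = 0,
    model_spec: ModelSpec | None = None,
    train_cfg: TrainConfig | None = None,
    standardize_mode: str = "whole",
) -> CVResult:
    """Repeated k-fold cross-validation of the feedforward classifier.

    ``standardize_mode="whole"`` z-scores the kinematic columns on the full
    dataset before splitting (the study's stated order, which leaks fold
    statistics); ``"per-fold"`` fits the scaler on each training fold only.
    ``split_mode="sample"`` randomises over rows, so one subject's tasks may
    span folds (again matching the protocol); ``"subject"`` keeps each
    subject's rows in a single fold. Best model = highest test-fold
    accuracy, ties broken by lower (repetition, fold) index.
    """
    if model_spec is None:
        model_spec = ModelSpec()
    if train_cfg is None:
        train_cfg = TrainConfig(seed=seed)
    n = len(table)
    if k > n:
        raise SplitError(f"k={k} exceeds number of samples n={n}")
    if standardize_mode not in ("whole", "per-fold"):
        raise SplitError(f"unknown standardize_mode {standardize_mode!r}")

    if standardize_mode == "whole":
        table_std, global_scaler = standardize(table, "fit")
    ss = np.random.SeedSequence(seed)
    rep_seeds = ss.spawn(repetitions)
    folds: list[FoldResult] = []
    rep_accs: list[float] = []
    best: tuple[float, float, tuple[int, int]] | None = None
    best_model: TrainedModel | None = None
    best_test: np.ndarray | None = None
    traces: list[np.ndarray] = []

    for rep in range(repetitions):
        rep_rng = np.random.default_rng(rep_seeds[rep])
        fold_idx = _fold_indices(table, k, split_mode, rep_rng)
        fold_accs = []
        for j, test_idx in enumerate(fold_idx):
            test_idx = np.sort(test_idx)
            train_mask = np.ones(n, dtype=bool)
            train_mask[test_idx] = False
            train_idx = np.flatnonzero(train_mask)
            if standardize_mode == "whole":
                scaler = global_scaler
                Xtr, ytr = table_std.X[train_idx], table_std.y[train_idx]
                Xte, yte = table_std.X[test_idx], table_std.y[test_idx]
            else:
                tr_std, scaler = standardize(table.subset(train_idx), "fit")
                te_std, _ = standardize(table.subset(test_idx), scaler)
                Xtr, ytr = tr_std.X, tr_std.y
                Xte, yte = te_std.X, te_std.y
            fold_seed_root = np.random.SeedSequence([seed, rep, j])
            model = build_model(model_spec, fold_seed_root)
            cfg = replace(train_cfg, seed=int(fold_seed_root.generate_state(1)[0]))
            model = train(model, Xtr, ytr, cfg, eval_set=(Xte, yte))
            model.scaler = scaler
            metrics = evaluate(model, Xte, yte)
            folds.append(FoldResult(rep, j, metrics, test_idx))
            fold_accs.append(metrics.accuracy)
            traces.append(np.asarray(model.accuracy_trace))
            key = (metrics.accuracy, metrics.sensitivity, (-rep, -j))
            if best is None or key > best:
                best = key
                best_model = model
                best_test = test_idx
        rep_accs.append(float(np.mean(fold_accs)))

    all_accs = np.array([f.metrics.accuracy for f in folds])
    assert best_model is not None and best is not None and best_test is not None
    return CVResult(
        k=k,
        repetitions=repetitions,
        folds=folds,
        mean_accuracy=float(np.mean(rep_accs)),
        sd_accuracy_reps=float(np.std(rep_accs, ddof=1)) if repetitions > 1 else 0.0,
        sd_accuracy_folds=float(np.std(all_accs, ddof=1)) if len(all_accs) > 1 else 0.0,
        best_model=best_model,
        best_fold=(-best[2][0], -best[2][1]),
        best_test_idx=best_test,
        epoch_accuracy_trace=np.mean(np.vstack(traces), axis=0),
    )


def grid_search_hidden(
    table: FeatureTable,
    candidates: list[int],
    k: int = 10,
    repetitions: int = 1,
    seed: int = 0,
    train_cfg: TrainConfig | None = None,
    tolerance: float = 0.01,
    **cv_kwargs,
) -> tuple[int, dict[int, float]]:
    """Descending search over hidden sizes; parsimony within ``tolerance``.

    Returns the smallest candidate whose mean CV accuracy is within
    ``tolerance`` (default one percentage point) of the best, plus the full
    per-candidate accuracy table.
    """
    if not candidates:
        raise ValueError("candidates must be non-empty")
    if list(candidates) != sorted(candidates, reverse=True):
        raise ValueError("candidates must be in descending order")
    accs: dict[int, float] = {}
    for h in candidates:
        res = cross_validate(
            table, k=k, repetitions=repetitions, seed=seed,
            model_spec=ModelSpec(n_inputs=len(ALL_FEATURES), n_hidden=h),
            train_cfg=train_cfg, **cv_kwargs,
        )
        accs[h] = res.mean_accuracy
        logger.info("grid search: H=%d -> mean CV accuracy %.4f", h, accs[h])
    best_acc = max(accs.values())
    eligible = [h for h, a in accs.items() if a >= best_acc - tolerance]
    return min(eligible), accs
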