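"""Optimisation and evaluation machinery.

Training minimises the margin loss with Adam, holding out a stratified
validation split of the training data; after every epoch the validation
loss is measured and the parameters with the lowest validation loss seen so
far are the ones returned (early stopping with patience).  Model assessment
uses stratified k-fold cross-validation (default 5-fold, i.e. 20% held out
per fold) and reports the area under the ROC curve.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.model_selection import StratifiedKFold, train_test_split

from .capsnet import CapsNetConfig, CapsuleNetwork
from .autodiff import Tensor

__all__ = ["TrainConfig", "TrainResult", "CVResult", "Adam", "train", "cross_validate", "roc_auc"]


@dataclass(frozen=True)
class TrainConfig:
    """Optimisation settings (Adam with standard moment decay)."""

    learning_rate: float = 0.001
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-8
    batch_size: int = 64
    large_batch_size: int = 512
    large_dataset_threshold: int = 100_000  # instances at which batch 512 kicks in
    max_epochs: int = 30
    patience: int = 5
    val_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self):
        if self.batch_size < 1 or self.max_epochs < 1:
            raise ValueError("batch_size and max_epochs must be >= 1")

    def effective_batch_size(self, n_instances: int) -> int:
        return self.large_batch_size if n_instances >= self.large_dataset_threshold else self.batch_size


@dataclass
class TrainResult:
    """Loss trajectory plus which epoch's weights were kept."""

    train_loss: list[float]
    val_loss: list[float]
    best_epoch: int
    best_val_loss: float

    @property
    def n_epochs(self) -> int:
        return len(self.train_loss)


@dataclass
class CVResult:
    """Per-fold models, scores and ROC summaries of a k-fold run."""

    fold_aucs: list[float]
    roc_curves: list[tuple[np.ndarray, np.ndarray]]  # (fpr, tpr) per fold
    fold_assignments: np.ndarray  # fold index of each instance
    scores: np.ndarray  # out-of-fold score of each instance
    labels: np.ndarray
    models: list[CapsuleNetwork]
    train_results: list[TrainResult]

    @property
    def mean_auc(self) -> float:
        return float(np.mean(self.fold_aucs))

    @property
    def median_auc(self) -> float:
        return float(np.median(self.fold_aucs))

    def summary_frame(self) -> pd.DataFrame:
        rows = [{"fold": i, "auc": a, "epochs": tr.n_epochs, "best_epoch": tr.best_epoch}
                for i, (a, tr) in enumerate(zip(self.fold_aucs, self.train_results))]
        return pd.DataFrame(rows)


class Adam:
    """Adam on a dict of autodiff Tensors (bias-corrected first/second moments)."""

    def __init__(self, params: dict[str, Tensor], cfg: TrainConfig):
        self.params = params
        self.cfg = cfg
        self.t = 0
        self.m = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.v = {k: np.zeros_like(p.data) for k, p in params.items()}

    def step(self) -> None:
        c = self.cfg
        self.t += 1
        for k, p in self.params.items():
            if p.grad is None:
                continue
            g = p.grad
            self.m[k] = c.beta1 * self.m[k] + (1 - c.beta1) * g
            self.v[k] = c.beta2 * self.v[k] + (1 - c.beta2) * g * g
            m_hat = self.m[k] / (1 - c.beta1**self.t)
            v_hat = self.v[k] / (1 - c.beta2**self.t)
            p.data = p.data - c.learning_rate * m_hat / (np.sqrt(v_hat) + c.eps)

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.grad = None


def _epoch_loss(net: CapsuleNetwork, X: np.ndarray, y: np.ndarray, batch: int) -> float:
    total, n = 0.0, 0
    for lo in range(0, len(y), batch):
        xb, yb = X[lo : lo + batch], y[lo : lo + batch]
        loss = net.loss_tensor(net.forward_tensor(xb), yb)
        total += float(loss.data) * len(yb)
        n += len(yb)
    return total / n


def train(
    X: np.ndarray,
    y: np.ndarray,
    net: CapsuleNetwork,
    cfg: TrainConfig = TrainConfig(),
) -> TrainResult:
    """Fit ``net`` in place and return the loss history.

    A stratified ``val_fraction`` of (X, y) is held out for early stopping;
    the weights restored at the end are those of the epoch with minimal
    validation loss.  Raises ``RuntimeError`` if the loss diverges to NaN.
    Fully deterministic for a fixed config seed.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.int64)
    idx_tr, idx_val = train_test_split(
        np.arange(len(y)), test_size=cfg.val_fraction, stratify=y, random_state=cfg.seed
    )
    Xtr, ytr, Xval, yval = X[idx_tr], y[idx_tr], X[idx_val], y[idx_val]
    batch = cfg.effective_batch_size(len(y))
    rng = np.random.default_rng(cfg.seed)
    opt = Adam(net.params, cfg)

    best_val = np.inf
    best_state = net.state_arrays()
    best_epoch = -1
    train_hist: list[float] = []
    val_hist: list[float] = []
    since_best = 0
    for epoch in range(cfg.max_epochs):
        order = rng.permutation(len(ytr))
        running, seen = 0.0, 0
        for lo in range(0, len(order), batch):
            sel = order[lo : lo + batch]
            opt.zero_grad()
            scores = net.forward_tensor(Xtr[sel])
            loss = net.loss_tensor(scores, ytr[sel])
            if not (np.isfinite(scores.data).all() and np.isfinite(loss.data)):
                raise RuntimeError(
                    f"training diverged: loss={float(loss.data)} at epoch {epoch}, batch {lo // batch}"
                )
            loss.backward()
            opt.step()
            running += float(loss.data) * len(sel)
            seen += len(sel)
        train_hist.append(running / seen)
        vloss = _epoch_loss(net, Xval, yval, batch)
        val_hist.append(vloss)
        if vloss < best_val:
            best_val = vloss
            best_state = net.state_arrays()
            best_epoch = epoch
            since_best = 0
        else:
            since_best += 1
            if since_best >= cfg.patience:
                break
    net.load_state_arrays(best_state)
    return TrainResult(train_hist, val_hist, best_epoch, float(best_val))


def cross_validate(
    X: np.ndarray,
    y: np.ndarray,
    model_config: CapsNetConfig,
    train_config: TrainConfig = TrainConfig(),
    k: int = 5,
) -> CVResult:
    """Stratified k-fold cross-validation of the capsule network.

    Each fold trains a fresh network on the other k-1 folds (with its own
    internal validation split for early stopping) and scores the held-out
    fold; AUC is reported per fold and in aggregate.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.int64)
    if k < 2:
        raise ValueError("k must be >= 2")
    n_pos, n_neg = int((y == 1).sum()), int((y == 0).sum())
    if n_pos < k or n_neg < k:
        raise ValueError(f"need at least k={k} instances of each class (have {n_pos}+/{n_neg}-)")

    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=train_config.seed)
    assignments = np.full(len(y), -1, dtype=np.int64)
    oof_scores = np.full(len(y), np.nan)
    aucs: list[float] = []
    curves: list[tuple[np.ndarray, np.ndarray]] = []
    models: list[CapsuleNetwork] = []
    results: list[TrainResult] = []
    for fold, (tr, te) in enumerate(skf.split(X, y)):
        assignments[te] = fold
        net = CapsuleNetwork(model_config, seed=train_config.seed + 1000 * (fold + 1))
        tr_res = train(X[tr], y[tr], net, replace(train_config, seed=train_config.seed + fold))
        scores = net.predict_scores(X[te])
        oof_scores[te] = scores
        auc, (fpr, tpr) = roc_auc(scores, y[te])
        aucs.append(auc)
        curves.append((fpr, tpr))
        models.append(net)
        results.append(tr_res)
    return CVResult(aucs, curves, assignments, oof_scores, y.copy(), models, results)


def roc_auc(scores, labels) -> tuple[float, tuple[np.ndarray, np.ndarray]]:
    """AUC (rank statistic, ties contribute 1/2) plus the ROC curve points."""
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels, dtype=np.int64)
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes must be present to compute AUC")
    auc = float(roc_auc_score(labels, scores))
    fpr, tpr, _ = roc_curve(labels, scores)
    return auc, (fpr, tpr)
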