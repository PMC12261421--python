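"""Homology-aware cross-validation and the training protocol.

Training follows a fixed schedule: Adam at an initial learning rate of 0.001,
batch size 8, up to 100 epochs, a reduce-on-plateau schedule (×0.5 after 10
epochs without validation improvement, 5-epoch cooldown) and early stopping
with patience 15, restoring the best-validation weights.  Cross-validation
folds respect homology: proteins whose pairwise sequence identity exceeds a
threshold (default 25%) are clustered by connected components and a cluster
is never split between train and validation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .featurize import (
    Representation,
    VoxelGrid,
    build_representation,
    reverse_representation,
)
from .network import Model
from .nnops import Adam, bce_with_logits_loss, mse_loss
from .structures import MutationRecord

__all__ = [
    "FoldSplit",
    "TrainConfig",
    "TrainingDataset",
    "ReduceLROnPlateau",
    "EarlyStopping",
    "homology_clusters",
    "make_folds",
    "assemble_dataset",
    "train_fold",
    "train_ensemble",
]


@dataclass(frozen=True)
class FoldSplit:
    """k disjoint (train, validation) index partitions."""

    folds: tuple[tuple[np.ndarray, np.ndarray], ...]
    k: int

    def __post_init__(self) -> None:
        if len(self.folds) != self.k:
            raise ValueError("fold count does not match k")


@dataclass(frozen=True)
class TrainConfig:
    """Hyperparameters of the published training protocol."""

    epochs: int = 100
    batch_size: int = 8
    lr: float = 1e-3
    scheduler_factor: float = 0.5
    scheduler_patience: int = 10
    scheduler_cooldown: int = 5
    early_stop_patience: int = 15
    seed: int = 0
    loss: str = "mse"
    min_lr: float = 1e-6

    def __post_init__(self) -> None:
        if self.loss not in ("mse", "bce"):
            raise ValueError("loss must be 'mse' or 'bce'")
        if not (0.0 < self.scheduler_factor < 1.0):
            raise ValueError("scheduler factor must lie in (0, 1)")
        for name in ("epochs", "batch_size", "early_stop_patience"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.lr <= 0:
            raise ValueError("lr must be positive")


class ReduceLROnPlateau:
    """Halving-style plateau scheduler; improvement = any decrease."""

    def __init__(
        self,
        lr: float,
        factor: float = 0.5,
        patience: int = 10,
        cooldown: int = 5,
        min_lr: float = 1e-6,
    ) -> None:
        self.lr = lr
        self.factor = factor
        self.patience = patience
        self.cooldown = cooldown
        self.min_lr = min_lr
        self.best = np.inf
        self.num_bad = 0
        self.cooldown_left = 0

    def step(self, val_loss: float) -> float:
        if val_loss < self.best:
            self.best = val_loss
            self.num_bad = 0
        elif self.cooldown_left > 0:
            self.cooldown_left -= 1
        else:
            self.num_bad += 1
            if self.num_bad > self.patience - 1 and self.lr > self.min_lr:
                self.lr = max(self.lr * self.factor, self.min_lr)
                self.num_bad = 0
                self.cooldown_left = self.cooldown
        return self.lr


class EarlyStopping:
    """Stop after `patience` epochs without validation improvement."""

    def __init__(self, patience: int = 15) -> None:
        self.patience = patience
        self.best = np.inf
        self.num_bad = 0

    def step(self, val_loss: float) -> bool:
        if val_loss < self.best:
            self.best = val_loss
            self.num_bad = 0
            return False
        self.num_bad += 1
        return self.num_bad >= self.patience


def homology_clusters(identity, threshold: float = 25.0) -> list[list]:
    """Connected components of the graph with edges where identity > threshold.

    `identity` is a square symmetric matrix of pairwise percent identities
    (DataFrame with ids, or plain array — then clusters contain indices).
    """
    if isinstance(identity, pd.DataFrame):
        ids = list(identity.index)
        if list(identity.columns) != ids:
            raise ValueError("identity matrix index and columns must match")
        mat = identity.to_numpy(dtype=float)
    else:
        mat = np.asarray(identity, dtype=float)
        ids = list(range(mat.shape[0]))
    if mat.ndim != 2 or mat.shape[0] != mat.shape[1]:
        raise ValueError("identity matrix must be square")
    if not np.allclose(mat, mat.T, atol=1e-8):
        raise ValueError("identity matrix must be symmetric")
    adj = mat > threshold
    np.fill_diagonal(adj, False)
    n_comp, labels = connected_components(csr_matrix(adj), directed=False)
    clusters: list[list] = [[] for _ in range(n_comp)]
    for idx, lab in enumerate(labels):
        clusters[lab].append(ids[idx])
    return clusters


def make_folds(
    clusters: list[list],
    k: int = 5,
    seed: int = 0,
    record_groups: list | None = None,
) -> FoldSplit:
    """Assign whole clusters to k folds (seeded, round-robin after shuffle).

    `record_groups` gives each record's protein id; a record's fold is its
    protein's cluster's fold, so neither a cluster nor a protein ever spans
    train and validation of the same fold.  Without `record_groups` the
    records are the proteins themselves.
    """
    if len(clusters) < k:
        raise ValueError(f"need at least k={k} clusters, got {len(clusters)}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(clusters))
    fold_of_protein: dict = {}
    for slot, cluster_idx in enumerate(order):
        for protein in clusters[cluster_idx]:
            fold_of_protein[protein] = slot % k
    if record_groups is None:
        record_groups = [p for cluster in clusters for p in cluster]
    fold_of_record = np.array([fold_of_protein[g] for g in record_groups])
    folds = []
    all_idx = np.arange(len(record_groups))
    for f in range(k):
        val = all_idx[fold_of_record == f]
        train = all_idx[fold_of_record != f]
        folds.append((train, val))
    return FoldSplit(folds=tuple(folds), k=k)


@dataclass
class TrainingDataset:
    """Stacked representations with labels and grouping metadata."""

    X: np.ndarray  # (N, 16, 16, 16, C) channel-last
    y: np.ndarray  # (N,) ΔΔG labels, kcal/mol
    groups: list[str]  # protein id per item (reverse items share the pair's)
    pair_ids: np.ndarray  # direct/reverse pairs share an id
    is_reverse: np.ndarray
    failures: list[tuple[MutationRecord, str]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.y)


def assemble_dataset(
    records: list[MutationRecord],
    grid_pairs: list[tuple[VoxelGrid, VoxelGrid] | None],
    mode: str = "wt_diff",
    augment_reverse: bool = True,
) -> TrainingDataset:
    """Stack per-record WT/MT grids into a training set.

    With reverse augmentation each record contributes a second item with the
    grid roles swapped and the label negated; the pair shares a pair id and a
    protein group, so fold splitting keeps direct and reverse together.
    Records with a missing grid pair are skipped and listed in `failures`.
    """
    tensors: list[np.ndarray] = []
    labels: list[float] = []
    groups: list[str] = []
    pair_ids: list[int] = []
    reverse_flags: list[bool] = []
    failures: list[tuple[MutationRecord, str]] = []
    for pair_id, (record, pair) in enumerate(zip(records, grid_pairs)):
        if pair is None:
            failures.append((record, "missing representation"))
            continue
        wt, mt = pair
        rep = build_representation(wt, mt, mode)
        tensors.append(rep.tensor)
        labels.append(record.ddg)
        groups.append(record.structure_id)
        pair_ids.append(pair_id)
        reverse_flags.append(record.is_reverse)
        if augment_reverse:
            rev_rep, rev_ddg = reverse_representation(wt, mt, record.ddg, mode)
            tensors.append(rev_rep.tensor)
            labels.append(rev_ddg)
            groups.append(record.structure_id)
            pair_ids.append(pair_id)
            reverse_flags.append(not record.is_reverse)
    if not tensors:
        raise ValueError("no usable records")
    return TrainingDataset(
        X=np.stack(tensors).astype(np.float32),
        y=np.array(labels, dtype=float),
        groups=groups,
        pair_ids=np.array(pair_ids),
        is_reverse=np.array(reverse_flags, dtype=bool),
        failures=failures,
    )


def _epoch_loss(model: Model, X: np.ndarray, y: np.ndarray, loss: str) -> float:
    total = 0.0
    for start in range(0, len(y), 32):
        xb = X[start : start + 32].astype(float).transpose(0, 4, 1, 2, 3)
        out = model.net.forward(xb).reshape(-1)
        fn = mse_loss if loss == "mse" else bce_with_logits_loss
        lb, _ = fn(out, y[start : start + 32])
        total += lb * len(out)
    return total / len(y)


def train_fold(
    model: Model,
    dataset: TrainingDataset,
    fold: tuple[np.ndarray, np.ndarray],
    config: TrainConfig,
) -> tuple[Model, dict]:
    """Train one model on one fold with the full schedule.

    Returns the model with its best-validation weights restored and a history
    dict with per-epoch train loss, validation loss, and learning rate.
    """
    train_idx, val_idx = np.asarray(fold[0]), np.asarray(fold[1])
    if len(train_idx) == 0:
        raise ValueError("empty training fold")
    y = dataset.y.copy()
    if config.loss == "bce":
        # classification: stabilizing (ΔΔG < 0) is class 1; ties excluded
        keep_train = y[train_idx] != 0
        keep_val = y[val_idx] != 0
        train_idx = train_idx[keep_train]
        val_idx = val_idx[keep_val]
        y = (y < 0).astype(float)
        if len(train_idx) == 0:
            raise ValueError("empty training fold after removing ΔΔG = 0 records")

    rng = np.random.default_rng(config.seed)
    scheduler = ReduceLROnPlateau(
        lr=config.lr,
        factor=config.scheduler_factor,
        patience=config.scheduler_patience,
        cooldown=config.scheduler_cooldown,
        min_lr=config.min_lr,
    )
    stopper = EarlyStopping(patience=config.early_stop_patience)
    optimizer = Adam(model.net.parameters(), lr=config.lr)
    loss_fn = mse_loss if config.loss == "mse" else bce_with_logits_loss

    history: dict = {"train_loss": [], "val_loss": [], "lr": []}
    best_val = np.inf
    best_state = model.net.get_state()
    for _epoch in range(config.epochs):
        order = rng.permutation(len(train_idx))
        epoch_loss = 0.0
        for start in range(0, len(order), config.batch_size):
            batch = train_idx[order[start : start + config.batch_size]]
            xb = dataset.X[batch].astype(float).transpose(0, 4, 1, 2, 3)
            out = model.net.forward(xb).reshape(-1)
            loss, grad = loss_fn(out, y[batch])
            model.net.backward(grad.reshape(-1, 1))
            optimizer.lr = scheduler.lr
            optimizer.step(model.net.gradients())
            epoch_loss += loss * len(batch)
        train_loss = epoch_loss / len(train_idx)
        val_loss = (
            _epoch_loss(model, dataset.X[val_idx], y[val_idx], config.loss)
            if len(val_idx)
            else train_loss
        )
        history["train_loss"].append(train_loss)
        history["val_loss"].append(val_loss)
        history["lr"].append(scheduler.lr)
        if val_loss < best_val:
            best_val = val_loss
            best_state = model.net.get_state()
        stop = stopper.step(val_loss)
        scheduler.step(val_loss)
        if stop:
            break
    model.net.set_state(best_state)
    history["best_val_loss"] = float(best_val)
    return model, history


def train_ensemble(
    dataset: TrainingDataset,
    splits: FoldSplit,
    config: TrainConfig,
    model_builder,
) -> tuple[list[Model], list[dict]]:
    """One model per fold; best validation weights saved for the ensemble.

    `model_builder(seed)` must return a fresh Model; fold f gets seed
    config.seed + f so members differ in initialization.
    """
    models: list[Model] = []
    manifest: list[dict] = []
    for f, fold in enumerate(splits.folds):
        model = model_builder(config.seed + f)
        model, history = train_fold(model, dataset, fold, config)
        models.append(model)
        manifest.append(
            {
                "fold": f,
                "best_val_loss": history["best_val_loss"],
                "epochs_run": len(history["val_loss"]),
            }
        )
    return models, manifest
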