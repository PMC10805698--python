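"""MIL-specific training machinery.

Covers the pieces that differ from ordinary supervised training:

* instance (data) dropout — every gradient update sees a fresh random
  subset of each bag's instances, while evaluation always uses all of
  them; this both regularizes and caps per-batch memory;
* inverse-frequency class weighting (mean sample weight 1);
* stratified K-fold plans and stratified minibatches, so every batch has
  proportional class representation;
* the loop itself: class-weighted cross-entropy plus the model's
  attention-L1 and L2 penalties, Adam, early stopping on validation
  weighted cross-entropy, per-epoch history.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

logger = logging.getLogger(__name__)

__all__ = [
    "instance_dropout_indices",
    "instance_dropout",
    "class_weights",
    "FoldPlan",
    "stratified_kfold",
    "stratified_split",
    "stratified_batches",
    "train",
]


# ---------------------------------------------------------------------------
# instance dropout


def instance_dropout_indices(n: int, rate: float, rng) -> np.ndarray:
    """Local indices of instances kept for one gradient update.

    Keeps a uniform random subset of ``ceil((1 - rate) * n)`` instances,
    never fewer than one. ``rate=0`` is the identity (all instances, in
    order).
    """
    if not 0.0 <= rate < 1.0:
        raise ValueError("dropout rate must be in [0, 1)")
    if rate == 0.0:
        return np.arange(n)
    keep = max(1, int(np.ceil((1.0 - rate) * n)))
    return np.sort(rng.choice(n, size=keep, replace=False))


def instance_dropout(bag, rate: float, rng, training: bool = True):
    """Bag-level view of instance dropout; evaluation mode is the identity."""
    if not training or rate == 0.0:
        return bag
    from .mil import Bag  # local import to keep module layering acyclic

    keep = instance_dropout_indices(bag.n_instances, rate, rng)
    return Bag(
        sample_id=bag.sample_id,
        instances={k: v[keep] for k, v in bag.instances.items()},
        label=bag.label,
        sample_features=bag.sample_features,
        key_flags=None if bag.key_flags is None else bag.key_flags[keep],
    )


# ---------------------------------------------------------------------------
# class weighting


def class_weights(labels: np.ndarray, n_classes: Optional[int] = None) -> np.ndarray:
    """Per-class weights proportional to inverse frequency, mean sample weight 1.

    ``w_c = n / (C * n_c)``; with counts (90, 10) this gives (0.556, 5.0).
    Raises on fewer than two observed classes or an empty class.
    """
    labels = np.asarray(labels, dtype=np.int64)
    if n_classes is None:
        n_classes = int(labels.max()) + 1 if len(labels) else 0
    counts = np.bincount(labels, minlength=n_classes)
    if (counts == 0).any() or n_classes < 2:
        raise ValueError("class weighting requires >= 1 sample in >= 2 classes")
    return len(labels) / (n_classes * counts)


# ---------------------------------------------------------------------------
# fold plans


@dataclass
class FoldPlan:
    """Sample -> fold assignment, stratified by label."""

    k: int
    assignments: dict
    stratify_by: str = "label"

    def fold_of(self, sample_id) -> int:
        return self.assignments[sample_id]

    def split(self, sample_ids) -> list[tuple[np.ndarray, np.ndarray]]:
        folds = np.array([self.assignments[s] for s in sample_ids])
        out = []
        for f in range(self.k):
            out.append((np.flatnonzero(folds != f), np.flatnonzero(folds == f)))
        return out


def stratified_kfold(sample_ids, labels, k: int, seed: int = 0) -> FoldPlan:
    """Stratified K folds, deterministic given the seed.

    Classes with fewer than k members are spread best-effort (with a
    warning), matching scikit-learn's behaviour.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    sample_ids = list(sample_ids)
    labels = np.asarray(labels)
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    assignments = {}
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        for fold, (_, test_idx) in enumerate(skf.split(np.zeros(len(labels)), labels)):
            for i in test_idx:
                assignments[sample_ids[i]] = fold
    for w in caught:
        logger.warning("stratified_kfold: %s", w.message)
    return FoldPlan(k=k, assignments=assignments)


def stratified_split(labels: np.ndarray, fraction: float, rng):
    """One stratified train/validation split (>= 1 sample per class held out)."""
    labels = np.asarray(labels)
    train, val = [], []
    for c in np.unique(labels):
        idx = rng.permutation(np.flatnonzero(labels == c))
        n_val = max(1, int(round(fraction * len(idx))))
        val.extend(idx[:n_val])
        train.extend(idx[n_val:])
    return np.sort(np.array(train)), np.sort(np.array(val))


def stratified_batches(labels: np.ndarray, batch_size: int, rng) -> list[np.ndarray]:
    """Batches with proportional class representation, reshuffled per call.

    Each class's samples are shuffled and placed at evenly spaced
    fractional positions; sorting by position interleaves the classes, and
    chunking the interleaved order yields stratified batches without
    replacement.
    """
    labels = np.asarray(labels)
    n = len(labels)
    pos = np.empty(n)
    for c in np.unique(labels):
        idx = np.flatnonzero(labels == c)
        perm = rng.permutation(len(idx))
        pos[idx] = (perm + rng.random(len(idx))) / len(idx)
    order = np.argsort(pos, kind="stable")
    return [order[i : i + batch_size] for i in range(0, n, batch_size)]


# ---------------------------------------------------------------------------
# the loop


def _weighted_ce(model, data, idx, weights) -> float:
    probs = _subset_probs(model, data, idx)
    labels = _subset_labels(data, idx)
    w = weights[labels]
    p = np.clip(probs[np.arange(len(labels)), labels], 1e-12, None)
    return float(-(w * np.log(p)).sum() / w.sum())


def _subset_probs(model, data, idx):
    if isinstance(data, tuple):  # (full _BagData, subset indices)
        base, sub = data
        logits, _, _, _ = model._forward(base, sub[idx] if idx is not None else sub)
        return model._probs_from_logits(logits)
    logits, _, _, _ = model._forward(data, np.arange(len(data)) if idx is None else idx)
    return model._probs_from_logits(logits)


def _subset_labels(data, idx):
    if isinstance(data, tuple):
        base, sub = data
        return base.labels[sub if idx is None else sub[idx]]
    return data.labels if idx is None else data.labels[idx]


def train(model, train_idx: np.ndarray, val_data=None, rng=None, verbose=False):
    """Fit `model` in place; returns a per-epoch history DataFrame.

    `val_data` is either None, a `_BagData`, or `(full_data, val_indices)`.
    Early stopping monitors validation weighted cross-entropy (training CE
    when no validation set exists) and restores the best parameters.
    """
    from .autodiff import Adam

    cfg = model.config
    rng = rng or np.random.default_rng(cfg.seed)
    data = model.data
    train_labels = data.labels[train_idx]
    if cfg.class_weights:
        weights = class_weights(train_labels, model.n_classes)
    else:
        weights = np.ones(model.n_classes)
    sample_w = weights[train_labels]

    opt = Adam(model.parameters(), lr=cfg.lr)
    rows = []
    best = np.inf
    best_params = [p.data.copy() for p in opt.params]
    best_epoch = -1
    since_best = 0

    for epoch in range(cfg.epochs):
        for batch in stratified_batches(train_labels, cfg.batch_size, rng):
            bag_idx = train_idx[batch]
            kept = None
            if cfg.instance_dropout > 0:
                kept = [
                    instance_dropout_indices(data.sizes[i], cfg.instance_dropout, rng)
                    for i in bag_idx
                ]
            loss = model._loss(data, bag_idx, kept, sample_w[batch], True, rng)
            if not np.isfinite(loss.data):
                raise RuntimeError(
                    f"training diverged: non-finite loss at epoch {epoch} "
                    f"(lr={cfg.lr}); lower the learning rate or increase "
                    f"regularization"
                )
            opt.zero_grad()
            loss.backward()
            opt.step()

        row = {"epoch": epoch}
        row["train_loss"] = _weighted_ce(model, data, train_idx, weights)
        if val_data is not None:
            row["val_loss"] = _weighted_ce(model, val_data, None, weights)
            monitor = row["val_loss"]
        else:
            monitor = row["train_loss"]
        rows.append(row)
        if verbose:
            logger.info("epoch %d: %s", epoch, row)

        if monitor < best - 1e-9:
            best = monitor
            best_epoch = epoch
            best_params = [p.data.copy() for p in opt.params]
            since_best = 0
        else:
            since_best += 1
            if cfg.patience and since_best >= cfg.patience:
                break

    if rows:
        for p, saved in zip(opt.params, best_params):
            p.data[...] = saved
        logger.info("restored parameters from epoch %d", best_epoch)
    return pd.DataFrame(rows)
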