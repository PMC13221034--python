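"""Finetuning curricula, early stopping, and post-training 2x2 evaluation.

Four curricula cross an image filter with a freeze policy, all trained only
on stimuli with 3D shading cues:

  1. all viewpoints,   all weights unfrozen,  lr 2e-5
  2. all viewpoints,   decision head only,    lr 1e-3
  3. canonical only,   all weights unfrozen,  lr 2e-5
  4. canonical only,   decision head only,    lr 1e-3

with batch size 96, an 80/20 train/validation split (stratified by shape
category, applied after the image filter), and early stopping: train until
the validation error rate first increases, then adopt the checkpoint with
the lowest validation error.

The trainable reference classifier is a deliberately small two-stage model
-- a tanh feature stage over block-pooled grayscale pixels and a linear
softmax decision head, trained by plain SGD on cross-entropy -- exposing
the protocol's model contract (``evaluate``, ``update``, ``freeze``):
curriculum, split, early-stopping and freezing logic are what this module
contributes, and any classifier honoring the contract (e.g. a real
transformer) can be dropped in.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .retexture import Manifest
from .shapes import CATEGORIES

__all__ = [
    "CURRICULA",
    "Curriculum",
    "TrainLog",
    "ArrayDataset",
    "ReferenceClassifier",
    "make_curriculum",
    "train_with_early_stop",
    "evaluate_generalization",
]

#: The four finetuning regimes: (image_filter, freeze_policy, learning_rate).
CURRICULA = {
    1: ("all_views", "all_unfrozen", 2e-5),
    2: ("all_views", "head_only", 1e-3),
    3: ("canonical_only", "all_unfrozen", 2e-5),
    4: ("canonical_only", "head_only", 1e-3),
}


@dataclass
class Curriculum:
    """One finetuning regime plus its train/validation record split."""

    id: int | None
    image_filter: str  # all_views | canonical_only
    freeze_policy: str  # all_unfrozen | head_only
    learning_rate: float
    batch_size: int = 96
    train_fraction: float = 0.8
    condition: str = "3D"
    seed: int = 0
    train_records: pd.DataFrame | None = None
    val_records: pd.DataFrame | None = None

    def __post_init__(self):
        if self.image_filter not in ("all_views", "canonical_only"):
            raise ValueError(f"unknown image_filter {self.image_filter!r}")
        if self.freeze_policy not in ("all_unfrozen", "head_only"):
            raise ValueError(f"unknown freeze_policy {self.freeze_policy!r}")
        if self.id is not None:
            if self.id not in CURRICULA:
                raise ValueError(f"unknown curriculum id {self.id}")
            filt, freeze, lr = CURRICULA[self.id]
            if (self.image_filter, self.freeze_policy) != (filt, freeze):
                raise ValueError(f"curriculum {self.id} is {filt}/{freeze}")
            if self.learning_rate != lr:
                raise ValueError(f"curriculum {self.id} uses lr {lr}")


@dataclass
class TrainLog:
    """Per-epoch errors plus the stopping and adoption decisions."""

    train_errors: list = field(default_factory=list)
    val_errors: list = field(default_factory=list)
    batch_stimulus_ids: list = field(default_factory=list)  # per epoch
    stopped_epoch: int = 0  # 1-based; last epoch actually run
    adopted_epoch: int = 0  # 1-based; argmin of val_errors

    def validate(self):
        if self.adopted_epoch > self.stopped_epoch:
            raise ValueError("adopted epoch must not exceed stopped epoch")
        if self.val_errors and (self.val_errors[self.adopted_epoch - 1]
                                != min(self.val_errors)):
            raise ValueError("adopted epoch must minimize validation error")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "epoch": np.arange(1, len(self.val_errors) + 1),
            "train_error": self.train_errors,
            "val_error": self.val_errors,
        })


@dataclass
class ArrayDataset:
    """In-memory stimuli: preprocessed feature rows, shape labels, records."""

    X: np.ndarray  # (N, D) features
    y: np.ndarray  # (N,) int shape-category index
    records: pd.DataFrame

    def __post_init__(self):
        if not (len(self.X) == len(self.y) == len(self.records)):
            raise ValueError("X, y and records must align")
        self._by_id = {sid: i for i, sid in enumerate(self.records["stimulus_id"])}

    @classmethod
    def from_manifest(cls, manifest: Manifest,
                      standardize: bool = True) -> "ArrayDataset":
        """Load a materialized manifest's PNGs into feature rows.

        With ``standardize`` (default), feature columns are z-scored over
        the dataset; constant columns (e.g. always-background pixels) are
        scaled out, which conditions plain-SGD training."""
        from PIL import Image

        feats, labels = [], []
        for _, r in manifest.records.iterrows():
            img = np.asarray(Image.open(r["image_path"]), dtype=float) / 255.0
            feats.append(ReferenceClassifier.preprocess(img))
            labels.append(CATEGORIES.index(r["shape_category"]))
        X = np.stack(feats)
        if standardize:
            X = (X - X.mean(axis=0)) / (X.std(axis=0) + 1e-6)
        return cls(X=X, y=np.asarray(labels),
                   records=manifest.records.reset_index(drop=True))

    def subset_ids(self, stimulus_ids) -> tuple[np.ndarray, np.ndarray]:
        idx = np.array([self._by_id[s] for s in stimulus_ids])
        return self.X[idx], self.y[idx]


class ReferenceClassifier:
    """Small trainable two-stage classifier honoring the protocol contract.

    ``evaluate(X) -> probabilities``; ``update(X, y, lr)`` takes one SGD
    step on cross-entropy; ``freeze("head_only")`` pins the feature stage so
    only the decision head's weights move (a linear probe).
    """

    def __init__(self, n_features: int = 256, n_hidden: int = 64,
                 n_classes: int = 10, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.W1 = rng.normal(0, np.sqrt(2.0 / n_features), (n_hidden, n_features))
        self.b1 = np.zeros(n_hidden)
        self.W2 = rng.normal(0, np.sqrt(2.0 / n_hidden), (n_classes, n_hidden))
        self.b2 = np.zeros(n_classes)
        self.frozen = None  # None | "head_only"

    @staticmethod
    def preprocess(image: np.ndarray, side: int = 16) -> np.ndarray:
        """Image -> feature row: grayscale, nearest-sampled to side x side."""
        img = np.asarray(image, dtype=float)
        if img.ndim == 3:
            img = img.mean(axis=2)
        if img.ndim != 2:
            raise ValueError("expected an image or a feature row")
        ri = np.linspace(0, img.shape[0] - 1, side).round().astype(int)
        ci = np.linspace(0, img.shape[1] - 1, side).round().astype(int)
        return (img[np.ix_(ri, ci)].ravel() * 2.0) - 1.0

    # -- protocol -----------------------------------------------------------

    def freeze(self, policy) -> None:
        if policy not in (None, "none", "head_only"):
            raise ValueError(f"unsupported freeze policy {policy!r}")
        self.frozen = "head_only" if policy == "head_only" else None

    def _hidden(self, X: np.ndarray) -> np.ndarray:
        return np.tanh(X @ self.W1.T + self.b1)

    def evaluate(self, X: np.ndarray) -> np.ndarray:
        """Softmax probabilities over the ten categories, one row per input."""
        logits = self._hidden(np.atleast_2d(X)) @ self.W2.T + self.b2
        logits = logits - logits.max(axis=1, keepdims=True)
        e = np.exp(logits)
        return e / e.sum(axis=1, keepdims=True)

    def update(self, X: np.ndarray, y: np.ndarray, lr: float) -> float:
        """One SGD step on mean cross-entropy; returns the batch loss."""
        X = np.atleast_2d(X)
        y = np.asarray(y, dtype=int)
        h = self._hidden(X)
        logits = h @ self.W2.T + self.b2
        logits = logits - logits.max(axis=1, keepdims=True)
        e = np.exp(logits)
        probs = e / e.sum(axis=1, keepdims=True)
        n = len(y)
        loss = float(-np.log(probs[np.arange(n), y] + 1e-12).mean())
        g = probs.copy()
        g[np.arange(n), y] -= 1.0
        g /= n
        gh = (g @ self.W2) * (1 - h**2)  # backprop through pre-update head
        self.W2 -= lr * (g.T @ h)
        self.b2 -= lr * g.sum(axis=0)
        if self.frozen != "head_only":
            self.W1 -= lr * (gh.T @ X)
            self.b1 -= lr * gh.sum(axis=0)
        return loss

    # -- checkpoints --------------------------------------------------------

    def get_params(self) -> dict:
        return {k: getattr(self, k).copy() for k in ("W1", "b1", "W2", "b2")}

    def set_params(self, params: dict) -> None:
        for k, v in params.items():
            setattr(self, k, v.copy())

    def save(self, path) -> None:
        np.savez(Path(path), **self.get_params())

    @classmethod
    def load(cls, path) -> "ReferenceClassifier":
        data = np.load(Path(path))
        model = cls(n_features=data["W1"].shape[1], n_hidden=data["W1"].shape[0],
                    n_classes=data["W2"].shape[0])
        model.set_params({k: data[k] for k in data.files})
        return model


def make_curriculum(id: int, manifest: Manifest, seed: int = 0) -> Curriculum:
    """Instantiate a curriculum on a manifest: filter, then stratified 80/20 split.

    The image filter (3D condition always; canonical viewpoints only for
    curricula 3/4) is applied before splitting; the split is stratified by
    shape category and deterministic under ``seed``; train and validation
    sets partition the filtered records exactly.
    """
    if id not in CURRICULA:
        raise ValueError(f"unknown curriculum id {id}")
    image_filter, freeze_policy, lr = CURRICULA[id]
    records = manifest.records
    keep = records["condition"] == "3D"
    if image_filter == "canonical_only":
        keep &= records["canonicality"] == "canonical"
    filtered = records[keep].reset_index(drop=True)
    if len(filtered) == 0:
        raise ValueError("no records survive the curriculum's image filter")

    rng = np.random.default_rng(seed)
    train_idx: list[int] = []
    for cat in sorted(filtered["shape_category"].unique()):
        idx = filtered.index[filtered["shape_category"] == cat].to_numpy()
        perm = rng.permutation(idx)
        n_train = int(round(0.8 * len(idx)))
        train_idx.extend(perm[:n_train])
    train_mask = np.zeros(len(filtered), dtype=bool)
    train_mask[np.asarray(train_idx, dtype=int)] = True
    return Curriculum(
        id=id, image_filter=image_filter, freeze_policy=freeze_policy,
        learning_rate=lr, seed=seed,
        train_records=filtered[train_mask].reset_index(drop=True),
        val_records=filtered[~train_mask].reset_index(drop=True),
    )


def _error_rate(model, X: np.ndarray, y: np.ndarray) -> float:
    return float((model.evaluate(X).argmax(axis=1) != y).mean())


def train_with_early_stop(model, curriculum: Curriculum, data: ArrayDataset,
                          max_epochs: int = 20):
    """Train until validation error first increases; adopt the best checkpoint.

    Epochs shuffle the training order once with the run seed's stream; the
    last partial batch is kept.  After each epoch the validation error is
    logged and the parameters snapshotted; training stops at the first
    epoch whose validation error exceeds the previous epoch's (or at
    ``max_epochs``), and the model is restored to the checkpoint with the
    minimum validation error.
    """
    if curriculum.train_records is None or curriculum.val_records is None:
        raise ValueError("curriculum carries no data split; use make_curriculum")
    if curriculum.freeze_policy == "head_only" and not hasattr(model, "freeze"):
        raise TypeError("model does not support freezing; head_only unavailable")
    if hasattr(model, "freeze"):
        model.freeze("head_only" if curriculum.freeze_policy == "head_only" else None)

    train_ids = list(curriculum.train_records["stimulus_id"])
    Xtr, ytr = data.subset_ids(train_ids)
    Xva, yva = data.subset_ids(list(curriculum.val_records["stimulus_id"]))

    rng = np.random.default_rng(curriculum.seed)
    log = TrainLog()
    checkpoints = []
    for epoch in range(1, max_epochs + 1):
        order = rng.permutation(len(Xtr))
        epoch_batches = []
        for lo in range(0, len(order), curriculum.batch_size):
            sel = order[lo:lo + curriculum.batch_size]
            model.update(Xtr[sel], ytr[sel], curriculum.learning_rate)
            epoch_batches.append([train_ids[i] for i in sel])
        log.batch_stimulus_ids.append(epoch_batches)
        log.train_errors.append(_error_rate(model, Xtr, ytr))
        log.val_errors.append(_error_rate(model, Xva, yva))
        checkpoints.append(model.get_params() if hasattr(model, "get_params") else None)
        log.stopped_epoch = epoch
        if epoch >= 2 and log.val_errors[-1] > log.val_errors[-2]:
            break
    log.adopted_epoch = int(np.argmin(log.val_errors)) + 1
    if checkpoints[log.adopted_epoch - 1] is not None:
        model.set_params(checkpoints[log.adopted_epoch - 1])
    log.validate()
    return model, log


def evaluate_generalization(model, data: ArrayDataset):
    """Post-training 2x2 accuracy table over condition x canonicality.

    Rows are conditions {3D, 2D}, columns canonicality {canonical,
    noncanonical}; the accompanying gaps give the canonical-minus-
    noncanonical accuracy difference within each condition (the humanlike
    signature is a larger gap for 2D than for 3D images).  Cells absent
    from the dataset are reported as NaN.
    """
    pred = model.evaluate(data.X).argmax(axis=1)
    correct = pred == data.y
    table = pd.DataFrame(np.nan, index=["3D", "2D"],
                         columns=["canonical", "noncanonical"])
    for cond in table.index:
        for canon in table.columns:
            sel = ((data.records["condition"] == cond)
                   & (data.records["canonicality"] == canon)).to_numpy()
            if sel.any():
                table.loc[cond, canon] = correct[sel].mean()
    gaps = {cond: float(table.loc[cond, "canonical"]
                        - table.loc[cond, "noncanonical"])
            for cond in table.index}
    return table, gaps
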