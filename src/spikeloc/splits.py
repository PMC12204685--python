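"""Transductive, inductive and cross-dataset split plans.

The 60/20/20 train/validation/test design with full coverage is realized as
a 5-group rotation: units (or animals, for inductive splits) are dealt into
five near-equal groups; fold ``i`` tests on group ``i``, validates on group
``(i+1) mod 5`` and trains on the remaining three groups.  Every unit is
therefore tested exactly once and validated exactly once across the five
folds.

Transductive plans stratify per (animal, class) so that each animal and
class contributes proportionally to every set.  Inductive plans assign whole
animals, so test animals are never seen during training.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datasets import Dataset, DatasetError, task_labels

__all__ = [
    "SplitPlan",
    "N_FOLDS",
    "transductive_splits",
    "inductive_splits",
    "cross_dataset_split",
]

N_FOLDS = 5
ASSIGNMENTS = ("train", "val", "test")


@dataclass(frozen=True)
class SplitPlan:
    """Fold-wise unit assignments for one task.

    ``folds[i]`` maps unit_id -> 'train' | 'val' | 'test'.
    """

    mode: str
    task: str
    folds: tuple[dict, ...]
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("transductive", "inductive", "cross_dataset"):
            raise ValueError(f"unknown split mode {self.mode!r}")
        for fold in self.folds:
            bad = set(fold.values()) - set(ASSIGNMENTS)
            if bad:
                raise ValueError(f"unknown assignments {bad}")

    @property
    def n_folds(self) -> int:
        return len(self.folds)

    def members(self, fold: int, assignment: str) -> list[str]:
        return [uid for uid, a in self.folds[fold].items() if a == assignment]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"unit_id": uid, "fold": i, "assignment": a}
            for i, fold in enumerate(self.folds)
            for uid, a in fold.items()
        ]
        return pd.DataFrame(rows)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, mode: str, task: str,
                   seed: int | None = None) -> "SplitPlan":
        folds = []
        for i in sorted(df["fold"].unique()):
            sub = df[df["fold"] == i]
            folds.append(dict(zip(sub["unit_id"].astype(str), sub["assignment"])))
        return cls(mode=mode, task=task, folds=tuple(folds), seed=seed)


def _rotate(groups: list[list[str]]) -> tuple[dict, ...]:
    """Fold i: test = group i, val = group i+1, train = the rest."""
    folds = []
    k = len(groups)
    for i in range(k):
        fold: dict[str, str] = {}
        for g, members in enumerate(groups):
            if g == i:
                a = "test"
            elif g == (i + 1) % k:
                a = "val"
            else:
                a = "train"
            for m in members:
                fold[m] = a
        folds.append(fold)
    return tuple(folds)


def _deal(items: list[str], rng: np.random.Generator, groups: list[list[str]],
          offset: int) -> int:
    """Deal shuffled items round-robin into the 5 groups, starting at offset."""
    items = list(items)
    rng.shuffle(items)
    for j, it in enumerate(items):
        groups[(offset + j) % N_FOLDS].append(it)
    return (offset + len(items)) % N_FOLDS


def transductive_splits(ds: Dataset, task: str, seed: int = 0) -> SplitPlan:
    """Per-animal, per-class stratified 5-fold rotation over units.

    Within every (animal, class) cell, units are dealt round-robin into the
    five groups; cells smaller than five continue the deal across animals of
    the same class, so class proportions are preserved globally to within
    one unit.
    """
    labels = task_labels(ds, task).dropna()
    if labels.empty:
        raise DatasetError(f"task {task!r}: no labelled units")
    rng = np.random.default_rng(seed)
    meta = ds.units_frame().loc[labels.index]
    groups: list[list[str]] = [[] for _ in range(N_FOLDS)]
    for cls in sorted(labels.unique()):
        cls_units = meta[labels == cls]
        # start each class at a random group to avoid systematic imbalance
        offset = int(rng.integers(N_FOLDS))
        for animal in sorted(cls_units["animal_id"].unique()):
            cell = list(cls_units[cls_units["animal_id"] == animal]["unit_id"])
            offset = _deal(cell, rng, groups, offset)
    return SplitPlan("transductive", task, _rotate(groups), seed)


def inductive_splits(ds: Dataset, task: str, seed: int = 0) -> SplitPlan:
    """Animal-level 5-fold rotation: test animals are fully held out."""
    labels = task_labels(ds, task).dropna()
    meta = ds.units_frame().loc[labels.index]
    animals = sorted(meta["animal_id"].unique())
    if len(animals) < N_FOLDS:
        raise DatasetError(
            f"inductive split needs >= {N_FOLDS} animals, got {len(animals)}; "
            "use a transductive split or more animals"
        )
    rng = np.random.default_rng(seed)
    agroups: list[list[str]] = [[] for _ in range(N_FOLDS)]
    _deal(animals, rng, agroups, 0)
    by_animal = {a: list(g["unit_id"]) for a, g in meta.groupby("animal_id")}
    groups = [[u for a in ag for u in by_animal[a]] for ag in agroups]
    return SplitPlan("inductive", task, _rotate(groups), seed)


def cross_dataset_split(train_ds: Dataset, test_ds: Dataset, task: str,
                        seed: int = 0) -> SplitPlan:
    """Train/val on one dataset, test on all of another.

    Classes are intersected; training units are split 80/20 into train and
    validation, stratified per class.  Test units whose class is absent from
    the training dataset are excluded.  Unit ids must not collide between
    the two datasets.
    """
    tr_labels = task_labels(train_ds, task).dropna()
    te_labels = task_labels(test_ds, task).dropna()
    shared = sorted(set(tr_labels.unique()) & set(te_labels.unique()))
    if not shared:
        raise DatasetError(f"task {task!r}: no shared classes between datasets")
    if len(shared) < 2:
        raise DatasetError(f"task {task!r}: only one shared class {shared}")
    overlap = set(tr_labels.index) & set(te_labels.index)
    if overlap:
        raise DatasetError("unit_id collision between train and test datasets")
    rng = np.random.default_rng(seed)
    fold: dict[str, str] = {}
    for cls in shared:
        members = list(tr_labels[tr_labels == cls].index)
        rng.shuffle(members)
        n_val = int(round(0.2 * len(members)))
        for u in members[:n_val]:
            fold[u] = "val"
        for u in members[n_val:]:
            fold[u] = "train"
    for u in te_labels[te_labels.isin(shared)].index:
        fold[u] = "test"
    return SplitPlan("cross_dataset", task, (fold,), seed)
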