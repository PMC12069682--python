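"""Scaffold-based train/test splitting and stratified k-fold plans.

Scaffold splitting assigns whole Bemis–Murcko scaffold groups to one side of
the partition, so the test set contains chemotypes the model never saw —
a deliberately harder generalization test than a random split.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np
from rdkit import Chem
from rdkit.Chem.Scaffolds import MurckoScaffold

from .datatypes import ACTIVE, INACTIVE, CompoundRecord, LabeledDataset
from .featurize import FingerprintMatrix

logger = logging.getLogger(__name__)

#: Scaffold key shared by all acyclic molecules (no ring framework).
ACYCLIC_KEY = ""


@dataclass(frozen=True)
class SplitResult:
    train: LabeledDataset
    test: LabeledDataset
    scaffold_assignment: Mapping[str, str]  # canonical SMILES -> scaffold key

    def __post_init__(self) -> None:
        train_sc = {self.scaffold_assignment[s] for s in self.train.smiles}
        test_sc = {self.scaffold_assignment[s] for s in self.test.smiles}
        overlap_smiles = self.train.smiles_set() & self.test.smiles_set()
        if overlap_smiles:
            raise ValueError(f"train/test share SMILES: {sorted(overlap_smiles)[:3]}")
        if train_sc & test_sc:
            raise ValueError(f"train/test share scaffolds: {sorted(train_sc & test_sc)[:3]}")


@dataclass(frozen=True)
class FoldPlan:
    """Assignment of every compound (by canonical SMILES) to one of k folds."""

    k: int
    fold_of: Mapping[str, int]
    seed: int

    def fold_indices(self, ds: LabeledDataset, fold: int) -> tuple[list[int], list[int]]:
        """(train_indices, heldout_indices) for one CV iteration."""
        held = [i for i, s in enumerate(ds.smiles) if self.fold_of[s] == fold]
        train = [i for i, s in enumerate(ds.smiles) if self.fold_of[s] != fold]
        return train, held


def murcko_scaffold(record: CompoundRecord | str) -> str:
    """Canonical SMILES of the Bemis–Murcko framework (rings + linkers).

    Acyclic molecules have an empty framework and share the reserved key
    ``""``, so they always travel together in a scaffold split.
    """
    smiles = record.canonical_smiles if isinstance(record, CompoundRecord) else record
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"SMILES does not parse: {smiles!r}")
    scaffold = MurckoScaffold.GetScaffoldForMol(mol)
    if scaffold is None or scaffold.GetNumAtoms() == 0:
        return ACYCLIC_KEY
    return Chem.MolToSmiles(scaffold)


def scaffold_split(ds: LabeledDataset, train_fraction: float = 0.8) -> SplitResult:
    """Deterministic greedy scaffold split.

    Scaffold groups are sorted by descending size (ties broken by scaffold
    key) and assigned whole to the training set until it holds
    ``train_fraction`` of the compounds; the remaining groups form the test
    set.  Large common scaffolds therefore land in train and the rarer
    chemotypes in test.
    """
    if len(ds) == 0:
        raise ValueError("cannot split an empty dataset")
    if not 0 < train_fraction < 1:
        raise ValueError("train_fraction must be in (0, 1)")

    assignment = {s: murcko_scaffold(s) for s in ds.smiles}
    groups: dict[str, list[int]] = {}
    for i, s in enumerate(ds.smiles):
        groups.setdefault(assignment[s], []).append(i)

    ordered = sorted(groups.items(), key=lambda kv: (-len(kv[1]), kv[0]))
    target = int(round(train_fraction * len(ds)))
    train_idx: list[int] = []
    test_idx: list[int] = []
    for _, members in ordered:
        if len(train_idx) < target:
            train_idx.extend(members)
        else:
            test_idx.extend(members)
    if not test_idx:
        warnings.warn(
            "scaffold split produced an empty test set "
            "(a single scaffold group dominates the dataset)",
            stacklevel=2,
        )
    return SplitResult(ds.select(sorted(train_idx)), ds.select(sorted(test_idx)), assignment)


def remove_cross_split_duplicates(split: SplitResult, fps: FingerprintMatrix) -> SplitResult:
    """Drop training compounds whose fingerprint collides with any test one.

    Folded fingerprints can collide even for distinct canonical SMILES; a
    collision across the split is information leakage, so the training copy
    is removed (the test set is left untouched).
    """
    test_keys = {fps.row(s).tobytes() for s in split.test.smiles}
    keep = [
        i
        for i, s in enumerate(split.train.smiles)
        if fps.row(s).tobytes() not in test_keys
    ]
    n_removed = len(split.train) - len(keep)
    if n_removed:
        logger.info("removed %d train compounds colliding with test fingerprints", n_removed)
    return SplitResult(split.train.select(keep), split.test, split.scaffold_assignment)


def stratified_kfold(ds: LabeledDataset, k: int = 10, seed: int = 0) -> FoldPlan:
    """Class-stratified k-fold plan: per class, a seeded permutation is dealt
    round-robin to folds, so each fold's active:inactive ratio deviates from
    the global ratio by at most one compound per class."""
    if k < 2:
        raise ValueError("k must be >= 2")
    for label in (ACTIVE, INACTIVE):
        n = sum(1 for l in ds.labels if l == label)
        if n < k:
            raise ValueError(f"class {label!r} has {n} members, fewer than k={k}")
    rng = np.random.default_rng(seed)
    fold_of: dict[str, int] = {}
    for label in (ACTIVE, INACTIVE):
        members = [s for s, l in zip(ds.smiles, ds.labels) if l == label]
        perm = rng.permutation(len(members))
        for pos, j in enumerate(perm):
            fold_of[members[j]] = pos % k
    return FoldPlan(k=k, fold_of=fold_of, seed=seed)
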