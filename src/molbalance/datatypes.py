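"""Core value types shared across the package.

The package works on two-class (active / inactive) compound collections.
``CompoundRecord`` is a single standardized molecule, ``LabeledDataset`` a
deduplicated collection of labelled records.  Both are deliberately small,
immutable containers; all heavy lifting (standardization, fingerprints,
models) lives in the dedicated modules.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Sequence

import pandas as pd

ACTIVE = "active"
INACTIVE = "inactive"
LABELS = (ACTIVE, INACTIVE)

#: Provenance of a compound record.
SOURCES = ("public", "generated", "synthetic")


@dataclass(frozen=True)
class CompoundRecord:
    """A standardized molecule: canonical SMILES plus provenance."""

    canonical_smiles: str
    compound_id: str = ""
    source: str = "public"

    def __post_init__(self) -> None:
        if not self.canonical_smiles:
            raise ValueError("canonical_smiles must be non-empty")
        if self.source not in SOURCES:
            raise ValueError(f"unknown source {self.source!r}; expected one of {SOURCES}")

    def with_source(self, source: str) -> "CompoundRecord":
        return replace(self, source=source)


@dataclass(frozen=True)
class RawBioactivity:
    """One raw dose-response measurement (EC50 / IC50 / Ki) for a compound."""

    compound_id: str
    smiles: str
    activity_type: str  # EC50 | IC50 | Ki
    relation: str  # = | > | < | >= | <=
    value: float
    unit: str  # nM | uM | M

    ACTIVITY_TYPES = ("EC50", "IC50", "Ki")

    def __post_init__(self) -> None:
        if self.value <= 0:
            raise ValueError(f"bioactivity value must be positive, got {self.value}")


class DuplicateSmilesError(ValueError):
    pass


class CrossLabelError(ValueError):
    pass


class LabeledDataset:
    """An immutable collection of ``(CompoundRecord, label)`` pairs.

    Invariants enforced at construction: every canonical SMILES occurs at
    most once, and never under both labels.  Use
    :func:`molbalance.curation.deduplicate` to build one from raw records.
    """

    def __init__(self, records: Iterable[tuple[CompoundRecord, str]]):
        records = tuple(records)
        seen: dict[str, str] = {}
        for rec, label in records:
            if label not in LABELS:
                raise ValueError(f"label must be one of {LABELS}, got {label!r}")
            prev = seen.get(rec.canonical_smiles)
            if prev is not None:
                if prev != label:
                    raise CrossLabelError(
                        f"{rec.canonical_smiles} appears under both labels"
                    )
                raise DuplicateSmilesError(f"duplicate SMILES {rec.canonical_smiles}")
            seen[rec.canonical_smiles] = label
        self._records = records

    # -- container protocol -------------------------------------------------
    def __len__(self) -> int:
        return len(self._records)

    def __iter__(self) -> Iterator[tuple[CompoundRecord, str]]:
        return iter(self._records)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, LabeledDataset):
            return NotImplemented
        return self._records == other._records

    def __repr__(self) -> str:
        return (
            f"LabeledDataset(n={len(self)}, actives={self.n_actives}, "
            f"inactives={self.n_inactives})"
        )

    # -- accessors ----------------------------------------------------------
    @property
    def records(self) -> tuple[tuple[CompoundRecord, str], ...]:
        return self._records

    @property
    def compounds(self) -> tuple[CompoundRecord, ...]:
        return tuple(r for r, _ in self._records)

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(l for _, l in self._records)

    @property
    def smiles(self) -> tuple[str, ...]:
        return tuple(r.canonical_smiles for r, _ in self._records)

    @property
    def n_actives(self) -> int:
        return sum(1 for _, l in self._records if l == ACTIVE)

    @property
    def n_inactives(self) -> int:
        return sum(1 for _, l in self._records if l == INACTIVE)

    def subset_label(self, label: str) -> "LabeledDataset":
        return LabeledDataset((r, l) for r, l in self._records if l == label)

    def select(self, indices: Sequence[int]) -> "LabeledDataset":
        return LabeledDataset(self._records[i] for i in indices)

    def smiles_set(self) -> frozenset[str]:
        return frozenset(self.smiles)

    def concat(self, other: "LabeledDataset") -> "LabeledDataset":
        return LabeledDataset(self._records + other._records)

    # -- serialization ------------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "compound_id": [r.compound_id for r, _ in self._records],
                "canonical_smiles": [r.canonical_smiles for r, _ in self._records],
                "label": [l for _, l in self._records],
                "source": [r.source for r, _ in self._records],
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "LabeledDataset":
        source = df["source"] if "source" in df.columns else ["public"] * len(df)
        ids = df["compound_id"] if "compound_id" in df.columns else [""] * len(df)
        return cls(
            (CompoundRecord(s, str(i), src), lab)
            for s, i, src, lab in zip(
                df["canonical_smiles"], ids, source, df["label"]
            )
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "LabeledDataset":
        return cls.from_frame(pd.read_csv(path))
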