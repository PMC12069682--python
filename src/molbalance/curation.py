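"""Standardization, activity labelling and dataset assembly.

The curation pipeline mirrors common practice for public dose-response data:

1. every raw SMILES is parsed, desalted (largest organic fragment kept),
   neutralized where chemically possible, and canonicalized;
2. a dual activity cutoff turns measured values into class labels —
   values at or below the active cutoff (default 1 µM) are active, values at
   or above the inactive cutoff (default 10 µM) are inactive, the band in
   between is excluded as ambiguous.  Censored measurements (">" / "≥")
   above the inactive cutoff still count as inactive;
3. duplicate canonical SMILES within a class are collapsed and any SMILES
   reported under both labels is dropped from both classes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from rdkit import Chem, RDLogger
from rdkit.Chem.MolStandardize import rdMolStandardize

from .datatypes import ACTIVE, INACTIVE, CompoundRecord, LabeledDataset, RawBioactivity

logger = logging.getLogger(__name__)

RDLogger.DisableLog("rdApp.*")  # rdkit is chatty about every rejected SMILES

EXCLUDED = "excluded"

_REL_ALIASES = {
    "=": "=",
    "==": "=",
    ">": ">",
    "<": "<",
    ">=": ">=",
    "<=": "<=",
    "≥": ">=",
    "≤": "<=",
}

_UNIT_TO_UM = {"nM": 1e-3, "uM": 1.0, "µM": 1.0, "um": 1.0, "M": 1e6}


@dataclass(frozen=True)
class CurationConfig:
    """Dual activity cutoffs, in µM."""

    active_cutoff_uM: float = 1.0
    inactive_cutoff_uM: float = 10.0

    def __post_init__(self) -> None:
        if self.active_cutoff_uM <= 0 or self.inactive_cutoff_uM <= 0:
            raise ValueError("cutoffs must be positive")
        if self.inactive_cutoff_uM < self.active_cutoff_uM:
            raise ValueError("inactive cutoff must be >= active cutoff")


@dataclass(frozen=True)
class Rejection:
    """A structured record of why a raw input was dropped."""

    raw: str
    reason: str


_uncharger = rdMolStandardize.Uncharger()
_fragment_chooser = rdMolStandardize.LargestFragmentChooser(preferOrganic=True)


def standardize_smiles(
    raw: str, compound_id: str = "", source: str = "public"
) -> CompoundRecord | Rejection:
    """Parse, desalt and canonicalize one SMILES.

    Keeps the largest organic fragment (salt/counter-ion stripping),
    neutralizes charges where chemically valid, and returns the canonical
    SMILES.  Unparsable input yields a :class:`Rejection` with a reason code
    rather than raising, so bulk curation can log and continue.
    """
    if not raw or not raw.strip():
        return Rejection(raw, "empty")
    mol = Chem.MolFromSmiles(raw.strip())
    if mol is None:
        return Rejection(raw, "parse_error")
    try:
        mol = _fragment_chooser.choose(mol)
        mol = _uncharger.uncharge(mol)
        canonical = Chem.MolToSmiles(mol)
    except Exception:  # pragma: no cover - rdkit failure on exotic input
        return Rejection(raw, "standardization_error")
    if not canonical:
        return Rejection(raw, "empty_after_standardization")
    return CompoundRecord(canonical_smiles=canonical, compound_id=compound_id, source=source)


def _to_uM(value: float, unit: str) -> float:
    try:
        factor = _UNIT_TO_UM[unit.strip()]
    except KeyError:
        raise ValueError(f"unknown unit {unit!r}; expected one of nM, uM/µM, M") from None
    return value * factor


def label_activity(b: RawBioactivity, cfg: CurationConfig = CurationConfig()) -> str:
    """Assign ``active`` / ``inactive`` / ``excluded`` from a dual cutoff.

    Censored values are treated conservatively: ">" bounds at or above the
    inactive cutoff are informative (inactive), "<" bounds at or below the
    active cutoff are informative (active); any other censored bound says
    nothing about the compound's class and is excluded.
    """
    if b.value <= 0:
        raise ValueError("bioactivity value must be positive")
    rel = _REL_ALIASES.get(b.relation.strip())
    if rel is None:
        raise ValueError(f"unknown relation {b.relation!r}")
    value_uM = _to_uM(b.value, b.unit)

    if value_uM <= cfg.active_cutoff_uM and rel in ("=", "<", "<="):
        return ACTIVE
    if value_uM >= cfg.inactive_cutoff_uM and rel in ("=", ">", ">="):
        return INACTIVE
    return EXCLUDED


def deduplicate(records: Iterable[tuple[CompoundRecord, str]]) -> LabeledDataset:
    """Collapse within-class duplicates; drop cross-class conflicts entirely.

    Deterministic: the first occurrence (input order) of each canonical
    SMILES within a class is retained.
    """
    first: dict[str, tuple[CompoundRecord, str]] = {}
    conflicted: set[str] = set()
    for rec, label in records:
        key = rec.canonical_smiles
        if key in conflicted:
            continue
        kept = first.get(key)
        if kept is None:
            first[key] = (rec, label)
        elif kept[1] != label:
            conflicted.add(key)
            del first[key]
    return LabeledDataset(first.values())


REQUIRED_COLUMNS = ("compound_id", "smiles", "activity_type", "relation", "value", "unit")


@dataclass
class CurationLog:
    """Counts of what happened to every input row."""

    n_input: int = 0
    n_rejected: dict[str, int] = field(default_factory=dict)
    n_active: int = 0
    n_inactive: int = 0
    n_excluded: int = 0
    n_duplicates_removed: int = 0
    n_conflicts_removed: int = 0
    notes: list[str] = field(default_factory=list)

    def as_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_rejected": dict(self.n_rejected),
            "n_active": self.n_active,
            "n_inactive": self.n_inactive,
            "n_excluded": self.n_excluded,
            "n_duplicates_removed": self.n_duplicates_removed,
            "n_conflicts_removed": self.n_conflicts_removed,
            "notes": list(self.notes),
        }


def read_bioactivity_table(path) -> pd.DataFrame:
    """Read the raw bioactivity schema from CSV or TSV (sniffed by extension)."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    try:
        df = pd.read_csv(path, sep=sep)
    except pd.errors.EmptyDataError:
        df = pd.DataFrame(columns=REQUIRED_COLUMNS)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"missing required column(s): {', '.join(missing)}")
    return df


def curate_bioactivities(
    rows: Sequence[RawBioactivity],
    cfg: CurationConfig = CurationConfig(),
) -> tuple[LabeledDataset, CurationLog]:
    """Standardize → label → deduplicate a sequence of raw measurements."""
    log = CurationLog(n_input=len(rows))
    labelled: list[tuple[CompoundRecord, str]] = []
    for b in rows:
        rec = standardize_smiles(b.smiles, compound_id=b.compound_id)
        if isinstance(rec, Rejection):
            log.n_rejected[rec.reason] = log.n_rejected.get(rec.reason, 0) + 1
            continue
        label = label_activity(b, cfg)
        if label == EXCLUDED:
            log.n_excluded += 1
            continue
        labelled.append((rec, label))
    ds = deduplicate(labelled)
    kept = ds.smiles_set()
    n_labelled_unique = len({r.canonical_smiles for r, _ in labelled})
    log.n_conflicts_removed = n_labelled_unique - len(kept)
    log.n_duplicates_removed = len(labelled) - n_labelled_unique
    log.n_active = ds.n_actives
    log.n_inactive = ds.n_inactives
    if log.n_input == 0:
        log.notes.append("empty input")
        logger.warning("curation input was empty")
    return ds, log


def build_dataset(
    path, cfg: CurationConfig = CurationConfig()
) -> tuple[LabeledDataset, CurationLog]:
    """Curate a CSV/TSV bioactivity table from disk.

    Returns the deduplicated dataset and a :class:`CurationLog` with one
    count per outcome (rejected-by-reason / excluded / kept / deduplicated).
    """
    df = read_bioactivity_table(path)
    rows = [
        RawBioactivity(
            compound_id=str(r.compound_id),
            smiles=str(r.smiles),
            activity_type=str(r.activity_type),
            relation=str(r.relation),
            value=float(r.value),
            unit=str(r.unit),
        )
        for r in df.itertuples(index=False)
    ]
    return curate_bioactivities(rows, cfg)


def read_smiles_file(path, source: str = "public") -> list[CompoundRecord]:
    """Read a .smi file (``smiles [id]`` per line), standardizing each entry."""
    out: list[CompoundRecord] = []
    for i, line in enumerate(Path(path).read_text().splitlines()):
        parts = line.split()
        if not parts:
            continue
        cid = parts[1] if len(parts) > 1 else f"smi_{i}"
        rec = standardize_smiles(parts[0], compound_id=cid, source=source)
        if isinstance(rec, CompoundRecord):
            out.append(rec)
    return out


def write_smiles_file(records: Iterable[CompoundRecord], path) -> None:
    lines = [f"{r.canonical_smiles} {r.compound_id}".rstrip() for r in records]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))
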