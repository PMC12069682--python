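"""Morgan fingerprints, Tanimoto similarity, physicochemical descriptors.

Fingerprints are hashed circular substructure fingerprints (radius 2 folded
to 1,024 bits ≈ ECFP4), the representation used throughout: model input,
class-overlap measurement, clustering and generation metrics all operate on
the same bits.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import Descriptors, rdFingerprintGenerator

from .datatypes import CompoundRecord, LabeledDataset


@dataclass(frozen=True)
class FingerprintConfig:
    n_bits: int = 1024
    radius: int = 2

    def __post_init__(self) -> None:
        if self.n_bits < 64 or (self.n_bits & (self.n_bits - 1)) != 0:
            raise ValueError("n_bits must be a power of two >= 64")
        if self.radius < 1:
            raise ValueError("radius must be >= 1")


@dataclass(frozen=True)
class DescriptorProfile:
    """Six standard physicochemical descriptors used for class profiling."""

    molecular_weight: float
    logp: float
    n_rings: int
    n_rotatable_bonds: int
    n_hbd: int
    n_hba: int


class FingerprintMatrix:
    """Aligned table of binary fingerprints: one row per compound id."""

    def __init__(self, ids: Sequence[str], bits: np.ndarray, config: FingerprintConfig):
        bits = np.asarray(bits, dtype=np.uint8)
        if bits.ndim != 2 or bits.shape[1] != config.n_bits:
            raise ValueError(
                f"bits must be (n, {config.n_bits}); got shape {bits.shape}"
            )
        if len(ids) != bits.shape[0]:
            raise ValueError("ids and bits row count differ")
        self.ids = list(ids)
        self.bits = bits
        self.config = config
        self._index = {cid: i for i, cid in enumerate(self.ids)}

    def __len__(self) -> int:
        return len(self.ids)

    def row(self, compound_id: str) -> np.ndarray:
        return self.bits[self._index[compound_id]]

    def select(self, indices: Sequence[int]) -> "FingerprintMatrix":
        idx = list(indices)
        return FingerprintMatrix([self.ids[i] for i in idx], self.bits[idx], self.config)

    def subset_ids(self, ids: Sequence[str]) -> "FingerprintMatrix":
        return self.select([self._index[i] for i in ids])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "compound_id": self.ids,
                "bits": ["".join(map(str, row)) for row in self.bits],
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, config: FingerprintConfig | None = None) -> "FingerprintMatrix":
        df = pd.read_csv(path, dtype={"bits": str})
        bits = np.array([[int(c) for c in s] for s in df["bits"]], dtype=np.uint8)
        if config is None:
            config = FingerprintConfig(n_bits=bits.shape[1])
        return cls([str(i) for i in df["compound_id"]], bits, config)


def _mol(record: CompoundRecord | str) -> Chem.Mol:
    smiles = record.canonical_smiles if isinstance(record, CompoundRecord) else record
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"SMILES does not parse: {smiles!r}")
    return mol


def morgan_fingerprint(
    record: CompoundRecord | str, cfg: FingerprintConfig = FingerprintConfig()
) -> np.ndarray:
    """Binary hashed circular fingerprint folded to ``cfg.n_bits``."""
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=cfg.radius, fpSize=cfg.n_bits)
    fp = gen.GetFingerprintAsNumPy(_mol(record))
    return fp.astype(np.uint8)


def fingerprint_records(
    records: Iterable[CompoundRecord], cfg: FingerprintConfig = FingerprintConfig()
) -> FingerprintMatrix:
    records = list(records)
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=cfg.radius, fpSize=cfg.n_bits)
    bits = np.zeros((len(records), cfg.n_bits), dtype=np.uint8)
    for i, rec in enumerate(records):
        bits[i] = gen.GetFingerprintAsNumPy(_mol(rec))
    return FingerprintMatrix([r.compound_id or r.canonical_smiles for r in records], bits, cfg)


def fingerprint_dataset(
    ds: LabeledDataset, cfg: FingerprintConfig = FingerprintConfig()
) -> FingerprintMatrix:
    """Fingerprint every record of a dataset, keyed by canonical SMILES.

    Canonical SMILES is the natural key here: it is unique within a
    ``LabeledDataset`` by construction, while user compound ids need not be.
    """
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=cfg.radius, fpSize=cfg.n_bits)
    bits = np.zeros((len(ds), cfg.n_bits), dtype=np.uint8)
    for i, (rec, _) in enumerate(ds):
        bits[i] = gen.GetFingerprintAsNumPy(_mol(rec))
    return FingerprintMatrix(list(ds.smiles), bits, cfg)


def tanimoto(a: np.ndarray, b: np.ndarray) -> float:
    """Tanimoto (Jaccard) similarity of two equal-length bit vectors.

    Defined as 0 when both vectors are all-zero.
    """
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.shape} vs {b.shape}")
    union = np.logical_or(a, b).sum()
    if union == 0:
        return 0.0
    return float(np.logical_and(a, b).sum() / union)


def bulk_tanimoto(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Pairwise Tanimoto matrix between the rows of A (n×d) and B (m×d)."""
    A = np.asarray(A, dtype=np.float64)
    B = np.asarray(B, dtype=np.float64)
    if A.shape[1] != B.shape[1]:
        raise ValueError("fingerprint lengths differ")
    inter = A @ B.T
    pop_a = A.sum(axis=1)[:, None]
    pop_b = B.sum(axis=1)[None, :]
    union = pop_a + pop_b - inter
    with np.errstate(divide="ignore", invalid="ignore"):
        sim = np.where(union > 0, inter / union, 0.0)
    return sim


def physchem_descriptors(record: CompoundRecord | str) -> DescriptorProfile:
    """Six descriptors used to profile class property distributions:
    molecular weight, logP, ring count, rotatable bonds, H-bond donors and
    acceptors."""
    mol = _mol(record)
    return DescriptorProfile(
        molecular_weight=float(Descriptors.MolWt(mol)),
        logp=float(Descriptors.MolLogP(mol)),
        n_rings=int(Descriptors.RingCount(mol)),
        n_rotatable_bonds=int(Descriptors.NumRotatableBonds(mol)),
        n_hbd=int(Descriptors.NumHDonors(mol)),
        n_hba=int(Descriptors.NumHAcceptors(mol)),
    )


def descriptor_table(records: Iterable[CompoundRecord]) -> pd.DataFrame:
    rows = []
    for rec in records:
        p = physchem_descriptors(rec)
        rows.append(
            {
                "compound_id": rec.compound_id,
                "canonical_smiles": rec.canonical_smiles,
                "molecular_weight": p.molecular_weight,
                "logp": p.logp,
                "n_rings": p.n_rings,
                "n_rotatable_bonds": p.n_rotatable_bonds,
                "n_hbd": p.n_hbd,
                "n_hba": p.n_hba,
            }
        )
    return pd.DataFrame(rows)
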