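"""Seeded two-class SMILES dataset generator for end-to-end testing.

Real bioactivity extracts cannot be bundled, so this module fabricates
datasets with the *shape* of public dose-response data:

* a configurable active:inactive imbalance;
* scaffold-family structure — each molecule is a ring core (a single ring
  or two linked rings) decorated with substituents, so Bemis–Murcko
  scaffolds group molecules into families with heavy-tailed (Zipf) sizes,
  the way real scaffold populations look;
* a class signal carried by chemistry: active families are built from one
  ring pool (benzene / pyridine / indole), inactive families from another
  (piperidine / pyrimidine / cyclohexane), so a model can generalize to an
  unseen family through shared ring chemistry while a scaffold split still
  withholds whole families;
* an adjustable family↔label correlation (``cross_family_mixing``), and
* an optional inversely imbalanced "HTS-like" test set.

Everything is grammar-constructed, so every emitted SMILES is valid and
unique, and fully reproducible from the seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations_with_replacement
from math import comb
from typing import Sequence

import numpy as np
from rdkit import Chem

from .datatypes import ACTIVE, INACTIVE, CompoundRecord, LabeledDataset, RawBioactivity

ACTIVE_RINGS: tuple[str, ...] = ("c1ccccc1", "c1ccncc1", "c1ccc2cc[nH]c2c1")
INACTIVE_RINGS: tuple[str, ...] = ("C1CCNCC1", "c1cncnc1", "C1CCCCC1")

#: Linkers joining two rings ("" = direct bond).
LINKERS: tuple[str, ...] = ("", "C", "CC", "O", "N")

SUBSTITUENTS: tuple[str, ...] = (
    "C", "CC", "CCC", "C(C)C", "O", "OC", "N", "F", "Cl", "Br", "C#N", "CO",
)

#: Fraction of scaffold families assigned to the active-dominant side.
_ACTIVE_FAMILY_SHARE = 0.75


@dataclass(frozen=True)
class SyntheticSpec:
    """Study conditions for one synthetic dataset.

    ``cross_family_mixing`` is the fraction of inactives drawn from
    active-dominant scaffold families: 0 gives perfectly family-pure
    classes, 0.5 destroys most of the scaffold–label signal.
    """

    n_active: int
    n_inactive: int
    n_scaffold_families: int = 6
    cross_family_mixing: float = 0.1
    seed: int = 0
    hts_test: bool = False
    hts_n_active: int = 6
    hts_n_inactive: int = 450  # ≈75:1 inactive:active, HTS-like

    def __post_init__(self) -> None:
        if self.n_active < 1 or self.n_inactive < 1:
            raise ValueError("class counts must be >= 1")
        if not 0.0 <= self.cross_family_mixing <= 1.0:
            raise ValueError("cross_family_mixing must be in [0, 1]")
        n_act, n_inact = _family_partition(self.n_scaffold_families)
        n_available = len(_enumerate_cores(ACTIVE_RINGS))
        if n_act < 1 or n_inact < 1:
            raise ValueError("need at least one family per class")
        if n_act > n_available or n_inact > n_available:
            raise ValueError(
                f"at most {2 * n_available} scaffold families are available"
            )


def benchmark_spec(seed: int, hts_test: bool = False) -> SyntheticSpec:
    """The standard synthetic benchmark: 8:1 active:inactive imbalance with
    a rich scaffold-family population (22 families), mirroring the shape of
    public dose-response extracts."""
    return SyntheticSpec(
        n_active=400,
        n_inactive=50,
        n_scaffold_families=22,
        cross_family_mixing=0.1,
        seed=seed,
        hts_test=hts_test,
    )


def _family_partition(n_families: int) -> tuple[int, int]:
    n_act = max(1, round(_ACTIVE_FAMILY_SHARE * n_families))
    return n_act, n_families - n_act


def _enumerate_cores(
    rings: Sequence[str], partners: Sequence[str] | None = None
) -> list[tuple[str, str, str]]:
    """Deterministic core list: single rings first, then linked pairs.

    ``partners`` extends the second ring of each pair beyond the class's
    own pool — used so inactive families also carry active-pool rings,
    which makes the classes share substructure the way real bioactivity
    classes do.
    """
    cores: list[tuple[str, str, str]] = [(r, "", "") for r in rings]
    pool = list(rings) + [r for r in (partners or ()) if r not in rings]
    for linker in LINKERS:
        pairs = {tuple(sorted((a, b))) for a in rings for b in pool}
        for a, b in sorted(pairs):
            cores.append((a, b, linker))
    return cores


def _ring_positions(mol: Chem.Mol) -> list[int]:
    return [
        a.GetIdx()
        for a in mol.GetAtoms()
        if a.GetSymbol() == "C" and a.GetTotalNumHs() >= 1 and a.IsInRing()
    ]


def _attach(mol: Chem.RWMol, at: int, frag: Chem.Mol) -> Chem.RWMol:
    offset = mol.GetNumAtoms()
    out = Chem.RWMol(Chem.CombineMols(mol, frag))
    out.AddBond(at, offset, Chem.BondType.SINGLE)
    return out


class _FamilyGrammar:
    """One scaffold family: a (possibly linked two-ring) core decorated
    with 1–3 substituents at free ring positions."""

    def __init__(self, core_def: tuple[str, str, str]):
        ring_a, ring_b, linker = core_def
        mol = Chem.RWMol(Chem.MolFromSmiles(ring_a))
        if ring_b:
            pos_a = _ring_positions(mol)[0]
            if linker:
                link = Chem.MolFromSmiles(linker)
                n_link = link.GetNumAtoms()
                at_b = mol.GetNumAtoms() + n_link - 1
                mol = _attach(mol, pos_a, link)
                offset = mol.GetNumAtoms()
                mol = Chem.RWMol(Chem.CombineMols(mol, Chem.MolFromSmiles(ring_b)))
                b_pos = _ring_positions(Chem.MolFromSmiles(ring_b))[0]
                mol.AddBond(at_b, offset + b_pos, Chem.BondType.SINGLE)
            else:
                offset = mol.GetNumAtoms()
                mol = Chem.RWMol(Chem.CombineMols(mol, Chem.MolFromSmiles(ring_b)))
                b_pos = _ring_positions(Chem.MolFromSmiles(ring_b))[0]
                mol.AddBond(pos_a, offset + b_pos, Chem.BondType.SINGLE)
        core = mol.GetMol()
        Chem.SanitizeMol(core)
        self.core = core
        self.core_smiles = Chem.MolToSmiles(core)
        self.positions = _ring_positions(core)
        self.frags = [Chem.MolFromSmiles(s) for s in SUBSTITUENTS]

    def capacity(self) -> int:
        p, s = len(self.positions), len(SUBSTITUENTS)
        return sum(comb(p, k) * s**k for k in (1, 2, 3))

    def sample(self, rng: np.random.Generator) -> str:
        n_sub = min(int(rng.integers(1, 4)), len(self.positions))
        chosen = rng.choice(len(self.positions), size=n_sub, replace=False)
        mol = Chem.RWMol(self.core)
        for p in sorted(int(c) for c in chosen):
            frag = self.frags[int(rng.integers(0, len(SUBSTITUENTS)))]
            mol = _attach(mol, self.positions[p], frag)
        out = mol.GetMol()
        Chem.SanitizeMol(out)
        return Chem.MolToSmiles(out)


def _zipf_weights(n: int) -> np.ndarray:
    w = 1.0 / np.arange(1, n + 1)
    return w / w.sum()


def _build_grammars(spec: SyntheticSpec) -> tuple[list[_FamilyGrammar], list[_FamilyGrammar]]:
    n_act, n_inact = _family_partition(spec.n_scaffold_families)
    act = [_FamilyGrammar(c) for c in _enumerate_cores(ACTIVE_RINGS)[:n_act]]
    inact = [_FamilyGrammar(c) for c in _enumerate_cores(INACTIVE_RINGS)[:n_inact]]
    return act, inact


def _sample_one(
    grammar: _FamilyGrammar, rng: np.random.Generator, taken: set[str]
) -> str:
    for _ in range(5000):
        smi = grammar.sample(rng)
        if smi not in taken:
            taken.add(smi)
            return smi
    raise ValueError(
        f"scaffold family {grammar.core_smiles!r} exhausted "
        f"(capacity {grammar.capacity()}); request fewer compounds"
    )


def generate_dataset(
    spec: SyntheticSpec,
) -> tuple[LabeledDataset, LabeledDataset | None]:
    """Generate a labelled dataset (and optionally an HTS-like test set).

    Actives are drawn from active-dominant families, inactives from
    inactive-dominant families except for a ``cross_family_mixing``
    fraction; family sizes follow a Zipf profile within each class, giving
    the heavy-tailed scaffold population a scaffold splitter needs.
    """
    rng = np.random.default_rng(spec.seed)
    act_g, inact_g = _build_grammars(spec)
    w_act, w_inact = _zipf_weights(len(act_g)), _zipf_weights(len(inact_g))
    taken: set[str] = set()

    def build(n_act: int, n_inact: int, prefix: str) -> LabeledDataset:
        records: list[tuple[CompoundRecord, str]] = []
        for i in range(n_act):
            g = act_g[int(rng.choice(len(act_g), p=w_act))]
            smi = _sample_one(g, rng, taken)
            records.append(
                (CompoundRecord(smi, f"{prefix}A{i:05d}", "synthetic"), ACTIVE)
            )
        for i in range(n_inact):
            if rng.random() < spec.cross_family_mixing:
                g = act_g[int(rng.choice(len(act_g), p=w_act))]
            else:
                g = inact_g[int(rng.choice(len(inact_g), p=w_inact))]
            smi = _sample_one(g, rng, taken)
            records.append(
                (CompoundRecord(smi, f"{prefix}I{i:05d}", "synthetic"), INACTIVE)
            )
        return LabeledDataset(records)

    main = build(spec.n_active, spec.n_inactive, "SYN-")
    hts = None
    if spec.hts_test:
        hts = build(spec.hts_n_active, spec.hts_n_inactive, "HTS-")
    return main, hts


@dataclass(frozen=True)
class ValueRanges:
    """Log-uniform potency ranges (µM) used to attach bioactivity values."""

    active_uM: tuple[float, float] = (0.01, 1.0)
    inactive_uM: tuple[float, float] = (10.0, 100.0)
    ambiguous_uM: tuple[float, float] = (1.0, 10.0)
    ambiguous_fraction: float = 0.0
    censored_inactive_fraction: float = 0.2  # reported as "> value"

    def __post_init__(self) -> None:
        for lo, hi in (self.active_uM, self.inactive_uM, self.ambiguous_uM):
            if lo >= hi:
                raise ValueError(f"inverted range ({lo}, {hi})")
        if not 0 <= self.ambiguous_fraction <= 1:
            raise ValueError("ambiguous_fraction must be in [0, 1]")


def generate_bioactivities(
    spec: SyntheticSpec, ranges: ValueRanges = ValueRanges()
) -> list[RawBioactivity]:
    """Attach seeded measurement rows to a synthetic dataset.

    Each compound gets one EC50/IC50/Ki row with a log-uniform value in its
    class range (or, with probability ``ambiguous_fraction``, in the
    ambiguous band between the cutoffs).  A fraction of inactives is
    reported as a censored ">" bound, as is common for public inactives.
    Units alternate between nM and µM to exercise unit conversion downstream.
    """
    ds, _ = generate_dataset(spec)
    rng = np.random.default_rng(spec.seed + 1)
    rows: list[RawBioactivity] = []

    def loguniform(lo: float, hi: float) -> float:
        return float(np.exp(rng.uniform(np.log(lo), np.log(hi))))

    for rec, label in ds:
        atype = RawBioactivity.ACTIVITY_TYPES[int(rng.integers(0, 3))]
        relation = "="
        if rng.random() < ranges.ambiguous_fraction:
            value = loguniform(*ranges.ambiguous_uM)
        elif label == ACTIVE:
            value = loguniform(*ranges.active_uM)
        else:
            value = loguniform(*ranges.inactive_uM)
            if rng.random() < ranges.censored_inactive_fraction:
                relation = ">"
        if rng.random() < 0.5:
            value, unit = value * 1000.0, "nM"
        else:
            unit = "uM"
        rows.append(
            RawBioactivity(
                compound_id=rec.compound_id,
                smiles=rec.canonical_smiles,
                activity_type=atype,
                relation=relation,
                value=value,
                unit=unit,
            )
        )
    return rows
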