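"""Class-overlap analysis as the inactive cutoff varies.

With a fixed active cutoff, sweeping the inactive cutoff upward shrinks the
inactive class (the sets are nested) and, with it, the number of actives
that closely resemble an inactive.  "Closely resemble" means a maximum
Tanimoto similarity above a threshold (default 0.5) in the same fingerprint
space used for modelling.  The scan reports, per candidate cutoff, the
class sizes and the overlap count; choosing the cutoff is left to the user.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .curation import (
    CurationConfig,
    Rejection,
    curate_bioactivities,
    label_activity,
    standardize_smiles,
)
from .datatypes import ACTIVE, INACTIVE, CompoundRecord, RawBioactivity
from .featurize import (
    FingerprintConfig,
    FingerprintMatrix,
    bulk_tanimoto,
    fingerprint_dataset,
    fingerprint_records,
)


@dataclass(frozen=True)
class CutoffScanRow:
    active_cutoff_uM: float
    inactive_cutoff_uM: float
    n_active: int
    n_inactive: int
    n_overlap: int
    n_overlap_pre_dedup: int  # overlap measured before cross-class removal

    def __post_init__(self) -> None:
        if self.n_overlap > self.n_active:
            raise ValueError("overlap count cannot exceed the active count")


def max_similarity_overlap(
    actives: FingerprintMatrix, inactives: FingerprintMatrix, threshold: float = 0.5
) -> int:
    """Number of actives whose maximum Tanimoto similarity to any inactive
    strictly exceeds ``threshold``."""
    if actives.config != inactives.config:
        raise ValueError("fingerprint configs differ between the two sets")
    if not 0 < threshold < 1:
        raise ValueError("threshold must be in (0, 1)")
    if len(actives) == 0 or len(inactives) == 0:
        return 0
    max_sim = bulk_tanimoto(actives.bits, inactives.bits).max(axis=1)
    return int((max_sim > threshold).sum())


def _pre_dedup_classes(
    bioactivities: Sequence[RawBioactivity], cfg: CurationConfig
) -> tuple[list[CompoundRecord], list[CompoundRecord]]:
    """Per-class unique records *before* cross-class conflict removal."""
    by_class: dict[str, dict[str, CompoundRecord]] = {ACTIVE: {}, INACTIVE: {}}
    for b in bioactivities:
        rec = standardize_smiles(b.smiles, compound_id=b.compound_id)
        if isinstance(rec, Rejection):
            continue
        label = label_activity(b, cfg)
        if label in by_class:
            by_class[label].setdefault(rec.canonical_smiles, rec)
    return list(by_class[ACTIVE].values()), list(by_class[INACTIVE].values())


def cutoff_scan(
    bioactivities: Sequence[RawBioactivity],
    active_cutoff: float = 1.0,
    inactive_cutoffs: Sequence[float] = tuple(range(2, 11)),
    threshold: float = 0.5,
    fp_config: FingerprintConfig = FingerprintConfig(),
) -> list[CutoffScanRow]:
    """Relabel, deduplicate, fingerprint and count overlap per cutoff.

    The full curation (including cross-class conflict removal) is re-run
    for every cutoff, since changing the cutoff changes which compounds
    conflict; the overlap before conflict removal is reported alongside.
    """
    cutoffs = list(inactive_cutoffs)
    if any(c < active_cutoff for c in cutoffs):
        raise ValueError("every inactive cutoff must be >= the active cutoff")
    if cutoffs != sorted(cutoffs):
        raise ValueError("inactive_cutoffs must be sorted ascending")

    rows = []
    for cutoff in cutoffs:
        cfg = CurationConfig(active_cutoff_uM=active_cutoff, inactive_cutoff_uM=cutoff)
        ds, _log = curate_bioactivities(bioactivities, cfg)
        fps = fingerprint_dataset(ds, fp_config)
        act_idx = [i for i, l in enumerate(ds.labels) if l == ACTIVE]
        inact_idx = [i for i, l in enumerate(ds.labels) if l == INACTIVE]
        overlap = max_similarity_overlap(
            fps.select(act_idx), fps.select(inact_idx), threshold
        )

        pre_act, pre_inact = _pre_dedup_classes(bioactivities, cfg)
        if pre_act and pre_inact:
            pre_overlap = max_similarity_overlap(
                fingerprint_records(pre_act, fp_config),
                fingerprint_records(pre_inact, fp_config),
                threshold,
            )
        else:
            pre_overlap = 0

        rows.append(
            CutoffScanRow(
                active_cutoff_uM=active_cutoff,
                inactive_cutoff_uM=cutoff,
                n_active=len(act_idx),
                n_inactive=len(inact_idx),
                n_overlap=overlap,
                n_overlap_pre_dedup=pre_overlap,
            )
        )
    return rows


def scan_table(rows: Sequence[CutoffScanRow]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in rows])
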