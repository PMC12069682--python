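import numpy as np
import pytest

from molbalance import (
    FingerprintConfig,
    FingerprintMatrix,
    LabeledDataset,
    SyntheticSpec,
    fingerprint_dataset,
    generate_dataset,
)
from molbalance.datatypes import ACTIVE, INACTIVE, CompoundRecord


@pytest.fixture(scope="session")
def small_dataset() -> LabeledDataset:
    """A 60:20 two-class synthetic dataset shared across tests."""
    ds, _ = generate_dataset(SyntheticSpec(60, 20, n_scaffold_families=8, seed=11))
    return ds


@pytest.fixture(scope="session")
def small_fps(small_dataset):
    return fingerprint_dataset(small_dataset)


@pytest.fixture()
def tiny_fp_config() -> FingerprintConfig:
    return FingerprintConfig(n_bits=64)


def make_fp_matrix(rows, config=None, ids=None) -> FingerprintMatrix:
    """Hand-built fingerprint matrix from on-bit index lists."""
    config = config or FingerprintConfig(n_bits=64)
    bits = np.zeros((len(rows), config.n_bits), dtype=np.uint8)
    for i, on in enumerate(rows):
        bits[i, list(on)] = 1
    ids = ids or [f"c{i}" for i in range(len(rows))]
    return FingerprintMatrix(ids, bits, config)


def make_dataset(actives, inactives) -> LabeledDataset:
    """Dataset from raw SMILES-like strings (no chemistry required)."""
    recs = [(CompoundRecord(s, s), ACTIVE) for s in actives]
    recs += [(CompoundRecord(s, s), INACTIVE) for s in inactives]
    return LabeledDataset(recs)
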