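"""Butina clustering, centroid augmentation, and classical resamplers."""

import numpy as np
import pytest

from molbalance import augment_dataset, cluster_compounds, cluster_to_target, traditional_resample
from molbalance.augmentation import select_centroids
from molbalance.datatypes import ACTIVE, INACTIVE, CompoundRecord, LabeledDataset
from molbalance.featurize import bulk_tanimoto

from .conftest import make_dataset, make_fp_matrix


def brute_force_butina(bits, ids, cutoff):
    """Literal sphere-exclusion transcription used as an oracle."""
    n = len(ids)
    sim = bulk_tanimoto(bits, bits)
    neighbors = {
        i: {j for j in range(n) if j != i and 1 - sim[i, j] <= cutoff} for i in range(n)
    }
    order = sorted(range(n), key=lambda i: (-len(neighbors[i]), ids[i]))
    assigned = set()
    clusters = []
    for i in order:
        if i in assigned:
            continue
        members = [i] + [j for j in sorted(neighbors[i]) if j not in assigned]
        assigned.update(members)
        clusters.append((ids[i], [ids[j] for j in members]))
    return clusters


class TestButina:
    def test_all_identical_one_cluster(self):
        fps = make_fp_matrix([{1, 2}] * 4)
        result = cluster_compounds(fps, 0.6)
        assert result.n_clusters == 1
        assert set(result.assignment.values()) == {0}

    def test_all_distant_all_singletons(self):
        fps = make_fp_matrix([{1}, {2}, {3}, {4}])
        result = cluster_compounds(fps, 0.6)
        assert result.n_clusters == 4
        assert set(result.centroids) == set(fps.ids)

    def test_two_group_hand_fixture(self):
        # group 1: three near-identical vectors; group 2: two identical,
        # far from group 1.  Centroids are the max-degree members.
        rows = [
            {1, 2, 3, 4},      # c0: sim to c1 = 4/5, to c2 = 4/5
            {1, 2, 3, 4, 5},   # c1: superset
            {1, 2, 3, 4, 6},   # c2
            {40, 41, 42},      # c3: identical to c4
            {40, 41, 42},      # c4
        ]
        fps = make_fp_matrix(rows)
        result = cluster_compounds(fps, 0.6)
        oracle = brute_force_butina(fps.bits, fps.ids, 0.6)
        assert result.n_clusters == len(oracle) == 2
        assert list(result.centroids) == [c for c, _ in oracle]
        for centroid, members in oracle:
            cid = result.assignment[centroid]
            assert {m for m, c in result.assignment.items() if c == cid} == set(members)

    def test_partition_and_coverage_invariants_match_oracle(self):
        rng = np.random.default_rng(0)
        for trial in range(20):
            n = int(rng.integers(5, 25))
            bits = (rng.random((n, 64)) < 0.25).astype(np.uint8)
            fps = make_fp_matrix([set(np.nonzero(r)[0]) for r in bits])
            result = cluster_compounds(fps, 0.55)
            # partition: every compound exactly once
            assert sorted(result.assignment) == sorted(fps.ids)
            assert result.n_clusters == len(set(result.assignment.values()))
            # centroid in own cluster
            for k, c in enumerate(result.centroids):
                assert result.assignment[c] == k
            # oracle agreement
            oracle = brute_force_butina(fps.bits, fps.ids, 0.55)
            assert list(result.centroids) == [c for c, _ in oracle]

    def test_coverage_guarantee(self):
        rng = np.random.default_rng(7)
        bits = (rng.random((30, 64)) < 0.2).astype(np.uint8)
        fps = make_fp_matrix([set(np.nonzero(r)[0]) for r in bits])
        result = cluster_compounds(fps, 0.7)
        sim = bulk_tanimoto(fps.bits, fps.bits)
        idx = {cid: i for i, cid in enumerate(fps.ids)}
        for compound, cluster in result.assignment.items():
            centroid = result.centroids[cluster]
            if compound != centroid:
                assert 1 - sim[idx[compound], idx[centroid]] <= 0.7

    def test_cutoff_validation(self):
        fps = make_fp_matrix([{1}])
        with pytest.raises(ValueError):
            cluster_compounds(fps, 1.5)

    def test_cluster_to_target_bisection(self):
        rng = np.random.default_rng(3)
        bits = (rng.random((40, 64)) < 0.25).astype(np.uint8)
        fps = make_fp_matrix([set(np.nonzero(r)[0]) for r in bits])
        result, cutoff = cluster_to_target(fps, 10, tol=2)
        assert abs(result.n_clusters - 10) <= 2
        assert 0 < cutoff < 1


class TestAugmentDataset:
    def test_no_additions_identity(self, small_dataset):
        out, log = augment_dataset(small_dataset, [], INACTIVE)
        assert out == small_dataset
        assert log["n_dropped"] == 0

    def test_duplicate_inactive_is_dropped(self):
        base = make_dataset(["a1"], ["i1"])
        out, _ = augment_dataset(base, [CompoundRecord("i1", "gen0", "generated")], INACTIVE)
        assert out.to_frame()["canonical_smiles"].tolist() == ["a1", "i1"]

    def test_collision_with_active_removes_both(self):
        base = make_dataset(["a1", "a2"], ["i1"])
        out, log = augment_dataset(base, [CompoundRecord("a1", "gen0", "generated")], INACTIVE)
        assert "a1" not in out.smiles_set()
        assert log["n_dropped"] == 2

    def test_counts_at_published_scale(self):
        """275 base inactives + 1,604 collision-free centroids → 1,879."""
        base = make_dataset(
            [f"act{i}" for i in range(1844)], [f"inact{i}" for i in range(275)]
        )
        additions = [CompoundRecord(f"gen{i}", f"g{i}", "generated") for i in range(1604)]
        out, _ = augment_dataset(base, additions, INACTIVE)
        assert out.n_inactives == 1879
        assert out.n_actives == 1844

    def test_source_flag_on_additions(self):
        base = make_dataset(["a1"], ["i1"])
        out, _ = augment_dataset(base, [CompoundRecord("i2", "g", "generated")], INACTIVE)
        by_smiles = {r.canonical_smiles: r.source for r, _ in out}
        assert by_smiles["i2"] == "generated"


class TestSelectCentroids:
    def test_returns_real_members(self):
        records = [CompoundRecord(f"s{i}", f"c{i}") for i in range(4)]
        fps = make_fp_matrix([{1, 2}, {1, 2}, {9}, {10}], ids=[r.compound_id for r in records])
        centroids = select_centroids(records, fps, 0.6)
        assert {c.compound_id for c in centroids} <= {r.compound_id for r in records}
        assert len(centroids) == 3


class TestTraditionalResample:
    def _imbalanced(self, n_major=60, n_minor=12, seed=0):
        rng = np.random.default_rng(seed)
        X = (rng.random((n_major + n_minor, 32)) < 0.3).astype(float)
        X[:n_major, :4] = 1.0  # majority signature
        X[n_major:, 4:8] = 1.0  # minority signature
        y = np.array([1] * n_major + [0] * n_minor)
        return X, y

    def test_enn_only_removes(self):
        X, y = self._imbalanced()
        Xr, yr = traditional_resample(X, y, "enn", seed=1)
        assert len(yr) <= len(y)
        assert (yr == 0).sum() == (y == 0).sum()  # minority untouched

    def test_smote_enn_oversamples_minority(self):
        X, y = self._imbalanced()
        Xr, yr = traditional_resample(X, y, "smote_enn", seed=1)
        assert (yr == 0).sum() > (y == 0).sum()

    def test_ksmote_moves_toward_balance(self):
        X, y = self._imbalanced()
        Xr, yr = traditional_resample(X, y, "ksmote", seed=1)
        assert (yr == 0).sum() == (yr == 1).sum()

    def test_outputs_binarized(self):
        X, y = self._imbalanced()
        for method in ("smote_enn", "ksmote"):
            Xr, _ = traditional_resample(X, y, method, seed=2)
            assert set(np.unique(Xr)) <= {0.0, 1.0}

    def test_determinism(self):
        X, y = self._imbalanced()
        a = traditional_resample(X, y, "smote_enn", seed=3)
        b = traditional_resample(X, y, "smote_enn", seed=3)
        assert np.array_equal(a[0], b[0]) and np.array_equal(a[1], b[1])

    def test_small_minority_rejected_with_requirement_named(self):
        X, y = self._imbalanced(n_minor=4)
        with pytest.raises(ValueError, match="neighbour"):
            traditional_resample(X, y, "smote_enn", seed=0)

    def test_unknown_method(self):
        X, y = self._imbalanced()
        with pytest.raises(ValueError, match="unknown method"):
            traditional_resample(X, y, "adasyn", seed=0)
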