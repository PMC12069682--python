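"""Minority-class augmentation and classical resampling comparators.

Generated molecules are not added wholesale: they are clustered by
sphere-exclusion (Butina) clustering on Tanimoto distance and only the
cluster centroids — real, valid molecules — join the training set, which
caps redundancy and keeps the additions structurally diverse.

For comparison, the classical feature-space resamplers are provided behind
the same interface: ENN undersampling, SMOTE-ENN, and k-means-guided SMOTE.
These operate on fingerprint vectors (synthetic points are binarized at 0.5)
and produce no molecules, only feature rows.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .curation import deduplicate
from .datatypes import ACTIVE, INACTIVE, CompoundRecord, LabeledDataset
from .featurize import FingerprintMatrix, bulk_tanimoto

logger = logging.getLogger(__name__)

RESAMPLE_METHODS = ("enn", "smote_enn", "ksmote")


@dataclass(frozen=True)
class ClusterResult:
    assignment: Mapping[str, int]  # compound id -> cluster id
    centroids: tuple[str, ...]  # one compound id per cluster

    @property
    def n_clusters(self) -> int:
        return len(self.centroids)


def cluster_compounds(fps: FingerprintMatrix, distance_cutoff: float = 0.6) -> ClusterResult:
    """Butina sphere-exclusion clustering on Tanimoto distance.

    Neighbours are pairs at distance (1 − similarity) ≤ cutoff.  Compounds
    are visited in order of decreasing neighbour count (ties broken by
    compound id); each unassigned compound founds a cluster absorbing its
    unassigned neighbours, and the founder is the centroid.  Deterministic.
    """
    if len(fps) == 0:
        raise ValueError("no compounds to cluster")
    if not 0 < distance_cutoff < 1:
        raise ValueError("distance_cutoff must be in (0, 1)")
    n = len(fps)
    sim = bulk_tanimoto(fps.bits, fps.bits)
    within = (1.0 - sim) <= distance_cutoff
    np.fill_diagonal(within, False)
    neighbor_count = within.sum(axis=1)
    order = sorted(range(n), key=lambda i: (-int(neighbor_count[i]), fps.ids[i]))

    assignment: dict[str, int] = {}
    centroids: list[str] = []
    assigned = np.zeros(n, dtype=bool)
    for i in order:
        if assigned[i]:
            continue
        cluster_id = len(centroids)
        centroids.append(fps.ids[i])
        members = [i] + [j for j in np.nonzero(within[i])[0] if not assigned[j]]
        for j in members:
            assigned[j] = True
            assignment[fps.ids[j]] = cluster_id
    return ClusterResult(assignment=assignment, centroids=tuple(centroids))


def cluster_to_target(
    fps: FingerprintMatrix,
    target_n_clusters: int,
    tol: int = 0,
    max_iter: int = 40,
) -> tuple[ClusterResult, float]:
    """Bisection on the distance cutoff toward a requested cluster count.

    Cluster count is a step function of the cutoff, so the exact target may
    be unattainable; the closest achieved clustering is returned along with
    the cutoff used.
    """
    lo, hi = 1e-6, 1.0 - 1e-6
    best = None
    best_gap = None
    for _ in range(max_iter):
        mid = (lo + hi) / 2
        res = cluster_compounds(fps, mid)
        gap = abs(res.n_clusters - target_n_clusters)
        if best is None or gap < best_gap:
            best, best_gap, best_cutoff = res, gap, mid
        if gap <= tol:
            return res, mid
        if res.n_clusters > target_n_clusters:
            lo = mid  # larger cutoff -> fewer clusters
        else:
            hi = mid
    return best, best_cutoff


def select_centroids(
    records: Sequence[CompoundRecord], fps: FingerprintMatrix, distance_cutoff: float = 0.6
) -> list[CompoundRecord]:
    """Cluster a set of generated compounds and keep one real molecule
    (the cluster founder) per cluster."""
    result = cluster_compounds(fps, distance_cutoff)
    by_id = {r.compound_id: r for r in records}
    return [by_id[cid] for cid in result.centroids]


def augment_dataset(
    base: LabeledDataset,
    additions: Sequence[CompoundRecord],
    label: str = INACTIVE,
) -> tuple[LabeledDataset, dict]:
    """Append additions under ``label`` and re-apply the dedup rules.

    A generated compound duplicating an existing record of the same class is
    dropped; one colliding with the *other* class triggers the usual
    both-removed conflict handling.  Returns the dataset and a count log.
    """
    if label not in (ACTIVE, INACTIVE):
        raise ValueError(f"label must be active or inactive, got {label!r}")
    records = list(base.records) + [
        (rec.with_source(rec.source if rec.source != "public" else "generated"), label)
        for rec in additions
    ]
    ds = deduplicate(records)
    log = {
        "n_base": len(base),
        "n_additions": len(additions),
        "n_result": len(ds),
        "n_dropped": len(base) + len(additions) - len(ds),
        "n_active": ds.n_actives,
        "n_inactive": ds.n_inactives,
    }
    if log["n_dropped"]:
        logger.info("augmentation dropped %d colliding records", log["n_dropped"])
    return ds, log


# ---------------------------------------------------------------------------
# Classical feature-space resamplers
# ---------------------------------------------------------------------------


def _check_minority(y: np.ndarray, k_needed: int, method: str) -> tuple[int, int]:
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) != 2:
        raise ValueError("resampling requires exactly two classes")
    minority = int(classes[np.argmin(counts)])
    if counts.min() <= k_needed:
        raise ValueError(
            f"{method} needs more than {k_needed} minority samples "
            f"(k-nearest-neighbour requirement); got {int(counts.min())}"
        )
    return minority, int(classes[np.argmax(counts)])


def _enn_mask(X: np.ndarray, y: np.ndarray, target_classes: Sequence[int], k: int = 3) -> np.ndarray:
    """Edited-nearest-neighbour cleaning: drop samples of the target classes
    whose majority vote among their k nearest neighbours disagrees with
    their own label."""
    from sklearn.neighbors import NearestNeighbors

    nn = NearestNeighbors(n_neighbors=k + 1).fit(X)
    _, idx = nn.kneighbors(X)
    keep = np.ones(len(y), dtype=bool)
    for i in range(len(y)):
        if y[i] not in target_classes:
            continue
        votes = y[idx[i, 1:]]
        if np.sum(votes == y[i]) <= k / 2:
            keep[i] = False
    return keep


def _smote(
    X: np.ndarray, y: np.ndarray, minority: int, n_new: int, rng: np.random.Generator, k: int = 5
) -> np.ndarray:
    """Classic SMOTE interpolation between minority neighbours."""
    from sklearn.neighbors import NearestNeighbors

    Xm = X[y == minority]
    nn = NearestNeighbors(n_neighbors=k + 1).fit(Xm)
    _, idx = nn.kneighbors(Xm)
    synth = np.empty((n_new, X.shape[1]))
    for t in range(n_new):
        i = int(rng.integers(0, len(Xm)))
        j = int(idx[i, 1 + rng.integers(0, k)])
        lam = rng.random()
        synth[t] = Xm[i] + lam * (Xm[j] - Xm[i])
    return synth


def traditional_resample(
    X: np.ndarray,
    y: np.ndarray,
    method: str,
    seed: int = 0,
    binarize: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Classical resampling of a fingerprint feature matrix.

    ``enn`` cleans the majority class only (undersampling); ``smote_enn``
    oversamples the minority to parity then ENN-cleans both classes;
    ``ksmote`` clusters the data with k-means, applies SMOTE within
    minority-dominated clusters (allocation weighted toward sparse
    clusters), then balances.  Synthetic interpolated rows are binarized at
    0.5 so downstream classifiers keep seeing binary fingerprints.

    Returns ``(X_resampled, y_resampled)``; synthetic rows have no SMILES.
    """
    if method not in RESAMPLE_METHODS:
        raise ValueError(f"unknown method {method!r}; expected one of {RESAMPLE_METHODS}")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    rng = np.random.default_rng(seed)

    if method == "enn":
        minority, majority = _check_minority(y, 3, method)
        keep = _enn_mask(X, y, target_classes=(majority,))
        return X[keep], y[keep]

    minority, majority = _check_minority(y, 5, method)
    n_deficit = int(np.sum(y == majority) - np.sum(y == minority))

    if method == "smote_enn":
        synth = _smote(X, y, minority, n_deficit, rng)
        if binarize:
            synth = (synth >= 0.5).astype(float)
        X2 = np.vstack([X, synth])
        y2 = np.concatenate([y, np.full(len(synth), minority)])
        keep = _enn_mask(X2, y2, target_classes=(minority, majority))
        return X2[keep], y2[keep]

    # ksmote: cluster, filter to minority-dominated clusters, SMOTE within
    from sklearn.cluster import KMeans

    n_clusters = min(8, max(2, int(np.sum(y == minority)) // 3))
    km = KMeans(n_clusters=n_clusters, random_state=seed, n_init=10).fit(X)
    cluster_ids = km.labels_
    eligible = []
    weights = []
    for c in range(n_clusters):
        mask = cluster_ids == c
        n_min = int(np.sum(y[mask] == minority))
        if n_min < 2 or n_min <= np.sum(y[mask] == majority):
            continue
        Xc = X[mask & (y == minority)]
        # sparsity weight: mean pairwise euclidean distance within cluster
        if len(Xc) > 1:
            d = np.linalg.norm(Xc[:, None, :] - Xc[None, :, :], axis=2)
            sparsity = float(d[np.triu_indices(len(Xc), 1)].mean()) + 1e-9
        else:
            sparsity = 1e-9
        eligible.append(mask & (y == minority))
        weights.append(sparsity)
    if not eligible:
        raise ValueError("ksmote found no minority-dominated cluster to oversample")
    weights = np.asarray(weights) / np.sum(weights)
    alloc = np.floor(weights * n_deficit).astype(int)
    alloc[: n_deficit - alloc.sum()] += 1
    new_rows = []
    for mask, n_new in zip(eligible, alloc):
        if n_new == 0:
            continue
        Xc = X[mask]
        k = min(5, len(Xc) - 1)
        sub_y = np.zeros(len(Xc), dtype=int)  # all minority within cluster
        synth = _smote(Xc, sub_y, 0, int(n_new), rng, k=k)
        new_rows.append(synth)
    synth = np.vstack(new_rows)
    if binarize:
        synth = (synth >= 0.5).astype(float)
    X2 = np.vstack([X, synth])
    y2 = np.concatenate([y, np.full(len(synth), minority)])
    return X2, y2
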