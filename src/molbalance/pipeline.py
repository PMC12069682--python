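"""Modelling pipelines: model kind × imbalance-correction strategy.

A :class:`PipelineSpec` bundles a classifier with one balancing strategy and
knows how to fit itself on a training portion only — the contract the
cross-validation harness relies on to avoid leakage:

* ``none`` — train on the data as-is (the imbalanced baseline);
* ``transfer`` — initialize hidden layers from a source-domain DNN, then
  fine-tune on the target data;
* ``generator_augment`` — add cluster centroids of language-model-generated
  minority compounds to the training portion (anything colliding with the
  held-out fold is dropped first, and the harness asserts none leaks);
* ``enn`` / ``smote_enn`` / ``ksmote`` — classical feature-space resampling
  of the training portion.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .augmentation import augment_dataset, select_centroids, traditional_resample
from .charrnn import CharRNNConfig, filter_generated, train_generator
from .datatypes import ACTIVE, INACTIVE, CompoundRecord, LabeledDataset
from .featurize import FingerprintMatrix, fingerprint_dataset, fingerprint_records
from .models import (
    ClassifierModel,
    DNNConfig,
    TransferSpec,
    fine_tune,
    train_from_arrays,
    transfer_weights,
)

logger = logging.getLogger(__name__)

STRATEGIES = ("none", "transfer", "generator_augment", "enn", "smote_enn", "ksmote")


class LeakageError(RuntimeError):
    pass


@dataclass
class PipelineSpec:
    """One trainable model+strategy combination for the CV harness."""

    model_kind: str = "dnn"
    strategy: str = "none"
    dnn_config: DNNConfig | None = None
    seed: int = 0
    label: str | None = None  # display name; defaults to strategy/kind

    # transfer
    source_model: ClassifierModel | None = None
    transfer_spec: TransferSpec = field(default_factory=TransferSpec)

    # generator augmentation
    generator_pool: Sequence[CompoundRecord] | None = None
    generator_config: CharRNNConfig | None = None
    n_generate: int = 2000
    cluster_cutoff: float = 0.6
    augment_label: str = INACTIVE

    def __post_init__(self) -> None:
        if self.strategy not in STRATEGIES:
            raise ValueError(f"unknown strategy {self.strategy!r}; expected {STRATEGIES}")
        if self.strategy == "transfer" and self.source_model is None:
            raise ValueError("transfer strategy requires a source_model")
        if self.strategy == "generator_augment" and (
            self.generator_pool is None and self.generator_config is None
        ):
            raise ValueError(
                "generator_augment requires a generator_pool or a generator_config"
            )

    @property
    def name(self) -> str:
        return self.label or f"{self.model_kind}+{self.strategy}"

    # ------------------------------------------------------------------
    def _augmented_training_set(
        self,
        train_ds: LabeledDataset,
        train_fps: FingerprintMatrix,
        heldout_smiles: frozenset[str],
    ) -> tuple[LabeledDataset, FingerprintMatrix]:
        corpus = [
            s for s, l in zip(train_ds.smiles, train_ds.labels) if l == self.augment_label
        ]
        other = [
            s for s, l in zip(train_ds.smiles, train_ds.labels) if l != self.augment_label
        ]
        if self.generator_pool is not None:
            pool = list(self.generator_pool)
        else:
            generator = train_generator(corpus, self.generator_config)
            raw = generator.sample(self.n_generate)
            pool = filter_generated(raw, corpus, exclude=other)
        # nothing that appears in the held-out fold (either class) may enter
        pool = [
            r
            for r in pool
            if r.canonical_smiles not in heldout_smiles
            and r.canonical_smiles not in set(corpus) | set(other)
        ]
        if not pool:
            logger.warning("generator pool empty after filtering; no augmentation")
            return train_ds, train_fps
        pool_fps = fingerprint_records(pool, train_fps.config)
        centroids = select_centroids(pool, pool_fps, self.cluster_cutoff)
        augmented, log = augment_dataset(train_ds, centroids, self.augment_label)
        leaked = augmented.smiles_set() & heldout_smiles
        if leaked:
            raise LeakageError(f"augmented set intersects held-out fold: {sorted(leaked)[:3]}")
        logger.info("augmentation: %s", log)
        aug_fps = fingerprint_dataset(augmented, train_fps.config)
        return augmented, aug_fps

    def fit(
        self,
        train_ds: LabeledDataset,
        train_fps: FingerprintMatrix,
        heldout_smiles: frozenset[str] = frozenset(),
    ) -> ClassifierModel:
        fp_cfg = train_fps.config
        dnn_cfg = self.dnn_config or DNNConfig(input_width=fp_cfg.n_bits, seed=self.seed)

        def arrays(ds: LabeledDataset, fps: FingerprintMatrix):
            X = fps.subset_ids(ds.smiles).bits.astype(float)
            y = np.array([1.0 if l == ACTIVE else 0.0 for l in ds.labels])
            return X, y

        if self.strategy == "none":
            X, y = arrays(train_ds, train_fps)
            return train_from_arrays(
                self.model_kind, X, y, fp_cfg, dnn_config=dnn_cfg, seed=self.seed
            )

        if self.strategy == "transfer":
            if self.model_kind != "dnn":
                raise ValueError("transfer strategy applies to the DNN only")
            model = transfer_weights(self.source_model, dnn_cfg, self.transfer_spec)
            train_sub = train_fps.subset_ids(train_ds.smiles)
            return fine_tune(model, train_ds, train_sub)

        if self.strategy == "generator_augment":
            aug_ds, aug_fps = self._augmented_training_set(
                train_ds, train_fps, heldout_smiles
            )
            X, y = arrays(aug_ds, aug_fps)
            return train_from_arrays(
                self.model_kind, X, y, fp_cfg, dnn_config=dnn_cfg, seed=self.seed
            )

        # classical resamplers
        X, y = arrays(train_ds, train_fps)
        Xr, yr = traditional_resample(X, y.astype(int), self.strategy, seed=self.seed)
        return train_from_arrays(
            self.model_kind, Xr, yr, fp_cfg, dnn_config=dnn_cfg, seed=self.seed
        )
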