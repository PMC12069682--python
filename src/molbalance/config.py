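"""Run configuration and end-to-end orchestration.

A :class:`RunConfig` is one YAML document describing a complete experiment:
the data source (a curated CSV or a synthetic-data specification), the
fingerprint/curation/model settings, the strategies to compare, and a
single global seed.  ``run_pipeline`` executes
curate → split → (strategies) → train → evaluate → compare and writes every
artifact plus a manifest (config hash, derived seeds, stage outputs) into
the run directory, so a run can be reproduced exactly from its manifest.

Per-stage seeds are derived from the global seed by hashing the stage name,
so stages are independently reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

from . import __version__
from .charrnn import CharRNNConfig
from .curation import CurationConfig, build_dataset
from .datatypes import INACTIVE, LabeledDataset
from .evaluation import (
    COMPARISON_METRICS,
    EvaluationReport,
    compare_models,
    cross_validate,
    declare_better,
)
from .featurize import FingerprintConfig, fingerprint_dataset
from .models import DNNConfig, TransferSpec, pretrain_source
from .pipeline import STRATEGIES, PipelineSpec
from .splitting import remove_cross_split_duplicates, scaffold_split, stratified_kfold
from .synthetic import SyntheticSpec, generate_dataset

logger = logging.getLogger(__name__)


def derive_seed(global_seed: int, stage: str) -> int:
    """Stable per-stage seed below 2**31."""
    return (int(global_seed) * 1000003 + zlib.crc32(stage.encode())) % (2**31)


@dataclass
class RunConfig:
    seed: int = 0
    out_dir: str = "run"
    # data: either a curated-CSV path or a synthetic spec (exactly one)
    data_path: str | None = None
    synthetic: dict | None = None
    curation: dict = field(default_factory=dict)
    fingerprint: dict = field(default_factory=dict)
    train_fraction: float = 0.8
    cv_folds: int = 10
    dnn: dict = field(default_factory=dict)
    charrnn: dict = field(default_factory=dict)
    transfer: dict = field(default_factory=dict)
    strategies: list = field(default_factory=lambda: ["none"])
    model_kind: str = "dnn"
    n_generate: int = 2000
    cluster_cutoff: float = 0.6
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if (self.data_path is None) == (self.synthetic is None):
            raise ValueError("config must set exactly one of data_path / synthetic")
        unknown = [s for s in self.strategies if s not in STRATEGIES]
        if unknown:
            raise ValueError(f"unknown strategies: {unknown}")

    # -- serialization ---------------------------------------------------
    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        fields = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - fields
        if unknown:
            raise ValueError(f"unknown config field(s): {sorted(unknown)}")
        return cls(**raw)

    def config_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _load_data(cfg: RunConfig) -> tuple[LabeledDataset, LabeledDataset | None]:
    if cfg.data_path is not None:
        path = Path(cfg.data_path)
        try:
            return LabeledDataset.from_csv(path), None
        except KeyError:
            ds, log = build_dataset(path, CurationConfig(**cfg.curation))
            logger.info("curation log: %s", log.as_dict())
            return ds, None
    spec = SyntheticSpec(seed=derive_seed(cfg.seed, "synth"), **cfg.synthetic)
    return generate_dataset(spec)


def run_pipeline(cfg: RunConfig) -> Path:
    """Execute a full experiment; returns the run directory."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {
        "config_hash": cfg.config_hash(),
        "version": __version__,
        "seed": cfg.seed,
        "stages": {},
    }
    stage = "init"
    try:
        stage = "data"
        ds, hts = _load_data(cfg)
        ds.to_csv(out / "dataset.csv")
        manifest["stages"]["data"] = {"n": len(ds), "actives": ds.n_actives}

        stage = "fingerprint"
        fp_cfg = FingerprintConfig(**cfg.fingerprint)
        fps = fingerprint_dataset(ds, fp_cfg)

        stage = "split"
        split = scaffold_split(ds, cfg.train_fraction)
        split = remove_cross_split_duplicates(split, fps)
        split.train.to_csv(out / "train.csv")
        split.test.to_csv(out / "test.csv")
        manifest["stages"]["split"] = {
            "n_train": len(split.train),
            "n_test": len(split.test),
        }

        stage = "folds"
        folds = stratified_kfold(
            split.train, cfg.cv_folds, derive_seed(cfg.seed, "folds")
        )

        stage = "strategies"
        dnn_cfg = DNNConfig(
            input_width=fp_cfg.n_bits, seed=derive_seed(cfg.seed, "dnn"), **cfg.dnn
        )
        source_model = None
        if "transfer" in cfg.strategies:
            # source domain: a larger, more balanced synthetic relative
            src_spec = SyntheticSpec(
                n_active=max(200, len(ds)),
                n_inactive=max(200, len(ds)),
                seed=derive_seed(cfg.seed, "source"),
            )
            src_ds, _ = generate_dataset(src_spec)
            src_fps = fingerprint_dataset(src_ds, fp_cfg)
            source_model = pretrain_source(src_ds, src_fps, dnn_cfg)

        pipelines = []
        for strat in cfg.strategies:
            pipelines.append(
                PipelineSpec(
                    model_kind=cfg.model_kind,
                    strategy=strat,
                    dnn_config=dnn_cfg,
                    seed=derive_seed(cfg.seed, f"strategy-{strat}"),
                    source_model=source_model,
                    transfer_spec=TransferSpec(**cfg.transfer),
                    generator_config=(
                        CharRNNConfig(
                            seed=derive_seed(cfg.seed, "charrnn"), **cfg.charrnn
                        )
                        if strat == "generator_augment"
                        else None
                    ),
                    n_generate=cfg.n_generate,
                    cluster_cutoff=cfg.cluster_cutoff,
                )
            )

        stage = "evaluate"
        external = [("scaffold_test", split.test, fps)]
        if hts is not None:
            hts_fps = fingerprint_dataset(hts, fp_cfg)
            external.append(("hts_test", hts, hts_fps))
        train_fps = fingerprint_dataset(split.train, fp_cfg)
        tables = []
        for pipe in pipelines:
            report = cross_validate(pipe, split.train, train_fps, folds, external)
            tables.append(report.table)
        import pandas as pd

        full = EvaluationReport(table=pd.concat(tables, ignore_index=True))
        full.to_csv(out / "evaluation.csv")
        full.summary().to_csv(out / "summary.csv", index=False)

        stage = "compare"
        comparison: dict[str, Any] = {}
        if len(pipelines) >= 3:
            results = {}
            for metric in COMPARISON_METRICS:
                table, names = full.metric_matrix(metric, surface="cv")
                results[metric] = compare_models(table, names)
                comparison[metric] = results[metric].as_dict()
            verdicts = declare_better(results, alpha=cfg.alpha)
            comparison["significantly_better"] = [
                {"better": a, "than": b} for (a, b), v in verdicts.items() if v
            ]
        (out / "comparison.json").write_text(json.dumps(comparison, indent=2))
        manifest["stages"]["compare"] = {"n_models": len(pipelines)}
    except Exception as e:
        manifest["failed_stage"] = stage
        manifest["error"] = str(e)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {e}") from e

    cfg.to_yaml(out / "config.yaml")
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return out
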