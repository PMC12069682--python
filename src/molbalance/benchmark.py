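"""The standard synthetic benchmark: one seeded end-to-end comparison.

For a given seed this builds the 8:1 synthetic dataset, scaffold-splits it
80:20 (with post-split fingerprint deduplication), then trains and
evaluates three DNN variants on the held-out scaffold-split test set:

* ``baseline`` — trained on the imbalanced data as-is;
* ``generator_augment`` — the training inactives are used as the corpus of
  a small character-level LSTM; sampled molecules are filtered and
  clustered, and the cluster centroids join the training inactives;
* ``transfer`` — hidden-layer weights are pretrained on a larger, balanced
  synthetic source domain and fine-tuned on the target data.

Model sizes here are deliberately compact (hidden layers 128/64, a
single-layer LSTM of width 128) — the benchmark's purpose is the
directional comparison between strategies at desk scale, not absolute
performance.
"""

from __future__ import annotations

from dataclasses import dataclass

from .charrnn import CharRNNConfig
from .datatypes import LabeledDataset
from .evaluation import MetricSet, evaluate_predictions
from .featurize import FingerprintConfig, fingerprint_dataset
from .models import DNNConfig, pretrain_source
from .pipeline import PipelineSpec
from .splitting import SplitResult, remove_cross_split_duplicates, scaffold_split
from .synthetic import SyntheticSpec, benchmark_spec, generate_dataset

FP_CONFIG = FingerprintConfig()


def benchmark_dnn_config(seed: int) -> DNNConfig:
    return DNNConfig(
        input_width=FP_CONFIG.n_bits,
        hidden_widths=(128, 64),
        max_epochs=150,
        early_stop_patience=20,
        seed=seed,
    )


def benchmark_charrnn_config(seed: int) -> CharRNNConfig:
    """Generator sized for a few-dozen-compound minority corpus."""
    return CharRNNConfig(
        n_layers=1,
        hidden_size=128,
        dropout_rate=0.0,
        learning_rate=0.005,
        epochs=300,
        batch_size=32,
        seed=seed,
        max_sample_length=80,
    )


@dataclass(frozen=True)
class BenchmarkResult:
    seed: int
    split: SplitResult
    baseline: MetricSet
    augmented: MetricSet
    transfer: MetricSet

    @property
    def augmentation_improves(self) -> bool:
        return (
            self.augmented.specificity > self.baseline.specificity
            and self.augmented.gmean > self.baseline.gmean
        )


def run_benchmark_seed(seed: int, n_generate: int = 2000) -> BenchmarkResult:
    """Run the three-strategy comparison for one seed."""
    ds, _ = generate_dataset(benchmark_spec(seed))
    fps = fingerprint_dataset(ds, FP_CONFIG)
    split = remove_cross_split_duplicates(scaffold_split(ds, 0.8), fps)
    train, test = split.train, split.test
    train_fps = fps.subset_ids(train.smiles)
    test_fps = fps.subset_ids(test.smiles)
    dnn_cfg = benchmark_dnn_config(seed)

    def evaluate(model) -> MetricSet:
        return evaluate_predictions(test.labels, model.predict_proba(test_fps))

    baseline = PipelineSpec(
        model_kind="dnn", strategy="none", dnn_config=dnn_cfg, seed=seed
    ).fit(train, train_fps)

    augmented = PipelineSpec(
        model_kind="dnn",
        strategy="generator_augment",
        dnn_config=dnn_cfg,
        seed=seed,
        generator_config=benchmark_charrnn_config(seed),
        n_generate=n_generate,
        cluster_cutoff=0.6,
    ).fit(train, train_fps)

    source_ds, _ = generate_dataset(
        SyntheticSpec(
            n_active=400, n_inactive=400, n_scaffold_families=22, seed=seed + 1000
        )
    )
    source_model = pretrain_source(
        source_ds, fingerprint_dataset(source_ds, FP_CONFIG), dnn_cfg
    )
    transferred = PipelineSpec(
        model_kind="dnn",
        strategy="transfer",
        dnn_config=dnn_cfg,
        seed=seed,
        source_model=source_model,
    ).fit(train, train_fps)

    return BenchmarkResult(
        seed=seed,
        split=split,
        baseline=evaluate(baseline),
        augmented=evaluate(augmented),
        transfer=evaluate(transferred),
    )
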