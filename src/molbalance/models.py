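"""Classifiers: the feed-forward DNN, baselines, and weight transfer.

The DNN is a fully connected network over fingerprint bits —
input → 1000 → 500 → 1 by default, ReLU hidden activations, sigmoid
output, dropout 0.25 on each hidden layer, binary cross-entropy trained
with Adam (lr 0.001, batch 64) and early stopping on the training loss
(patience 50).  It is implemented directly on NumPy with explicit weight
matrices, which keeps every parameter inspectable and makes the
transfer-learning mechanism (copying trained hidden layers into a fresh
network) an exact, testable operation.

Baselines (Bernoulli naive Bayes, random forest, gradient boosting) wrap
scikit-learn / XGBoost behind the same ``predict_proba`` contract.
"""

from __future__ import annotations

import json
import pickle
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from .datatypes import ACTIVE, LabeledDataset
from .featurize import FingerprintConfig, FingerprintMatrix

BASELINE_KINDS = ("naive_bayes", "random_forest", "gradient_boosting")
MODEL_KINDS = ("dnn",) + BASELINE_KINDS


@dataclass(frozen=True)
class DNNConfig:
    input_width: int = 1024
    hidden_widths: tuple[int, ...] = (1000, 500)
    dropout_rate: float = 0.25
    learning_rate: float = 0.001
    batch_size: int = 64
    max_epochs: int = 2000
    early_stop_patience: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.dropout_rate < 1:
            raise ValueError("dropout_rate must be in [0, 1)")
        if any(w <= 0 for w in self.hidden_widths) or self.input_width <= 0:
            raise ValueError("layer widths must be positive")
        object.__setattr__(self, "hidden_widths", tuple(self.hidden_widths))


@dataclass(frozen=True)
class TransferSpec:
    """Which hidden layers to copy from the source network.

    ``fine_tune_transferred=False`` freezes the copied layers during
    subsequent training on the target data.
    """

    layers_to_transfer: tuple[int, ...] = (0,)
    fine_tune_transferred: bool = True

    def __post_init__(self) -> None:
        object.__setattr__(self, "layers_to_transfer", tuple(self.layers_to_transfer))


class MLP:
    """Plain-NumPy fully connected binary classifier (ReLU → sigmoid)."""

    def __init__(self, cfg: DNNConfig):
        self.cfg = cfg
        self.rng = np.random.default_rng(cfg.seed)
        widths = [cfg.input_width, *cfg.hidden_widths, 1]
        self.W: list[np.ndarray] = []
        self.b: list[np.ndarray] = []
        for fan_in, fan_out in zip(widths[:-1], widths[1:]):
            # He init for the ReLU layers; the final (sigmoid) layer gets it
            # too — scale only matters up to the loss surface traversed.
            self.W.append(self.rng.normal(0.0, np.sqrt(2.0 / fan_in), (fan_in, fan_out)))
            self.b.append(np.zeros(fan_out))
        self.frozen = [False] * len(self.W)
        self.loss_curve: list[float] = []

    @property
    def n_hidden(self) -> int:
        return len(self.cfg.hidden_widths)

    # -- forward ------------------------------------------------------------
    def _forward(self, X: np.ndarray, dropout_rng: np.random.Generator | None = None):
        """Returns (activations per layer, dropout masks).  Dropout (inverted
        scaling) is applied to hidden activations only when training."""
        acts = [X]
        masks = []
        h = X
        for i, (W, b) in enumerate(zip(self.W, self.b)):
            z = h @ W + b
            if i < self.n_hidden:
                h = np.maximum(z, 0.0)
                if dropout_rng is not None and self.cfg.dropout_rate > 0:
                    keep = 1.0 - self.cfg.dropout_rate
                    mask = (dropout_rng.random(h.shape) < keep) / keep
                    h = h * mask
                    masks.append(mask)
                else:
                    masks.append(None)
            else:
                h = 1.0 / (1.0 + np.exp(-z))  # sigmoid output
            acts.append(h)
        return acts, masks

    def hidden_activation(self, X: np.ndarray, layer: int) -> np.ndarray:
        """Post-ReLU output of one hidden layer (inference mode)."""
        h = np.asarray(X, dtype=float)
        for i in range(layer + 1):
            h = np.maximum(h @ self.W[i] + self.b[i], 0.0)
        return h

    def hidden_preactivation(self, X: np.ndarray, layer: int) -> np.ndarray:
        h = np.asarray(X, dtype=float)
        for i in range(layer):
            h = np.maximum(h @ self.W[i] + self.b[i], 0.0)
        return h @ self.W[layer] + self.b[layer]

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        acts, _ = self._forward(np.asarray(X, dtype=float), dropout_rng=None)
        return acts[-1].ravel()

    # -- training -----------------------------------------------------------
    def fit(self, X: np.ndarray, y: np.ndarray) -> "MLP":
        cfg = self.cfg
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        n = len(X)
        if n == 0:
            raise ValueError("empty training set")

        mW = [np.zeros_like(W) for W in self.W]
        vW = [np.zeros_like(W) for W in self.W]
        mb = [np.zeros_like(b) for b in self.b]
        vb = [np.zeros_like(b) for b in self.b]
        beta1, beta2, eps = 0.9, 0.999, 1e-8
        t = 0
        best = np.inf
        stall = 0
        order_rng = np.random.default_rng(cfg.seed + 1)
        drop_rng = np.random.default_rng(cfg.seed + 2)

        for _epoch in range(cfg.max_epochs):
            order = order_rng.permutation(n)
            epoch_loss = 0.0
            for start in range(0, n, cfg.batch_size):
                idx = order[start : start + cfg.batch_size]
                Xb, yb = X[idx], y[idx]
                acts, masks = self._forward(Xb, dropout_rng=drop_rng)
                p = np.clip(acts[-1].ravel(), 1e-9, 1 - 1e-9)
                epoch_loss += float(
                    -np.sum(yb * np.log(p) + (1 - yb) * np.log(1 - p))
                )
                # backprop: d(BCE)/dz_out = p - y for sigmoid+BCE
                delta = ((p - yb) / len(idx))[:, None]
                grads_W: list[np.ndarray] = [None] * len(self.W)  # type: ignore
                grads_b: list[np.ndarray] = [None] * len(self.b)  # type: ignore
                for i in range(len(self.W) - 1, -1, -1):
                    grads_W[i] = acts[i].T @ delta
                    grads_b[i] = delta.sum(axis=0)
                    if i > 0:
                        delta = delta @ self.W[i].T
                        if masks[i - 1] is not None:
                            delta = delta * masks[i - 1]
                        delta = delta * (acts[i] > 0)
                t += 1
                for i in range(len(self.W)):
                    if self.frozen[i]:
                        continue
                    for g, m, v, param in (
                        (grads_W[i], mW[i], vW[i], self.W[i]),
                        (grads_b[i], mb[i], vb[i], self.b[i]),
                    ):
                        m *= beta1
                        m += (1 - beta1) * g
                        v *= beta2
                        v += (1 - beta2) * g * g
                        m_hat = m / (1 - beta1**t)
                        v_hat = v / (1 - beta2**t)
                        param -= cfg.learning_rate * m_hat / (np.sqrt(v_hat) + eps)
            epoch_loss /= n
            self.loss_curve.append(epoch_loss)
            if epoch_loss < best - 1e-6:
                best = epoch_loss
                stall = 0
            else:
                stall += 1
                if stall >= cfg.early_stop_patience:
                    break
        return self


@dataclass
class ClassifierModel:
    """A trained classifier behind a uniform probability interface."""

    kind: str
    backend: object
    fingerprint_config: FingerprintConfig
    manifest: dict = field(default_factory=dict)

    def predict_proba(self, fps: FingerprintMatrix | np.ndarray) -> np.ndarray:
        if isinstance(fps, FingerprintMatrix):
            if fps.config != self.fingerprint_config:
                raise ValueError(
                    f"fingerprint config mismatch: model {self.fingerprint_config}, "
                    f"input {fps.config}"
                )
            X = fps.bits.astype(float)
        else:
            X = np.asarray(fps, dtype=float)
            if X.shape[1] != self.fingerprint_config.n_bits:
                raise ValueError("fingerprint width mismatch")
        if self.kind == "dnn":
            return self.backend.predict_proba(X)
        return self.backend.predict_proba(X)[:, 1]

    def predict_label(self, fps, threshold: float = 0.5) -> np.ndarray:
        """Hard labels: active iff probability ≥ threshold."""
        return (self.predict_proba(fps) >= threshold).astype(int)


def _training_arrays(ds: LabeledDataset, fps: FingerprintMatrix):
    X = fps.subset_ids(ds.smiles).bits.astype(float)
    y = np.array([1 if l == ACTIVE else 0 for l in ds.labels], dtype=float)
    return X, y


def train_dnn(
    ds: LabeledDataset, fps: FingerprintMatrix, cfg: DNNConfig | None = None
) -> ClassifierModel:
    """Train the feed-forward DNN on a labelled, fingerprinted dataset."""
    cfg = cfg or DNNConfig(input_width=fps.config.n_bits)
    if cfg.input_width != fps.config.n_bits:
        raise ValueError("cfg.input_width must equal fingerprint n_bits")
    X, y = _training_arrays(ds, fps)
    if cfg.max_epochs > 0 and (y.sum() == 0 or y.sum() == len(y)):
        raise ValueError("training set must contain both classes")
    mlp = MLP(cfg).fit(X, y) if cfg.max_epochs > 0 else MLP(cfg)
    return ClassifierModel(
        kind="dnn",
        backend=mlp,
        fingerprint_config=fps.config,
        manifest={
            "kind": "dnn",
            "config": asdict(cfg),
            "n_train": len(ds),
            "n_epochs_run": len(mlp.loss_curve),
            "final_loss": mlp.loss_curve[-1] if mlp.loss_curve else None,
        },
    )


def train_from_arrays(
    kind: str,
    X: np.ndarray,
    y: np.ndarray,
    fp_config: FingerprintConfig,
    dnn_config: DNNConfig | None = None,
    seed: int = 0,
    **hyperparameters,
) -> ClassifierModel:
    """Train any model kind directly from a feature matrix.

    Used when the training rows are not all backed by molecules (e.g. after
    SMOTE-style resampling, whose synthetic points have no SMILES).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if kind == "dnn":
        cfg = dnn_config or DNNConfig(input_width=fp_config.n_bits, seed=seed)
        if cfg.max_epochs > 0 and (y.sum() == 0 or y.sum() == len(y)):
            raise ValueError("training set must contain both classes")
        mlp = MLP(cfg).fit(X, y) if cfg.max_epochs > 0 else MLP(cfg)
        return ClassifierModel(
            kind="dnn",
            backend=mlp,
            fingerprint_config=fp_config,
            manifest={"kind": "dnn", "config": asdict(cfg), "n_train": len(y)},
        )
    if kind not in BASELINE_KINDS:
        raise ValueError(f"unknown model kind {kind!r}; expected one of {MODEL_KINDS}")
    if kind == "naive_bayes":
        from sklearn.naive_bayes import BernoulliNB

        est = BernoulliNB(**hyperparameters)
    elif kind == "random_forest":
        from sklearn.ensemble import RandomForestClassifier

        hyperparameters.setdefault("random_state", seed)
        est = RandomForestClassifier(**hyperparameters)
    else:
        from xgboost import XGBClassifier

        hyperparameters.setdefault("random_state", seed)
        hyperparameters.setdefault("n_jobs", 1)
        hyperparameters.setdefault("eval_metric", "logloss")
        est = XGBClassifier(**hyperparameters)
    est.fit(X, y.astype(int))
    return ClassifierModel(
        kind=kind,
        backend=est,
        fingerprint_config=fp_config,
        manifest={"kind": kind, "hyperparameters": est.get_params(), "n_train": len(y)},
    )


def train_baseline(
    kind: str,
    ds: LabeledDataset,
    fps: FingerprintMatrix,
    seed: int = 0,
    **hyperparameters,
) -> ClassifierModel:
    """Train one of the baseline classifiers with library defaults.

    ``naive_bayes`` → Bernoulli naive Bayes, ``random_forest`` → random
    forest, ``gradient_boosting`` → XGBoost.  Hyperparameter overrides are
    passed through and recorded in the model manifest.
    """
    if kind not in BASELINE_KINDS:
        raise ValueError(f"unknown baseline kind {kind!r}; expected one of {BASELINE_KINDS}")
    X, y = _training_arrays(ds, fps)
    return train_from_arrays(kind, X, y, fps.config, seed=seed, **hyperparameters)


def pretrain_source(
    source_ds: LabeledDataset, source_fps: FingerprintMatrix, cfg: DNNConfig | None = None
) -> ClassifierModel:
    """Train the source-domain DNN used as the transfer-learning donor.

    Identical to :func:`train_dnn`; a separate entry point so run manifests
    distinguish source pretraining from target training.
    """
    model = train_dnn(source_ds, source_fps, cfg)
    model.manifest["role"] = "transfer_source"
    return model


def transfer_weights(
    source: ClassifierModel,
    target_cfg: DNNConfig,
    spec: TransferSpec = TransferSpec(),
) -> ClassifierModel:
    """Copy trained hidden layers from ``source`` into a fresh network.

    The listed hidden layers' weights and biases are copied exactly; every
    other layer is freshly initialized under the target seed.  Optimizer,
    loss and hyperparameters are those of ``target_cfg`` — nothing else of
    the model changes.  The returned model is initialized but untrained on
    the target data; fine-tune it with :func:`fine_tune`.
    """
    if source.kind != "dnn":
        raise ValueError("transfer source must be a DNN")
    src: MLP = source.backend  # type: ignore[assignment]
    mlp = MLP(target_cfg)
    for layer in spec.layers_to_transfer:
        if not 0 <= layer < min(src.n_hidden, mlp.n_hidden):
            raise ValueError(f"layer {layer} is not a hidden layer of both networks")
        if src.W[layer].shape != mlp.W[layer].shape:
            raise ValueError(
                f"width mismatch at layer {layer}: "
                f"source {src.W[layer].shape} vs target {mlp.W[layer].shape}"
            )
        mlp.W[layer] = src.W[layer].copy()
        mlp.b[layer] = src.b[layer].copy()
        if not spec.fine_tune_transferred:
            mlp.frozen[layer] = True
    return ClassifierModel(
        kind="dnn",
        backend=mlp,
        fingerprint_config=source.fingerprint_config,
        manifest={
            "kind": "dnn",
            "config": asdict(target_cfg),
            "transfer": {
                "layers": list(spec.layers_to_transfer),
                "fine_tune_transferred": spec.fine_tune_transferred,
                "source": source.manifest.get("config"),
            },
        },
    )


def fine_tune(
    model: ClassifierModel, ds: LabeledDataset, fps: FingerprintMatrix
) -> ClassifierModel:
    """Train a (possibly transfer-initialized) DNN on the target data."""
    if model.kind != "dnn":
        raise ValueError("fine_tune applies to DNN models only")
    X, y = _training_arrays(ds, fps)
    if y.sum() == 0 or y.sum() == len(y):
        raise ValueError("training set must contain both classes")
    model.backend.fit(X, y)
    model.manifest["n_train"] = len(ds)
    model.manifest["n_epochs_run"] = len(model.backend.loss_curve)
    return model


# ---------------------------------------------------------------------------
# Persistence: JSON manifest + native weight file in one directory
# ---------------------------------------------------------------------------


def save_model(model: ClassifierModel, directory) -> None:
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    manifest = dict(model.manifest)
    manifest["fingerprint_config"] = asdict(model.fingerprint_config)
    manifest["kind"] = model.kind
    (d / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    if model.kind == "dnn":
        mlp: MLP = model.backend  # type: ignore[assignment]
        arrays = {f"W{i}": W for i, W in enumerate(mlp.W)}
        arrays |= {f"b{i}": b for i, b in enumerate(mlp.b)}
        np.savez(d / "weights.npz", **arrays)
    else:
        with open(d / "estimator.pkl", "wb") as fh:
            pickle.dump(model.backend, fh)


def load_model(directory) -> ClassifierModel:
    d = Path(directory)
    manifest = json.loads((d / "manifest.json").read_text())
    fp_cfg = FingerprintConfig(**manifest["fingerprint_config"])
    kind = manifest["kind"]
    if kind == "dnn":
        cfg_dict = dict(manifest["config"])
        cfg_dict["hidden_widths"] = tuple(cfg_dict["hidden_widths"])
        mlp = MLP(DNNConfig(**cfg_dict))
        with np.load(d / "weights.npz") as data:
            mlp.W = [data[f"W{i}"] for i in range(len(mlp.W))]
            mlp.b = [data[f"b{i}"] for i in range(len(mlp.b))]
        backend: object = mlp
    else:
        with open(d / "estimator.pkl", "rb") as fh:
            backend = pickle.load(fh)
    return ClassifierModel(kind=kind, backend=backend, fingerprint_config=fp_cfg, manifest=manifest)
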