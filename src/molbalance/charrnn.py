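"""Character-level LSTM language model over SMILES strings.

The generator treats SMILES as a language-modelling problem: a stacked LSTM
(default 3 layers × 600 hidden units, dropout 0.2 between layers) with a
softmax next-token head is trained by maximum likelihood (next-token
cross-entropy, Adam, lr 0.001, batch 64, 50 epochs) on the minority-class
corpus, then sampled token-by-token from BEGIN until END to propose new
molecules.  Sampled strings are filtered (validity, minimum length,
deduplication, novelty against the training corpus) before entering the
augmentation stage, and generation quality is summarized with the usual
molecular-generation benchmark statistics (validity, uniqueness, novelty,
internal diversity, similarity to nearest training neighbour).

Tokenization is per character except for the two-character element symbols
"Cl" and "Br", which are atomic tokens — splitting them would make almost
every sampled halogenated string syntactically invalid.

The network is implemented directly on NumPy (explicit gates, truncated
nowhere: full backpropagation through time), so training is exactly
reproducible from the seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .curation import Rejection, standardize_smiles
from .datatypes import CompoundRecord
from .featurize import FingerprintConfig, bulk_tanimoto, fingerprint_records

logger = logging.getLogger(__name__)

BEGIN, END, PAD = "^", "$", " "
_TWO_CHAR = ("Cl", "Br")


@dataclass(frozen=True)
class TokenVocabulary:
    tokens: tuple[str, ...]  # sorted corpus tokens + (BEGIN, END, PAD)

    def __post_init__(self) -> None:
        if len(set(self.tokens)) != len(self.tokens):
            raise ValueError("duplicate tokens")
        for special in (BEGIN, END, PAD):
            if special not in self.tokens:
                raise ValueError(f"missing special token {special!r}")

    @property
    def size(self) -> int:
        return len(self.tokens)

    @property
    def token_of(self) -> dict[str, int]:
        return {t: i for i, t in enumerate(self.tokens)}

    @property
    def begin_id(self) -> int:
        return self.tokens.index(BEGIN)

    @property
    def end_id(self) -> int:
        return self.tokens.index(END)

    @property
    def pad_id(self) -> int:
        return self.tokens.index(PAD)

    def encode(self, smiles: str) -> list[int]:
        tok = self.token_of
        try:
            return [tok[t] for t in tokenize(smiles)]
        except KeyError as e:
            raise ValueError(f"token {e.args[0]!r} not in vocabulary") from None

    def decode(self, ids: Sequence[int]) -> str:
        specials = {self.begin_id, self.end_id, self.pad_id}
        return "".join(self.tokens[i] for i in ids if i not in specials)


def tokenize(smiles: str) -> list[str]:
    """Split a SMILES string into tokens (single chars; Cl/Br atomic)."""
    out = []
    i = 0
    while i < len(smiles):
        if smiles[i : i + 2] in _TWO_CHAR:
            out.append(smiles[i : i + 2])
            i += 2
        else:
            out.append(smiles[i])
            i += 1
    return out


def detokenize(tokens: Sequence[str]) -> str:
    return "".join(tokens)


def build_vocabulary(corpus: Sequence[str]) -> TokenVocabulary:
    """Deterministic (sorted) vocabulary over a SMILES corpus + specials."""
    if not corpus:
        raise ValueError("empty corpus")
    seen: set[str] = set()
    for s in corpus:
        seen.update(tokenize(s))
    for special in (BEGIN, END, PAD):
        if special in seen:
            raise ValueError(f"corpus contains reserved token {special!r}")
    return TokenVocabulary(tuple(sorted(seen)) + (BEGIN, END, PAD))


@dataclass(frozen=True)
class CharRNNConfig:
    n_layers: int = 3
    hidden_size: int = 600
    dropout_rate: float = 0.2
    learning_rate: float = 0.001
    batch_size: int = 64
    epochs: int = 50
    seed: int = 0
    max_sample_length: int = 120
    temperature: float = 1.0

    def __post_init__(self) -> None:
        if self.n_layers < 1 or self.hidden_size < 1:
            raise ValueError("n_layers and hidden_size must be >= 1")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -60, 60)))


class GeneratorModel:
    """Stacked-LSTM SMILES language model with explicit NumPy parameters."""

    def __init__(self, vocabulary: TokenVocabulary, config: CharRNNConfig):
        self.vocabulary = vocabulary
        self.config = config
        V, H, L = vocabulary.size, config.hidden_size, config.n_layers
        rng = np.random.default_rng(config.seed)
        k = 1.0 / np.sqrt(H)
        self.Wx = []
        self.Wh = []
        self.b = []
        for layer in range(L):
            in_dim = V if layer == 0 else H
            self.Wx.append(rng.uniform(-k, k, (in_dim, 4 * H)))
            self.Wh.append(rng.uniform(-k, k, (H, 4 * H)))
            bias = np.zeros(4 * H)
            bias[H : 2 * H] = 1.0  # forget-gate bias: remember by default
            self.b.append(bias)
        self.Wy = rng.uniform(-k, k, (H, V))
        self.by = np.zeros(V)
        self.loss_curve: list[float] = []

    # -- forward ------------------------------------------------------------
    def _layer_forward(self, X: np.ndarray, layer: int):
        """Run one LSTM layer over a (B, T, in_dim) sequence.

        Returns hidden sequence (B, T, H) and per-step caches for BPTT.
        """
        B, T, _ = X.shape
        H = self.config.hidden_size
        h = np.zeros((B, H))
        c = np.zeros((B, H))
        Hs = np.zeros((B, T, H))
        caches = []
        for t in range(T):
            x_t = X[:, t, :]
            z = x_t @ self.Wx[layer] + h @ self.Wh[layer] + self.b[layer]
            i = _sigmoid(z[:, :H])
            f = _sigmoid(z[:, H : 2 * H])
            g = np.tanh(z[:, 2 * H : 3 * H])
            o = _sigmoid(z[:, 3 * H :])
            c_new = f * c + i * g
            tanh_c = np.tanh(c_new)
            h_new = o * tanh_c
            caches.append((x_t, h, c, i, f, g, o, tanh_c))
            h, c = h_new, c_new
            Hs[:, t, :] = h
        return Hs, caches

    def _layer_backward(self, dHs: np.ndarray, caches, layer: int):
        """BPTT through one layer; returns gradient wrt the layer's input."""
        B, T, _ = dHs.shape
        H = self.config.hidden_size
        in_dim = self.Wx[layer].shape[0]
        dWx = np.zeros_like(self.Wx[layer])
        dWh = np.zeros_like(self.Wh[layer])
        db = np.zeros_like(self.b[layer])
        dX = np.zeros((B, T, in_dim))
        dh_next = np.zeros((B, H))
        dc_next = np.zeros((B, H))
        for t in range(T - 1, -1, -1):
            x_t, h_prev, c_prev, i, f, g, o, tanh_c = caches[t]
            dh = dHs[:, t, :] + dh_next
            do = dh * tanh_c
            dc = dc_next + dh * o * (1.0 - tanh_c**2)
            di = dc * g
            df = dc * c_prev
            dg = dc * i
            dc_next = dc * f
            dz = np.concatenate(
                [
                    di * i * (1 - i),
                    df * f * (1 - f),
                    dg * (1 - g**2),
                    do * o * (1 - o),
                ],
                axis=1,
            )
            dWx += x_t.T @ dz
            dWh += h_prev.T @ dz
            db += dz.sum(axis=0)
            dX[:, t, :] = dz @ self.Wx[layer].T
            dh_next = dz @ self.Wh[layer].T
        return dX, dWx, dWh, db

    def _forward_stack(self, X: np.ndarray, drop_rng: np.random.Generator | None):
        """All layers over a one-hot batch; dropout between layers in training."""
        caches = []
        masks = []
        h = X
        for layer in range(self.config.n_layers):
            h, cache = self._layer_forward(h, layer)
            caches.append(cache)
            if layer < self.config.n_layers - 1:
                if drop_rng is not None and self.config.dropout_rate > 0:
                    keep = 1.0 - self.config.dropout_rate
                    mask = (drop_rng.random(h.shape) < keep) / keep
                    h = h * mask
                    masks.append(mask)
                else:
                    masks.append(None)
        return h, caches, masks

    def next_token_probs(self, prefix_ids: Sequence[int]) -> np.ndarray:
        """Distribution over the vocabulary after consuming a prefix."""
        V = self.vocabulary.size
        X = np.zeros((1, len(prefix_ids), V))
        X[0, np.arange(len(prefix_ids)), list(prefix_ids)] = 1.0
        h, _, _ = self._forward_stack(X, drop_rng=None)
        logits = h[0, -1, :] @ self.Wy + self.by
        logits -= logits.max()
        e = np.exp(logits)
        return e / e.sum()

    # -- training -----------------------------------------------------------
    def _params(self):
        for layer in range(self.config.n_layers):
            yield self.Wx[layer]
            yield self.Wh[layer]
            yield self.b[layer]
        yield self.Wy
        yield self.by

    def fit(self, corpus: Sequence[str]) -> "GeneratorModel":
        """Maximum-likelihood training by next-token cross-entropy.

        Teacher forcing throughout; sequences padded per batch with PAD,
        which is masked out of the loss.
        """
        if not corpus:
            raise ValueError("empty corpus")
        cfg = self.config
        vocab = self.vocabulary
        V = vocab.size
        encoded = [
            [vocab.begin_id] + vocab.encode(s) + [vocab.end_id] for s in corpus
        ]
        params = list(self._params())
        m = [np.zeros_like(p) for p in params]
        v = [np.zeros_like(p) for p in params]
        beta1, beta2, eps = 0.9, 0.999, 1e-8
        step = 0
        order_rng = np.random.default_rng(cfg.seed + 1)
        drop_rng = np.random.default_rng(cfg.seed + 2)

        for _epoch in range(cfg.epochs):
            order = order_rng.permutation(len(encoded))
            total_loss = 0.0
            total_tokens = 0
            for start in range(0, len(encoded), cfg.batch_size):
                batch = [encoded[i] for i in order[start : start + cfg.batch_size]]
                B = len(batch)
                T = max(len(s) for s in batch) - 1
                X = np.zeros((B, T, V))
                targets = np.full((B, T), vocab.pad_id, dtype=int)
                for bi, seq in enumerate(batch):
                    L = len(seq) - 1
                    X[bi, np.arange(L), seq[:-1]] = 1.0
                    # PAD the input positions beyond the sequence too
                    X[bi, np.arange(L, T), vocab.pad_id] = 1.0
                    targets[bi, :L] = seq[1:]
                mask = targets != vocab.pad_id
                n_tok = int(mask.sum())

                Htop, caches, drop_masks = self._forward_stack(X, drop_rng)
                logits = Htop @ self.Wy + self.by
                logits -= logits.max(axis=2, keepdims=True)
                expl = np.exp(logits)
                probs = expl / expl.sum(axis=2, keepdims=True)
                tgt_probs = np.take_along_axis(probs, targets[:, :, None], axis=2)[..., 0]
                loss = -float(np.log(np.clip(tgt_probs[mask], 1e-12, None)).sum())
                total_loss += loss
                total_tokens += n_tok

                # backward
                dlogits = probs.copy()
                bidx = np.arange(B)[:, None]
                tidx = np.arange(T)[None, :]
                dlogits[bidx, tidx, targets] -= 1.0
                dlogits *= mask[:, :, None] / n_tok
                dWy = np.tensordot(Htop, dlogits, axes=([0, 1], [0, 1]))
                dby = dlogits.sum(axis=(0, 1))
                dH = dlogits @ self.Wy.T
                grads: list[np.ndarray] = []
                for layer in range(cfg.n_layers - 1, -1, -1):
                    if layer < cfg.n_layers - 1 and drop_masks[layer] is not None:
                        dH = dH * drop_masks[layer]
                    dH, dWx, dWh, db = self._layer_backward(dH, caches[layer], layer)
                    grads = [dWx, dWh, db] + grads
                grads += [dWy, dby]

                # global-norm clip keeps early updates sane
                norm = np.sqrt(sum(float((g**2).sum()) for g in grads))
                if norm > 5.0:
                    grads = [g * (5.0 / norm) for g in grads]

                step += 1
                for p, g, mi, vi in zip(params, grads, m, v):
                    mi *= beta1
                    mi += (1 - beta1) * g
                    vi *= beta2
                    vi += (1 - beta2) * g * g
                    m_hat = mi / (1 - beta1**step)
                    v_hat = vi / (1 - beta2**step)
                    p -= cfg.learning_rate * m_hat / (np.sqrt(v_hat) + eps)

            self.loss_curve.append(total_loss / max(total_tokens, 1))
        return self

    # -- sampling -----------------------------------------------------------
    def _step(self, x: np.ndarray, hs, cs):
        """One timestep through the stack for a (B, V) one-hot input."""
        H = self.config.hidden_size
        h_in = x
        for layer in range(self.config.n_layers):
            z = h_in @ self.Wx[layer] + hs[layer] @ self.Wh[layer] + self.b[layer]
            i = _sigmoid(z[:, :H])
            f = _sigmoid(z[:, H : 2 * H])
            g = np.tanh(z[:, 2 * H : 3 * H])
            o = _sigmoid(z[:, 3 * H :])
            cs[layer] = f * cs[layer] + i * g
            hs[layer] = o * np.tanh(cs[layer])
            h_in = hs[layer]
        logits = h_in @ self.Wy + self.by
        return logits

    def _rollout(self, n: int, rng: np.random.Generator | None, greedy: bool) -> list[str]:
        vocab = self.vocabulary
        V = vocab.size
        cfg = self.config
        H = cfg.hidden_size
        hs = [np.zeros((n, H)) for _ in range(cfg.n_layers)]
        cs = [np.zeros((n, H)) for _ in range(cfg.n_layers)]
        x = np.zeros((n, V))
        x[:, vocab.begin_id] = 1.0
        done = np.zeros(n, dtype=bool)
        seqs: list[list[int]] = [[] for _ in range(n)]
        for _ in range(cfg.max_sample_length):
            logits = self._step(x, hs, cs)
            # BEGIN and PAD are bookkeeping tokens, never emitted
            logits[:, vocab.begin_id] = -np.inf
            logits[:, vocab.pad_id] = -np.inf
            if greedy:
                choice = logits.argmax(axis=1)
            else:
                scaled = logits / cfg.temperature
                scaled -= scaled.max(axis=1, keepdims=True)
                p = np.exp(scaled)
                p /= p.sum(axis=1, keepdims=True)
                cum = p.cumsum(axis=1)
                u = rng.random((n, 1))
                choice = (u < cum).argmax(axis=1)
            for bi in range(n):
                if not done[bi]:
                    if choice[bi] == vocab.end_id:
                        done[bi] = True
                    else:
                        seqs[bi].append(int(choice[bi]))
            if done.all():
                break
            x = np.zeros((n, V))
            x[np.arange(n), choice] = 1.0
        return [vocab.decode(s) for s in seqs]

    def sample(self, n: int, seed: int | None = None) -> list[str]:
        """Draw ``n`` raw SMILES strings (validity not guaranteed)."""
        if n == 0:
            return []
        rng = np.random.default_rng(self.config.seed + 3 if seed is None else seed)
        return self._rollout(n, rng, greedy=False)

    def greedy_decode(self) -> str:
        """Argmax rollout from BEGIN — the temperature → 0 limit."""
        return self._rollout(1, None, greedy=True)[0]


def train_generator(corpus: Sequence[str], cfg: CharRNNConfig | None = None) -> GeneratorModel:
    """Build the vocabulary from ``corpus`` and fit the language model."""
    cfg = cfg or CharRNNConfig()
    vocab = build_vocabulary(corpus)
    model = GeneratorModel(vocab, cfg)
    model.fit(corpus)
    logger.info(
        "charrnn trained: %d epochs, loss %.4f -> %.4f",
        len(model.loss_curve), model.loss_curve[0], model.loss_curve[-1],
    )
    return model


# ---------------------------------------------------------------------------
# Post-generation filtering and quality metrics
# ---------------------------------------------------------------------------


def _canonical_set(smiles: Sequence[str]) -> set[str]:
    out = set()
    for s in smiles:
        rec = standardize_smiles(s)
        if isinstance(rec, CompoundRecord):
            out.add(rec.canonical_smiles)
    return out


def filter_generated(
    raw: Sequence[str],
    training_corpus: Sequence[str],
    exclude: Sequence[str] = (),
    id_prefix: str = "gen",
) -> list[CompoundRecord]:
    """Standardize and filter raw generated SMILES.

    Pipeline: parse/standardize (silently dropping invalid strings) →
    drop strings shorter (in characters) than the shortest training SMILES →
    deduplicate canonical SMILES (first occurrence kept) → drop anything
    present in the training corpus or in ``exclude`` (e.g. the active class).
    """
    if not training_corpus:
        raise ValueError("training corpus must be non-empty")
    corpus_canonical = _canonical_set(training_corpus)
    min_len = min(len(s) for s in corpus_canonical)
    forbidden = corpus_canonical | _canonical_set(exclude)
    seen: set[str] = set()
    out: list[CompoundRecord] = []
    for s in raw:
        rec = standardize_smiles(s, source="generated")
        if isinstance(rec, Rejection):
            continue
        smi = rec.canonical_smiles
        if len(smi) < min_len or smi in seen or smi in forbidden:
            continue
        seen.add(smi)
        out.append(
            CompoundRecord(smi, f"{id_prefix}_{len(out):05d}", "generated")
        )
    return out


@dataclass(frozen=True)
class GenerationReport:
    n_requested: int
    n_valid: int
    validity: float
    uniqueness: float
    novelty: float
    internal_diversity: float
    snn_to_train: float

    def as_dict(self) -> dict:
        return {
            "n_requested": self.n_requested,
            "n_valid": self.n_valid,
            "validity": self.validity,
            "uniqueness": self.uniqueness,
            "novelty": self.novelty,
            "internal_diversity": self.internal_diversity,
            "snn_to_train": self.snn_to_train,
        }


def generation_metrics(
    raw: Sequence[str],
    training_corpus: Sequence[str],
    fp_config: FingerprintConfig = FingerprintConfig(),
    max_pairwise: int = 2000,
) -> GenerationReport:
    """Benchmark-style quality statistics for a raw sample.

    validity = valid / requested; uniqueness = unique canonical / valid;
    novelty = fraction of unique canonical SMILES absent from the training
    corpus; internal diversity = 1 − mean pairwise Tanimoto among the unique
    valid molecules; snn_to_train = mean over those molecules of the maximum
    Tanimoto similarity to any training compound.
    """
    n_requested = len(raw)
    canonical: list[str] = []
    for s in raw:
        rec = standardize_smiles(s, source="generated")
        if isinstance(rec, CompoundRecord):
            canonical.append(rec.canonical_smiles)
    n_valid = len(canonical)
    unique = list(dict.fromkeys(canonical))
    if n_valid == 0:
        logger.warning("no valid molecules in generated sample")
        return GenerationReport(n_requested, 0, 0.0, 0.0, 0.0, 0.0, 0.0)

    train_set = _canonical_set(training_corpus)
    novelty = sum(1 for s in unique if s not in train_set) / len(unique)

    if len(unique) > max_pairwise:
        unique_fp = unique[:max_pairwise]
    else:
        unique_fp = unique
    gen_fps = fingerprint_records(
        [CompoundRecord(s, f"g{i}", "generated") for i, s in enumerate(unique_fp)],
        fp_config,
    ).bits
    train_fps = fingerprint_records(
        [CompoundRecord(s, f"t{i}", "public") for i, s in enumerate(dict.fromkeys(training_corpus))],
        fp_config,
    ).bits

    if len(unique_fp) > 1:
        sim = bulk_tanimoto(gen_fps, gen_fps)
        iu = np.triu_indices(len(unique_fp), k=1)
        internal_diversity = 1.0 - float(sim[iu].mean())
    else:
        internal_diversity = 0.0
    snn = float(bulk_tanimoto(gen_fps, train_fps).max(axis=1).mean())

    return GenerationReport(
        n_requested=n_requested,
        n_valid=n_valid,
        validity=n_valid / n_requested if n_requested else 0.0,
        uniqueness=len(unique) / n_valid,
        novelty=novelty,
        internal_diversity=internal_diversity,
        snn_to_train=snn,
    )
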