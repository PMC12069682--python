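# Methods

This note documents the models and procedures implemented in `molbalance`,
the parameters that matter, the design choices made where the design was
genuinely open, and what the synthetic benchmark does and does not show.

## Data curation

Raw bioactivity rows (`compound_id, smiles, activity_type ∈ {EC50, IC50,
Ki}, relation, value, unit`) pass through three stages.

**Standardization.** Each SMILES is parsed with RDKit, the largest organic
fragment is kept (salt/counter-ion stripping), charges are neutralized
where chemically valid, and the canonical SMILES is emitted. Unparsable
input is recorded with a reason code and skipped, never fatal.

**Dual-cutoff labelling.** Values are converted to µM; ≤ 1 µM with
relation `=`/`<`/`≤` is *active*, ≥ 10 µM with `=`/`>`/`≥` is *inactive*,
everything between the cutoffs is *excluded* as ambiguous. Censored
bounds carry information only on one side: a `>` bound at or above the
inactive cutoff is a genuine inactive even without an absolute
measurement, while a `<` bound above the active cutoff says nothing and
is excluded (the symmetric treatment of `<` bounds is this package's
choice; the curation log flags how many rows it affected). Both cutoffs
are configurable (`CurationConfig`).

**Deduplication.** One record per canonical SMILES per class (first
occurrence by input order, for determinism); a SMILES reported under both
labels is removed from both classes.

The `cutoff_scan` module quantifies why a dual cutoff is worth its
exclusion zone: for a fixed active cutoff it relabels the data at each
candidate inactive cutoff, re-runs the full deduplication, and counts the
actives whose maximum Tanimoto similarity to any inactive exceeds a
threshold (default 0.5, strict inequality). Because inactive sets are
nested as the cutoff rises, both the inactive count and the overlap count
are non-increasing — the monotonicity the acceptance suite asserts.
Whether overlap should be measured before or after cross-class removal is
ambiguous; the scan computes it after, and reports the before value in
the same row.

## Features

All modelling uses hashed circular (Morgan) fingerprints, radius 2 folded
to 1,024 presence bits (≈ ECFP4), computed by RDKit. Tanimoto similarity
|A∩B|/|A∪B| is defined as 0 for two all-zero vectors — the convention can
only *under*-count overlap. Six physicochemical descriptors (MW, logP,
rings, rotatable bonds, HBD, HBA) support class profiling.

## Splitting

`scaffold_split` groups compounds by Bemis–Murcko framework (acyclic
molecules share the reserved empty key and travel together), sorts groups
by descending size with lexicographic tie-break, and fills the training
set greedily until it holds 80% of the *compounds* (not scaffolds);
remaining groups form the test set. The procedure is fully deterministic.
After splitting, any training compound whose folded fingerprint collides
with a test compound is removed from the training set — fingerprint
identity, not SMILES identity, defines this deduplication, because a
collision in the model's representation is leakage regardless of the
molecule behind it.

`stratified_kfold` permutes each class under the seed and deals
round-robin to k folds, so per-fold class counts deviate from the ideal
allocation by at most one compound per class.

## Classifiers

The DNN is a fully connected network (1,024 → 1,000 → 500 → 1 by
default), ReLU hidden activations and a sigmoid output, dropout 0.25 on
each hidden layer, binary cross-entropy loss, Adam (lr 0.001, batch 64),
up to 2,000 epochs with early stopping when the epoch training loss fails
to improve for 50 epochs. Early stopping monitors the *training* loss —
no validation split is carved out, preserving the 80:20 design; the
patience and monitored quantity are configurable. The implementation is
plain NumPy with explicit weight matrices and a hand-written Adam; this
makes training exactly reproducible from the seed and weight transfer an
exact copy operation. Baselines — Bernoulli naive Bayes, random forest,
XGBoost — wrap scikit-learn/XGBoost with library defaults behind the same
`predict_proba` contract; all hyperparameters land in the model manifest.

Hard labels use a fixed 0.5 threshold with `≥` tie-break.

**Transfer learning.** `transfer_weights` copies the weights and biases
of selected hidden layers from a source-domain model into a freshly
initialized target network; nothing else (optimizer, loss,
hyperparameters) changes. The default transfers layer 0 only and leaves
it trainable during fine-tuning; both the layer set and freezing are
explicit in `TransferSpec`, since "first hidden layers" is ambiguous
between {0} and {0,1} and freezing is a genuinely open choice. The choice
used is recorded in the model manifest.

## SMILES language model

The generator is a character-level stacked LSTM (default 3 × 600 hidden
units, dropout 0.2 between layers, softmax head) trained by next-token
maximum likelihood with teacher forcing (Adam, lr 0.001, batch 64,
50 epochs; padding masked from the loss). Tokenization is per character
except `Cl`/`Br`, which are atomic tokens — splitting two-character
element symbols makes almost every halogenated sample invalid for no
modelling benefit. Sampling draws from the temperature-scaled softmax
from BEGIN until END or 120 tokens; BEGIN/PAD are bookkeeping symbols and
are masked out of the sampling distribution, so the temperature → 0 limit
equals greedy argmax decoding. Gradients are clipped at global norm 5.

Generated strings pass a four-stage filter before augmentation:
standardize (drop invalid), drop strings shorter in characters than the
shortest training SMILES (string length, not atom count — the simplest
reading of a minimum-size rule; the corpus is canonicalized first so the
comparison is consistent), deduplicate canonical SMILES, and drop
anything present in the training corpus or the opposite class. Quality is
summarized with the standard generation-benchmark statistics: validity,
uniqueness, novelty, internal diversity (1 − mean pairwise Tanimoto) and
mean similarity to the nearest training neighbour.

## Clustering and augmentation

Generated survivors are clustered by Butina sphere exclusion on Tanimoto
distance (default cutoff 0.6): neighbour counts are computed once,
compounds are visited in decreasing-degree order (ties by id), each
unassigned compound founds a cluster absorbing its unassigned neighbours,
and the founder is the centroid. Centroids are therefore *real generated
molecules*, never bit-vector averages — augmented training needs valid
structures. `cluster_to_target` bisects the cutoff toward a requested
cluster count when a fixed augmentation size is wanted. Added records
carry `source=generated` and the full dedup/conflict rules are re-applied
on augmentation.

The classical comparators (ENN undersampling of the majority, SMOTE-ENN,
k-means-guided SMOTE) are implemented on scikit-learn primitives
(`NearestNeighbors`, `KMeans`) following the original algorithm
descriptions: ENN removes samples whose 3-NN majority vote disagrees with
their label (majority class only for plain ENN; both classes after
SMOTE); SMOTE interpolates uniformly between minority 5-NN pairs up to
class parity; k-means SMOTE restricts interpolation to minority-dominated
clusters with allocation weighted toward sparse clusters. Interpolated
rows are binarized at 0.5 so classifiers keep seeing binary fingerprints;
synthetic rows have no molecules behind them, which is exactly the
contrast with generative augmentation the package exists to measure.

## Evaluation protocol

Metrics: sensitivity, specificity, MCC, G-mean, accuracy, and ROC AUC by
the rank statistic with half-credit for ties. Degenerate conventions: an
empty denominator gives 0 (and MCC 0 for any constant predictor); ROC AUC
is reported as missing — not 0 — for single-class test sets, where
accuracy is the meaningful number.

Cross-validation re-applies the balancing strategy *inside every fold* on
the training portion only. For generator augmentation the candidate pool
is re-filtered per fold against the held-out compounds and the harness
asserts that no augmented SMILES occurs in the held-out fold. When a
pre-generated pool is supplied (the cheap path), the generator itself was
trained on the full training split; the per-fold novelty filter removes
exact duplicates, and refitting the generator per fold is available via
`generator_config` where that residual leakage matters. Each fold's model
is also evaluated on every external test surface (scaffold-split, HTS,
single-class sets), giving the per-fold distributions the statistics
need.

Friedman's test uses the tie-corrected chi-square form (blocks = folds,
treatments = models), verified in the test suite against SciPy. The
Conover–Friedman post-hoc uses the rank-sum statistic with variance
2(n·A1 − ΣRj²)/((n−1)(k−1)) on a t distribution with (n−1)(k−1) df,
two-sided, no multiplicity adjustment by default (none is standard for
this protocol; a flag can add it). When the residual rank variance is
exactly zero the statistic is undefined; the implementation returns p = 1
for tied rank sums and p = 0 for differing ones (a perfectly consistent
ranking across all blocks). Verdicts follow the all-three-metrics rule at
α = 0.05.

## Synthetic data

Real extracts cannot be bundled, so the generator fabricates datasets
with the *shape* of public dose-response data. Molecules are ring cores —
single rings or two linked rings (linkers: bond, C, CC, O, N) — decorated
with 1–3 substituents from a 12-member set at enumerated ring positions;
construction is grammar-based, so every SMILES is valid, unique, and has
a genuine Murcko scaffold (its core). Families are Zipf-sized within each
class, mirroring the heavy-tailed scaffold populations of real data, and
this matters: with uniform family sizes, a greedy scaffold split
degenerates (one class's families land wholly on one side).

The class signal is carried by ring chemistry: active families draw on
benzene/pyridine/indole, inactive families always contain at least one of
piperidine/pyrimidine/cyclohexane but may link it to an active-pool ring.
Classes therefore share substructure — a model starved of inactives
over-weights the shared aromatic bits and mislabels unseen-scaffold
inactives, the failure mode the balancing strategies correct.
`cross_family_mixing` (default 0.1) draws that fraction of inactives from
active-dominant families, an irreducible-noise dial: scaffold-split
G-mean of a fixed baseline decays as it rises. Three-quarters of the
families are active-dominant, so with an imbalanced dataset family sizes
straddle the split boundary for both classes. A seeded bioactivity-value
layer (log-uniform potencies, censored `>` bounds, an ambiguous band,
mixed nM/µM units) exercises curation end-to-end, and an optional
HTS-like test set is ≈75:1 inactive:active.

What passing the synthetic benchmark shows: the full pipeline —
curation → split → generation → filtering → clustering → augmentation →
training → evaluation — is correct, leak-free and directionally
effective when minority chemistry is under-covered. What it does not
show: performance on real assay data, whose chemistry is vastly higher
dimensional, noisier in label and assay type, and not grammar-bounded; no
pharmacological realism is attempted.

## Benchmark problem sizes

The standard benchmark (`molbalance.benchmark`) uses 400 actives : 50
inactives over 22 families, an 80:20 scaffold split, a compact classifier
(hidden layers 128/64, ≤150 epochs, patience 20) and a compact generator
(single LSTM layer of 128 units, lr 0.005, 300 epochs, 2,000 samples,
centroid cutoff 0.6), with a balanced 400:400 source domain for transfer.
These sizes were chosen so a full five-seed comparison runs in minutes on
one CPU while leaving the directional contrast between strategies well
resolved; the full-scale defaults on every config object are the ones
stated in the sections above.

## Known limitations

* The LSTM trains by full BPTT on padded batches; very long SMILES
  (> max_sample_length) would be truncated at sampling, not training.
* Conover–Friedman p-values are unadjusted for multiplicity by default.
* k-means SMOTE needs at least one minority-dominated cluster and raises
  otherwise rather than silently degrading to plain SMOTE.
* The synthetic grammar cannot represent fused novel ring systems beyond
  indole; generative novelty is correspondingly bounded.
* MCC is known to be ratio-sensitive under extreme imbalance (visible on
  the HTS-like surface); G-mean and ROC AUC are the more stable summaries
  there.
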