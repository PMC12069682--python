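"""Metrics, the cross-validation harness, and model comparison statistics.

Binary classification under class imbalance is summarized by sensitivity,
specificity, the Matthews correlation coefficient (MCC), ROC AUC and the
G-mean (geometric mean of sensitivity and specificity):

    sensitivity = TP / (TP + FN)
    specificity = TN / (TN + FP)
    MCC = (TP·TN − FP·FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN))
    G-mean = sqrt(sensitivity · specificity)

Model comparison across CV folds uses Friedman's rank test (folds as
blocks, models as treatments) followed by the Conover–Friedman post-hoc on
the fold ranks; a model is declared significantly better than another only
when the pairwise test is significant for MCC, ROC AUC *and* G-mean and its
mean is higher on all three.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import ACTIVE, INACTIVE, LabeledDataset
from .featurize import FingerprintMatrix
from .splitting import FoldPlan

COMPARISON_METRICS = ("mcc", "roc_auc", "gmean")


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass(frozen=True)
class MetricSet:
    sensitivity: float
    specificity: float
    mcc: float
    roc_auc: float | None
    gmean: float
    accuracy: float

    def as_dict(self) -> dict:
        return {
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "mcc": self.mcc,
            "roc_auc": self.roc_auc,
            "gmean": self.gmean,
            "accuracy": self.accuracy,
        }


def _to_binary(y) -> np.ndarray:
    """Coerce labels to {1 = active/positive, 0 = inactive/negative}."""
    arr = np.asarray(y)
    if arr.dtype.kind in "USO":
        mapped = np.zeros(len(arr), dtype=int)
        for i, v in enumerate(arr):
            if v == ACTIVE:
                mapped[i] = 1
            elif v == INACTIVE:
                mapped[i] = 0
            else:
                raise ValueError(f"unknown label {v!r}")
        return mapped
    return (arr > 0.5).astype(int) if arr.dtype.kind == "f" else arr.astype(int)


def confusion(y_true, y_pred) -> ConfusionCounts:
    """Exact confusion counts with *active* as the positive class."""
    t = _to_binary(y_true)
    p = _to_binary(y_pred)
    if len(t) != len(p):
        raise ValueError(f"length mismatch: {len(t)} vs {len(p)}")
    return ConfusionCounts(
        tp=int(np.sum((t == 1) & (p == 1))),
        tn=int(np.sum((t == 0) & (p == 0))),
        fp=int(np.sum((t == 0) & (p == 1))),
        fn=int(np.sum((t == 1) & (p == 0))),
    )


def roc_auc_from_scores(y_true, scores) -> float | None:
    """ROC AUC via the rank (Mann–Whitney) statistic, 0.5 credit for ties.

    Returns ``None`` when only one class is present (the AUC is undefined
    on a single-class test set; accuracy is the reported metric there).
    """
    t = _to_binary(y_true)
    s = np.asarray(scores, dtype=float)
    n_pos = int(t.sum())
    n_neg = len(t) - n_pos
    if n_pos == 0 or n_neg == 0:
        return None
    ranks = stats.rankdata(s)  # average ranks on ties
    auc = (ranks[t == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)
    return float(auc)


def metrics(
    c: ConfusionCounts,
    scores: Sequence[float] | None = None,
    y_true=None,
) -> MetricSet:
    """Compute the metric set from confusion counts (plus scores for AUC).

    Degenerate conventions: a metric whose denominator is empty (no
    positives for sensitivity, no negatives for specificity) is 0; MCC is 0
    when any marginal factor is 0 (a constant predictor carries no
    correlation); ROC AUC is ``None`` without scores or with one-class truth.
    """
    sens = c.tp / (c.tp + c.fn) if (c.tp + c.fn) else 0.0
    spec = c.tn / (c.tn + c.fp) if (c.tn + c.fp) else 0.0
    denom = (c.tp + c.fp) * (c.tp + c.fn) * (c.tn + c.fp) * (c.tn + c.fn)
    mcc = (c.tp * c.tn - c.fp * c.fn) / math.sqrt(denom) if denom else 0.0
    auc = roc_auc_from_scores(y_true, scores) if scores is not None else None
    total = c.total
    acc = (c.tp + c.tn) / total if total else 0.0
    return MetricSet(
        sensitivity=float(sens),
        specificity=float(spec),
        mcc=float(mcc),
        roc_auc=auc,
        gmean=float(math.sqrt(sens * spec)),
        accuracy=float(acc),
    )


def evaluate_predictions(y_true, scores, threshold: float = 0.5) -> MetricSet:
    """Hard-label metrics at a probability threshold (active iff p ≥ threshold)."""
    s = np.asarray(scores, dtype=float)
    y_pred = (s >= threshold).astype(int)
    return metrics(confusion(y_true, y_pred), scores=s, y_true=y_true)


# ---------------------------------------------------------------------------
# Statistical model comparison
# ---------------------------------------------------------------------------


def _rank_matrix(table: np.ndarray) -> np.ndarray:
    """Within-block (row) ranks with average ranks on ties."""
    return np.apply_along_axis(stats.rankdata, 1, table)


def _check_table(table: np.ndarray) -> np.ndarray:
    table = np.asarray(table, dtype=float)
    if table.ndim != 2:
        raise ValueError("metric table must be 2-D (folds × models)")
    if np.isnan(table).any():
        raise ValueError("metric table is incomplete (contains NaN)")
    n, k = table.shape
    if k < 3:
        raise ValueError("need at least 3 models")
    if n < 2:
        raise ValueError("need at least 2 folds")
    return table


def friedman_test(table: np.ndarray) -> tuple[float, float]:
    """Friedman's rank test over a folds × models table.

    Uses the tie-corrected chi-square form
    ``T1 = (k−1)·Σ(Rj − n(k+1)/2)² / (A1 − C1)`` with A1 = ΣΣ rij² and
    C1 = nk(k+1)²/4, which reduces to the classic statistic without ties.
    Identical columns give statistic 0 and p = 1.
    """
    table = _check_table(table)
    n, k = table.shape
    r = _rank_matrix(table)
    col_sums = r.sum(axis=0)
    a1 = float((r**2).sum())
    c1 = n * k * (k + 1) ** 2 / 4.0
    if a1 == c1:  # every block fully tied
        return 0.0, 1.0
    t1 = (k - 1) * float(((col_sums - n * (k + 1) / 2.0) ** 2).sum()) / (a1 - c1)
    p = float(stats.chi2.sf(t1, df=k - 1))
    return float(t1), p


def conover_friedman(table: np.ndarray) -> np.ndarray:
    """Conover's post-hoc all-pairs comparison on Friedman ranks.

    For models i, j the statistic is ``|Ri − Rj| / sqrt(2(n·A1 − ΣRj²) /
    ((n−1)(k−1)))`` referred to a t distribution with (n−1)(k−1) degrees of
    freedom (two-sided).  Returns the symmetric k×k p-value matrix with a
    unit diagonal.  Fully tied input gives p = 1 everywhere.
    """
    table = _check_table(table)
    n, k = table.shape
    r = _rank_matrix(table)
    col_sums = r.sum(axis=0)
    a1 = float((r**2).sum())
    b1 = float((col_sums**2).sum())
    df = (n - 1) * (k - 1)
    var = 2.0 * (n * a1 - b1) / df
    p = np.ones((k, k))
    if var <= 0:
        # zero residual rank variance: either every block is fully tied
        # (rank sums equal -> p = 1) or the ranking is perfectly consistent
        # across blocks (different rank sums are infinitely significant)
        for i in range(k):
            for j in range(i + 1, k):
                if col_sums[i] != col_sums[j]:
                    p[i, j] = p[j, i] = 0.0
        return p
    sd = math.sqrt(var)
    for i in range(k):
        for j in range(i + 1, k):
            tval = abs(col_sums[i] - col_sums[j]) / sd
            pij = 2.0 * float(stats.t.sf(tval, df=df))
            p[i, j] = p[j, i] = min(1.0, pij)
    return p


@dataclass(frozen=True)
class ComparisonResult:
    model_names: tuple[str, ...]
    friedman_statistic: float
    friedman_p: float
    posthoc_p: np.ndarray  # k × k, symmetric, unit diagonal
    means: np.ndarray  # per-model mean of the metric

    def as_dict(self) -> dict:
        return {
            "models": list(self.model_names),
            "friedman_statistic": self.friedman_statistic,
            "friedman_p": self.friedman_p,
            "posthoc_p": self.posthoc_p.tolist(),
            "means": self.means.tolist(),
        }


def compare_models(table: np.ndarray, model_names: Sequence[str]) -> ComparisonResult:
    """Omnibus Friedman + Conover–Friedman post-hoc for one metric table."""
    table = _check_table(table)
    stat, p = friedman_test(table)
    return ComparisonResult(
        model_names=tuple(model_names),
        friedman_statistic=stat,
        friedman_p=p,
        posthoc_p=conover_friedman(table),
        means=table.mean(axis=0),
    )


def declare_better(
    results: Mapping[str, ComparisonResult], alpha: float = 0.05
) -> dict[tuple[str, str], bool]:
    """All-three-metrics significance rule.

    Model A is significantly better than B iff, for every one of MCC,
    ROC AUC and G-mean, the Conover–Friedman pairwise p is below ``alpha``
    and A's fold-mean exceeds B's.  Returns the full pairwise verdict map.
    """
    missing = [m for m in COMPARISON_METRICS if m not in results]
    if missing:
        raise ValueError(f"missing comparison metrics: {missing}")
    names = results[COMPARISON_METRICS[0]].model_names
    for m in COMPARISON_METRICS:
        if results[m].model_names != names:
            raise ValueError("model sets differ across metrics")
    verdicts: dict[tuple[str, str], bool] = {}
    k = len(names)
    for i in range(k):
        for j in range(k):
            if i == j:
                continue
            wins = all(
                results[m].posthoc_p[i, j] < alpha
                and results[m].means[i] > results[m].means[j]
                for m in COMPARISON_METRICS
            )
            verdicts[(names[i], names[j])] = wins
    return verdicts


# ---------------------------------------------------------------------------
# Cross-validation harness
# ---------------------------------------------------------------------------


@dataclass
class EvaluationReport:
    """Tidy per-fold metric table: model, strategy, fold, surface, metric, value."""

    table: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    def metric_matrix(
        self, metric: str, surface: str = "cv", models: Sequence[str] | None = None
    ) -> tuple[np.ndarray, list[str]]:
        """Pivot to a folds × models matrix for statistical comparison."""
        df = self.table[(self.table.surface == surface) & (self.table.metric == metric)]
        pivot = df.pivot_table(index="fold", columns="model", values="value")
        if models is not None:
            pivot = pivot[list(models)]
        if pivot.isna().any().any():
            raise ValueError(f"incomplete model×fold grid for metric {metric!r}")
        return pivot.to_numpy(), list(pivot.columns)

    def summary(self) -> pd.DataFrame:
        return (
            self.table.groupby(["model", "surface", "metric"])["value"]
            .agg(["mean", "std"])
            .reset_index()
        )

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def _metric_rows(
    ms: MetricSet, model: str, strategy: str, fold: int, surface: str
) -> list[dict]:
    rows = []
    for metric, value in ms.as_dict().items():
        if value is None:
            continue
        rows.append(
            {
                "model": model,
                "strategy": strategy,
                "fold": fold,
                "surface": surface,
                "metric": metric,
                "value": value,
            }
        )
    return rows


def cross_validate(
    pipeline,
    ds: LabeledDataset,
    fps: FingerprintMatrix,
    folds: FoldPlan,
    external_tests: Sequence[tuple[str, LabeledDataset, FingerprintMatrix]] = (),
    threshold: float = 0.5,
) -> EvaluationReport:
    """Stratified k-fold CV of one modelling pipeline.

    ``pipeline`` is a :class:`molbalance.pipeline.PipelineSpec`-like object
    exposing ``name`` and ``fit(train_ds, train_fps, heldout_smiles) ->
    model`` where the returned model has ``predict_proba(FingerprintMatrix)``.
    The balancing strategy runs inside each fold on the training portion
    only; ``heldout_smiles`` lets the strategy (and the harness) assert that
    no augmented compound leaks into the held-out fold.  Each fold's model
    is evaluated on the held-out fold and on every external test surface.
    """
    rows: list[dict] = []
    for fold in range(folds.k):
        train_idx, held_idx = folds.fold_indices(ds, fold)
        train_ds = ds.select(train_idx)
        held_ds = ds.select(held_idx)
        train_fps = fps.subset_ids(train_ds.smiles)
        held_fps = fps.subset_ids(held_ds.smiles)
        model = pipeline.fit(train_ds, train_fps, heldout_smiles=held_ds.smiles_set())
        scores = model.predict_proba(held_fps)
        rows += _metric_rows(
            evaluate_predictions(held_ds.labels, scores, threshold),
            pipeline.name, pipeline.strategy, fold, "cv",
        )
        for surf_name, ext_ds, ext_fps in external_tests:
            ext_scores = model.predict_proba(ext_fps.subset_ids(ext_ds.smiles))
            rows += _metric_rows(
                evaluate_predictions(ext_ds.labels, ext_scores, threshold),
                pipeline.name, pipeline.strategy, fold, surf_name,
            )
    return EvaluationReport(
        table=pd.DataFrame(rows),
        metadata={"k": folds.k, "seed": folds.seed, "threshold": threshold},
    )
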