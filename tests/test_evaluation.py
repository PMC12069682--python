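"""Metrics, ROC AUC, the CV harness and the statistical comparison protocol."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from molbalance import (
    ComparisonResult,
    DNNConfig,
    compare_models,
    confusion,
    conover_friedman,
    cross_validate,
    declare_better,
    evaluate_predictions,
    friedman_test,
    metrics,
    stratified_kfold,
)
from molbalance.evaluation import EvaluationReport, roc_auc_from_scores
from molbalance.pipeline import PipelineSpec


class TestConfusion:
    def test_perfect_predictions(self):
        c = confusion([1, 1, 0, 0], [1, 1, 0, 0])
        assert (c.fp, c.fn) == (0, 0)

    def test_all_predicted_active(self):
        c = confusion([1, 0, 1, 0], [1, 1, 1, 1])
        assert (c.fn, c.tn) == (0, 0)

    def test_hand_case(self):
        truth = list("AAAAAIIIII")
        pred = list("AAAIIAIIII")
        c = confusion(
            ["active" if t == "A" else "inactive" for t in truth],
            ["active" if p == "A" else "inactive" for p in pred],
        )
        assert (c.tp, c.fn, c.fp, c.tn) == (3, 2, 1, 4)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            confusion([1, 0], [1])


class TestMetrics:
    def test_perfect_classifier(self):
        m = metrics(confusion([1, 0], [1, 0]))
        assert (m.sensitivity, m.specificity, m.gmean, m.mcc) == (1, 1, 1, 1)

    def test_hand_case_values(self):
        m = metrics(confusion([1] * 5 + [0] * 5, [1, 1, 1, 0, 0, 1, 0, 0, 0, 0]))
        assert m.sensitivity == pytest.approx(0.6)
        assert m.specificity == pytest.approx(0.8)
        assert m.mcc == pytest.approx(10 / math.sqrt(600))
        assert m.gmean == pytest.approx(math.sqrt(0.48))

    def test_single_class_truth(self):
        m = metrics(confusion([1, 1, 1], [1, 1, 1]), scores=[0.9, 0.8, 0.7], y_true=[1, 1, 1])
        assert m.accuracy == 1.0
        assert m.roc_auc is None

    def test_constant_predictor_has_zero_mcc(self):
        m = metrics(confusion([1, 0, 1, 0], [1, 1, 1, 1]))
        assert m.mcc == 0.0

    def test_gmean_bounded_by_max_component(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            y = rng.integers(0, 2, 30)
            p = rng.integers(0, 2, 30)
            m = metrics(confusion(y, p))
            assert m.gmean <= max(m.sensitivity, m.specificity) + 1e-12

    def test_threshold_tie_break_half_is_active(self):
        m = evaluate_predictions([1, 0], [0.5, 0.5])
        # both predicted active at exactly 0.5
        assert m.sensitivity == 1.0 and m.specificity == 0.0


class TestRocAuc:
    def test_matches_sklearn_with_ties(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(2)
        for _ in range(30):
            y = rng.integers(0, 2, 40)
            if y.sum() in (0, 40):
                continue
            s = np.round(rng.random(40), 1)  # coarse scores force ties
            assert roc_auc_from_scores(y, s) == pytest.approx(
                roc_auc_score(y, s), abs=1e-12
            )

    def test_one_class_is_missing(self):
        assert roc_auc_from_scores([1, 1], [0.2, 0.7]) is None


def dominant_model_table(seed=0):
    """4 models × 10 folds; model 0 strictly best in every fold."""
    rng = np.random.default_rng(seed)
    base = rng.random((10, 4)) * 0.1 + 0.5
    base[:, 0] += 0.3
    return base


class TestFriedman:
    def test_identical_columns(self):
        stat, p = friedman_test(np.ones((6, 4)))
        assert stat == 0.0 and p == 1.0

    def test_dominant_model_significant(self):
        stat, p = friedman_test(dominant_model_table())
        assert p < 0.05

    def test_matches_scipy(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            table = rng.random((8, 4))
            if rng.random() < 0.5:
                table = np.round(table, 1)  # introduce ties
            stat, p = friedman_test(table)
            ref_stat, ref_p = stats.friedmanchisquare(*table.T)
            assert stat == pytest.approx(ref_stat, abs=1e-9)
            assert p == pytest.approx(ref_p, abs=1e-9)

    def test_model_order_invariance(self):
        table = dominant_model_table()
        _, p1 = friedman_test(table)
        _, p2 = friedman_test(table[:, ::-1])
        assert p1 == pytest.approx(p2, abs=1e-12)

    def test_incomplete_matrix_rejected(self):
        table = dominant_model_table()
        table[0, 0] = np.nan
        with pytest.raises(ValueError, match="incomplete"):
            friedman_test(table)

    def test_too_few_models_or_folds(self):
        with pytest.raises(ValueError):
            friedman_test(np.ones((10, 2)))
        with pytest.raises(ValueError):
            friedman_test(np.ones((1, 4)))


def conover_oracle(table):
    """Independent literal transcription: the T1-factored variance form,
    algebraically equivalent to the implementation's rank-sum form."""
    table = np.asarray(table, float)
    n, k = table.shape
    r = np.vstack([stats.rankdata(row) for row in table])
    R = r.sum(axis=0)
    A1 = (r**2).sum()
    C1 = n * k * (k + 1) ** 2 / 4
    T1 = (k - 1) * ((R - n * (k + 1) / 2) ** 2).sum() / (A1 - C1)
    df = (n - 1) * (k - 1)
    var = 2 * n * (A1 - C1) / df * (1 - T1 / (n * (k - 1)))
    p = np.ones((k, k))
    for i in range(k):
        for j in range(k):
            if i != j:
                t = abs(R[i] - R[j]) / math.sqrt(var)
                p[i, j] = min(1.0, 2 * stats.t.sf(t, df))
    return p


class TestConover:
    def test_identical_columns_all_ones(self):
        p = conover_friedman(np.ones((6, 4)))
        assert np.all(p == 1.0)

    def test_symmetry_and_unit_diagonal(self):
        p = conover_friedman(dominant_model_table())
        assert np.array_equal(p, p.T)
        assert np.all(np.diag(p) == 1.0)

    def test_matches_independent_oracle(self):
        rng = np.random.default_rng(4)
        for _ in range(10):
            table = rng.random((10, 4))
            np.testing.assert_allclose(
                conover_friedman(table), conover_oracle(table), atol=1e-12
            )

    def test_dominant_model_p_values_are_minima(self):
        """The dominant model is the most distinguishable partner of every
        other model: p[0, j] is the column minimum for all j."""
        p = conover_friedman(dominant_model_table())
        for j in range(1, 4):
            others = [p[i, j] for i in range(4) if i not in (j, 0)]
            assert p[0, j] < min(others)
        assert p[0, 1:].max() < 0.05


class TestDeclareBetter:
    def _result(self, names, p, means):
        return ComparisonResult(
            model_names=tuple(names),
            friedman_statistic=0.0,
            friedman_p=0.0,
            posthoc_p=np.asarray(p, float),
            means=np.asarray(means, float),
        )

    def test_all_p_one_no_verdicts(self):
        names = ("a", "b", "c")
        res = {
            m: self._result(names, np.ones((3, 3)), [0.9, 0.5, 0.1])
            for m in ("mcc", "roc_auc", "gmean")
        }
        assert not any(declare_better(res).values())

    def test_two_of_three_metrics_is_not_enough(self):
        names = ("a", "b", "c")
        sig = np.full((3, 3), 0.001)
        np.fill_diagonal(sig, 1.0)
        res = {
            "mcc": self._result(names, sig, [0.9, 0.5, 0.1]),
            "roc_auc": self._result(names, sig, [0.9, 0.5, 0.1]),
            "gmean": self._result(names, np.ones((3, 3)), [0.9, 0.5, 0.1]),
        }
        assert not any(declare_better(res).values())

    def test_dominant_model_earns_all_its_verdicts(self):
        # models b, c, d are identical in every fold; only "best" stands out,
        # so only "best" may earn verdicts
        rng = np.random.default_rng(0)
        col = rng.random(10) * 0.1 + 0.5
        table = np.column_stack([col + 0.3, col, col, col])
        names = ("best", "b", "c", "d")
        res = {m: compare_models(table, names) for m in ("mcc", "roc_auc", "gmean")}
        verdicts = declare_better(res)
        winners = {a for (a, b), v in verdicts.items() if v}
        assert winners == {"best"}
        assert all(verdicts[("best", other)] for other in ("b", "c", "d"))

    def test_missing_metric_rejected(self):
        with pytest.raises(ValueError, match="missing"):
            declare_better({"mcc": None})


class TestCrossValidate:
    @pytest.fixture()
    def cv_report(self, small_dataset, small_fps):
        folds = stratified_kfold(small_dataset, 4, seed=0)
        pipe = PipelineSpec(model_kind="naive_bayes", strategy="none", seed=0)
        ext = [("ext", small_dataset, small_fps)]
        return cross_validate(pipe, small_dataset, small_fps, folds, ext), folds

    def test_grid_shape_complete(self, cv_report):
        report, folds = cv_report
        for surface in ("cv", "ext"):
            mat, names = report.metric_matrix("gmean", surface=surface)
            assert mat.shape == (folds.k, 1)

    def test_summary_has_all_metrics(self, cv_report):
        report, _ = cv_report
        assert set(report.table.metric) >= {"sensitivity", "specificity", "mcc", "roc_auc", "gmean", "accuracy"}

    def test_incomplete_grid_detected(self):
        rows = [
            {"model": m, "strategy": "none", "fold": f, "surface": "cv",
             "metric": "gmean", "value": 0.5}
            for m in ("a", "b") for f in range(3)
        ]
        del rows[-1]  # model "b" is missing fold 2
        with pytest.raises(ValueError, match="incomplete"):
            EvaluationReport(table=pd.DataFrame(rows)).metric_matrix("gmean", "cv")

    def test_augmentation_never_leaks_into_heldout(self, small_dataset, small_fps):
        """The pool deliberately contains held-out compounds; none may
        survive into the augmented training set."""
        from molbalance.datatypes import CompoundRecord

        folds = stratified_kfold(small_dataset, 3, seed=1)
        _, held = folds.fold_indices(small_dataset, 0)
        heldout_smiles = [small_dataset.smiles[i] for i in held]
        pool = [CompoundRecord(s, f"g{i}", "generated") for i, s in enumerate(heldout_smiles)]
        pipe = PipelineSpec(
            model_kind="naive_bayes", strategy="generator_augment",
            generator_pool=pool, seed=0,
        )
        train_idx, _ = folds.fold_indices(small_dataset, 0)
        train_ds = small_dataset.select(train_idx)
        aug_ds, _ = pipe._augmented_training_set(
            train_ds, small_fps.subset_ids(train_ds.smiles), frozenset(heldout_smiles)
        )
        assert not (aug_ds.smiles_set() & set(heldout_smiles))
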