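"""Transfer splits, SVM training, metrics, exact Wilcoxon, aggregation."""

import itertools

import numpy as np
import pytest
from scipy.stats import rankdata
from sklearn import metrics as skmetrics

from mibci.evaluation import (
    ConfusionMatrix,
    EvaluationError,
    TrainConfig,
    accuracy,
    aggregate_report,
    cohen_kappa,
    cst_split,
    evaluate,
    precision_recall,
    sst_split,
    train_model,
    wilcoxon_signed_rank_exact,
)
from mibci.features import FeatureMatrix


class _Sess:
    """Minimal labelled-session stand-in for split planning."""

    def __init__(self, labels, session_id, montage=("C3", "C4")):
        self.labels = np.asarray(labels)
        self.session_id = session_id
        self.montage = list(montage)


def _balanced(n_per_class, classes=("LH", "RH", "F", "T")):
    return np.repeat(classes, n_per_class)


class TestSplits:
    def test_sst_uses_whole_sessions(self):
        s1 = _Sess(_balanced(72), "S1")
        s2 = _Sess(_balanced(72), "S2")
        plan = sst_split(s1, s2)
        assert len(plan.train_ids) == 288 and len(plan.test_ids) == 288
        assert plan.test_ids.min() == 288

    def test_sst_requires_distinct_sessions_and_montages(self):
        s1 = _Sess(_balanced(2), "S1")
        with pytest.raises(EvaluationError):
            sst_split(s1, _Sess(_balanced(2), "S1"))
        with pytest.raises(EvaluationError):
            sst_split(s1, _Sess(_balanced(2), "S2", montage=("C3", "Cz")))

    def test_cst_balanced_floor_split(self):
        s1 = _Sess(_balanced(72), "S1")
        s2 = _Sess(_balanced(72), "S2")
        plan = cst_split(s1, s2, fraction=0.40)
        # floor(0.4 * 72) = 28 calibration epochs per class, 44 for test
        assert len(plan.train_ids) == 288 + 4 * 28
        assert len(plan.test_ids) == 4 * 44
        labels2 = np.asarray(s2.labels)
        calib = plan.train_ids[plan.train_ids >= 288] - 288
        for cls in ("LH", "RH", "F", "T"):
            cls_idx = np.flatnonzero(labels2 == cls)
            # chronologically first 28 of each class are calibration
            assert set(cls_idx[:28]) <= set(calib)

    def test_cst_degenerate_fraction_rejected(self):
        s1 = _Sess(_balanced(4), "S1")
        s2 = _Sess(_balanced(4), "S2")
        with pytest.raises(EvaluationError):
            cst_split(s1, s2, fraction=0.0)

    def test_cst_missing_class_rejected(self):
        s1 = _Sess(_balanced(4), "S1")
        s2 = _Sess(_balanced(4), "S2")
        s2.labels = np.where(s2.labels == "T", "F", s2.labels)
        with pytest.raises(EvaluationError):
            cst_split(s1, s2)

    def test_cst_disjoint_and_test_inside_session2(self, rng):
        for _ in range(20):
            n1 = int(rng.integers(3, 8))
            n2 = int(rng.integers(3, 8))
            frac = float(rng.uniform(0.1, 0.9))
            s1 = _Sess(_balanced(n1), "S1")
            s2 = _Sess(rng.permutation(_balanced(n2)), "S2")
            plan = cst_split(s1, s2, fraction=frac)
            assert np.intersect1d(plan.train_ids, plan.test_ids).size == 0
            assert plan.test_ids.min() >= 4 * n1
            assert set(plan.train_ids) | set(plan.test_ids) == set(
                range(4 * n1 + 4 * n2)
            )


def _feature_matrix(rng, n_per_class=12, separable=True):
    classes = ["LH", "RH", "F", "T"]
    rows, labels = [], []
    for k, cls in enumerate(classes):
        centre = np.zeros(6)
        if separable:
            centre[k] = 5.0
        rows.append(rng.normal(centre, 0.3, size=(n_per_class, 6)))
        labels += [cls] * n_per_class
    return FeatureMatrix(
        values=np.vstack(rows),
        tags=[f"f{j}" for j in range(6)],
        labels=np.array(labels),
    )


FAST = TrainConfig(c_grid=(1.0,), gamma_grid=(0.1,), s_grid=(6,), n_folds=4)


class TestTrainModel:
    def test_separable_features_reach_full_validation_accuracy(self, rng):
        model = train_model(_feature_matrix(rng), FAST)
        assert model.validation_accuracy == 100.0

    def test_shuffled_labels_fall_to_chance(self, rng):
        fm = _feature_matrix(rng)
        fm = FeatureMatrix(
            values=fm.values,
            tags=fm.tags,
            labels=np.random.default_rng(3).permutation(fm.labels),
        )
        model = train_model(fm, FAST)
        n = fm.n_epochs
        half_width = 100 * 2.576 * np.sqrt(0.25 * 0.75 / n)
        assert abs(model.validation_accuracy - 25.0) <= half_width

    def test_deterministic_hyperparameter_choice(self, rng):
        fm = _feature_matrix(rng)
        cfg = TrainConfig(c_grid=(0.5, 2.0), gamma_grid=(0.05, 0.5), s_grid=(3, 6), n_folds=4)
        a = train_model(fm, cfg)
        b = train_model(fm, cfg)
        assert (a.c, a.gamma, a.s) == (b.c, b.gamma, b.s)
        assert a.validation_accuracy == b.validation_accuracy

    def test_class_too_small_for_folds_rejected(self, rng):
        fm = _feature_matrix(rng, n_per_class=3)
        with pytest.raises(EvaluationError):
            train_model(fm, TrainConfig(n_folds=10))


class TestEvaluate:
    def test_train_equals_test_on_separable_data_is_diagonal(self, rng):
        fm = _feature_matrix(rng)
        model = train_model(fm, FAST)
        cm = evaluate(model, fm)
        assert np.trace(cm.counts) == cm.total

    def test_three_class_mode_gives_3x3_matrix(self, rng):
        fm = _feature_matrix(rng)
        keep = fm.labels != "T"
        fm3 = FeatureMatrix(values=fm.values[keep], tags=fm.tags, labels=fm.labels[keep])
        model = train_model(fm3, FAST)
        cm = evaluate(model, fm3)
        assert cm.counts.shape == (3, 3)

    def test_empty_test_rejected(self, rng):
        model = train_model(_feature_matrix(rng), FAST)
        empty = FeatureMatrix(
            values=np.empty((0, 6)), tags=[f"f{j}" for j in range(6)],
            labels=np.array([], dtype=str),
        )
        with pytest.raises(EvaluationError):
            evaluate(model, empty)


def _cm(counts):
    counts = np.asarray(counts)
    return ConfusionMatrix(counts=counts, classes=np.arange(counts.shape[0]))


class TestMetrics:
    def test_diagonal_matrix_is_perfect(self):
        cm = _cm(np.diag([10, 12, 8, 9]))
        assert accuracy(cm) == 100.0
        assert cohen_kappa(cm) == pytest.approx(1.0)
        assert precision_recall(cm) == (1.0, 1.0)

    def test_uniform_confusion_is_chance(self):
        cm = _cm(np.full((4, 4), 5))
        assert accuracy(cm) == 25.0
        assert cohen_kappa(cm) == pytest.approx(0.0)

    def test_binary_worked_example(self):
        cm = _cm([[30, 10], [10, 30]])
        assert accuracy(cm) == 75.0
        assert cohen_kappa(cm) == pytest.approx(0.5)
        prec, rec = precision_recall(cm)
        assert prec == pytest.approx(0.75) and rec == pytest.approx(0.75)

    def test_never_predicted_class_contributes_zero_precision(self):
        cm = _cm([[5, 0], [5, 0]])
        prec, rec = precision_recall(cm)
        assert prec == pytest.approx(0.25)  # (0.5 + 0) / 2
        assert rec == pytest.approx(0.5)

    def test_degenerate_single_cell_kappa_rejected(self):
        with pytest.raises(EvaluationError):
            cohen_kappa(_cm([[7]]))

    def test_matches_sklearn_on_random_confusions(self, rng):
        """Independent cross-check of all three metrics against sklearn
        on reconstructed label vectors."""
        for _ in range(10):
            counts = rng.integers(0, 12, size=(4, 4))
            if counts.sum() == 0 or np.trace(counts) == counts.sum():
                continue
            y_true, y_pred = [], []
            for i, j in itertools.product(range(4), range(4)):
                y_true += [i] * counts[i, j]
                y_pred += [j] * counts[i, j]
            cm = _cm(counts)
            assert accuracy(cm) == pytest.approx(
                100 * skmetrics.accuracy_score(y_true, y_pred)
            )
            assert cohen_kappa(cm) == pytest.approx(
                skmetrics.cohen_kappa_score(y_true, y_pred)
            )
            prec, rec = precision_recall(cm)
            assert prec == pytest.approx(
                skmetrics.precision_score(y_true, y_pred, average="macro", zero_division=0)
            )
            assert rec == pytest.approx(
                skmetrics.recall_score(y_true, y_pred, average="macro", zero_division=0)
            )

    def test_kappa_is_one_iff_off_diagonal_empty(self, rng):
        cm = _cm(np.diag([3, 4, 5]) + np.array([[0, 1, 0], [0, 0, 0], [0, 0, 0]]))
        assert cohen_kappa(cm) < 1.0


def wilcoxon_oracle(a, b):
    """Brute-force enumeration of all sign assignments."""
    d = np.asarray(b, dtype=float) - np.asarray(a, dtype=float)
    d = d[d != 0]
    if d.size == 0:
        return 1.0
    ranks = rankdata(np.abs(d))
    w_obs = min(ranks[d > 0].sum(), ranks[d < 0].sum())
    total = ranks.sum()
    count = 0
    n_assign = 0
    for signs in itertools.product([0, 1], repeat=d.size):
        w_pos = sum(r for r, s in zip(ranks, signs) if s)
        n_assign += 1
        if w_pos <= w_obs + 1e-9 or w_pos >= total - w_obs - 1e-9:
            count += 1
    return count / n_assign


class TestWilcoxon:
    def test_single_nonzero_pair_gives_p_one(self):
        _, p = wilcoxon_signed_rank_exact([1.0], [2.0])
        assert p == 1.0

    def test_all_zero_differences_warn_and_return_one(self):
        with pytest.warns(UserWarning):
            _, p = wilcoxon_signed_rank_exact([1.0, 2.0], [1.0, 2.0])
        assert p == 1.0

    def test_nine_uniform_improvements(self):
        # all differences positive, n = 9: p = 2 / 2^9
        a = np.arange(9, dtype=float)
        _, p = wilcoxon_signed_rank_exact(a, a + 1.0)
        assert p == pytest.approx(2 / 512)

    def test_matches_enumeration_oracle_for_all_small_n(self, rng):
        for n in range(1, 13):
            for _ in range(4):
                a = rng.integers(-5, 6, size=n).astype(float)
                b = rng.integers(-5, 6, size=n).astype(float)
                if np.all(a == b):
                    continue
                _, p = wilcoxon_signed_rank_exact(a, b)
                assert p == pytest.approx(wilcoxon_oracle(a, b), abs=1e-12)

    def test_ties_use_midranks(self):
        # |d| = (1, 1, 2, 2): midranks (1.5, 1.5, 3.5, 3.5)
        a = np.zeros(4)
        b = np.array([1.0, -1.0, 2.0, 2.0])
        w, p = wilcoxon_signed_rank_exact(a, b)
        assert w == 1.5
        assert p == pytest.approx(wilcoxon_oracle(a, b))

    def test_out_of_range_n_rejected(self):
        with pytest.raises(EvaluationError):
            wilcoxon_signed_rank_exact(np.zeros(26), np.ones(26))


class TestAggregateReport:
    def test_mean_and_sample_sd(self):
        report = aggregate_report(
            {
                "s1": {"acc": 50.0, "kappa": 0.2},
                "s2": {"acc": 60.0, "kappa": 0.4},
                "s3": {"acc": 70.0, "kappa": 0.6},
            }
        )
        assert report.mean["acc"] == pytest.approx(60.0)
        assert report.sd["acc"] == pytest.approx(10.0)  # ddof = 1

    def test_single_subject_sd_missing(self):
        report = aggregate_report({"s1": {"acc": 50.0}})
        assert np.isnan(report.sd["acc"])

    def test_identical_subjects_sd_zero(self):
        report = aggregate_report({f"s{i}": {"acc": 42.0} for i in range(5)})
        assert report.sd["acc"] == 0.0

    def test_empty_rejected(self):
        with pytest.raises(EvaluationError):
            aggregate_report({})
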