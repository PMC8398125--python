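import datetime as dt

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from adlseq.benchmarks import (
    ARUBA_CV_WITH_CONTEXT,
    ARUBA_CV_WITHOUT_PREV,
    ARUBA_HOLDOUT,
    ARUBA_SEQUENTIAL,
)
from adlseq.casas_io import ActivityInstance, SensorEvent, segment_activities
from adlseq.evaluation import (
    confusion_counts,
    cross_validate,
    evaluate_holdout,
    evaluate_sequential,
    metrics_from_confusion,
    stratified_folds,
)
from adlseq.features import build_vocabulary, encode_dataset, encode_instance
from adlseq.model import Model, ModelSpec, build_model, predict, train_model
from adlseq.preprocessing import CLASS_ORDER, Dataset, attach_context, select_classes
from adlseq.synthetic_data import default_sim_config, simulate_log


class TestStratifiedFolds:
    def test_balanced_partition(self):
        labels = np.repeat(np.arange(9), 60)
        folds = stratified_folds(labels, k=10, seed=0)
        assert len(folds) == 10
        for f in folds:
            assert len(f) == 54  # 6 per class
            counts = np.bincount(labels[f], minlength=9)
            assert (counts == 6).all()
        union = np.concatenate(folds)
        assert len(union) == 540 and len(np.unique(union)) == 540

    def test_train_side_count(self):
        labels = np.repeat(np.arange(9), 60)
        folds = stratified_folds(labels, k=10, seed=3)
        train = np.setdiff1d(np.arange(540), folds[0])
        assert (np.bincount(labels[train], minlength=9) == 54).all()

    def test_reproducible_given_seed(self):
        labels = np.repeat(np.arange(4), 12)
        f1 = stratified_folds(labels, k=4, seed=9)
        f2 = stratified_folds(labels, k=4, seed=9)
        assert all(np.array_equal(a, b) for a, b in zip(f1, f2))

    def test_class_smaller_than_k_errors(self):
        with pytest.raises(ValueError, match="fewer than k"):
            stratified_folds([0] * 20 + [1] * 3, k=5)


class TestMetrics:
    def test_identity_confusion_is_perfect(self):
        report = metrics_from_confusion(np.eye(9))
        assert np.allclose(report.per_class[["precision", "recall",
                                             "specificity", "f1"]], 1.0)
        assert np.allclose(report.per_class["error"], 0.0)

    def test_published_aruba_cv_with_context(self):
        report = metrics_from_confusion(ARUBA_CV_WITH_CONTEXT)
        assert report.macro["f1"] == pytest.approx(0.917, abs=0.002)
        enter = report.per_class.loc["Enter_Home"]
        assert enter["precision"] == pytest.approx(0.997, abs=0.001)
        assert enter["recall"] == pytest.approx(1.000, abs=0.001)
        assert enter["f1"] == pytest.approx(0.998, abs=0.001)
        assert report.macro["accuracy"] == pytest.approx(98.148, abs=0.05)

    def test_published_aruba_cv_without_prev(self):
        report = metrics_from_confusion(ARUBA_CV_WITHOUT_PREV)
        assert report.macro["f1"] == pytest.approx(0.734, abs=0.002)

    def test_published_holdout_and_sequential_recall(self):
        # rows of the printed matrices are rounded to 3 decimals, so recall
        # (TP / row sum) may differ from the raw diagonal in the 4th decimal
        assert ARUBA_HOLDOUT.diagonal().mean() == pytest.approx(0.923, abs=0.0005)
        assert ARUBA_SEQUENTIAL.diagonal().mean() == pytest.approx(0.927, abs=0.0005)
        assert metrics_from_confusion(ARUBA_HOLDOUT).macro["recall"] == pytest.approx(
            0.923, abs=0.001
        )
        assert metrics_from_confusion(ARUBA_SEQUENTIAL).macro["recall"] == pytest.approx(
            0.927, abs=0.001
        )

    @settings(deadline=None, max_examples=40)
    @given(st.integers(0, 2**32 - 1), st.integers(2, 6), st.integers(20, 120))
    def test_agrees_with_per_sample_tally(self, seed, n_classes, n):
        rng = np.random.default_rng(seed)
        y_true = rng.integers(0, n_classes, size=n)
        y_pred = rng.integers(0, n_classes, size=n)
        # ensure every class occurs so no macro row is dropped
        y_true[:n_classes] = np.arange(n_classes)
        M = confusion_counts(y_true, y_pred, n_classes)
        report = metrics_from_confusion(M, class_order=[str(c) for c in range(n_classes)])
        for j in range(n_classes):
            tp = np.sum((y_true == j) & (y_pred == j))
            fp = np.sum((y_true != j) & (y_pred == j))
            fn = np.sum((y_true == j) & (y_pred != j))
            tn = n - tp - fp - fn
            row = report.per_class.iloc[j]
            assert row["precision"] == pytest.approx(tp / (tp + fp) if tp + fp else 0.0)
            assert row["recall"] == pytest.approx(tp / (tp + fn) if tp + fn else 0.0)
            assert row["specificity"] == pytest.approx(tn / (tn + fp) if tn + fp else 0.0)
            assert row["accuracy"] == pytest.approx((tp + tn) / n * 100)

    @settings(deadline=None, max_examples=30)
    @given(st.integers(0, 2**32 - 1))
    def test_metric_identities(self, seed):
        rng = np.random.default_rng(seed)
        M = rng.integers(0, 30, size=(9, 9)) + np.eye(9, dtype=int)
        report = metrics_from_confusion(M)
        assert np.allclose(report.confusion.sum(axis=1), 1.0, atol=1e-9)
        assert np.allclose(report.per_class["accuracy"] + report.per_class["error"], 100.0)
        pc = report.per_class
        nz = pc["precision"] + pc["recall"] > 0
        expected_f1 = 2 * pc["precision"] * pc["recall"] / (pc["precision"] + pc["recall"])
        assert np.allclose(pc["f1"][nz], expected_f1[nz])
        assert report.counts.sum() == M.sum()

    def test_invalid_matrices_rejected(self):
        with pytest.raises(ValueError, match="square"):
            metrics_from_confusion(np.ones((3, 4)), class_order=list("abc"))
        with pytest.raises(ValueError, match="non-negative"):
            metrics_from_confusion(-np.eye(9))


@pytest.fixture(scope="module")
def small_pool():
    events = simulate_log(default_sim_config(n_days=40, seed=17))
    pool = select_classes(
        Dataset(attach_context(segment_activities(events))), CLASS_ORDER
    )
    return pool, build_vocabulary(events)


SMALL_SPEC = ModelSpec(recurrent_nodes=6, hidden_units=8, epochs=2, seed=1)


class TestCrossValidate:
    def test_single_repeat_two_fold_matches_direct_computation(self, small_pool):
        pool, vocab = small_pool
        n = min(pool.counts().values())
        result = cross_validate(pool, SMALL_SPEC, vocab, n_per_class=n, k=2,
                                repeats=1, seed=5)
        assert result.report.counts.sum() == n * 9
        assert result.report.n_folds == 2 and result.report.n_repeats == 1

    def test_fixed_seed_reproducible(self, small_pool):
        pool, vocab = small_pool
        n = min(pool.counts().values())
        r1 = cross_validate(pool, SMALL_SPEC, vocab, n_per_class=n, k=2, repeats=1, seed=5)
        r2 = cross_validate(pool, SMALL_SPEC, vocab, n_per_class=n, k=2, repeats=1, seed=5)
        assert np.array_equal(r1.report.counts, r2.report.counts)

    def test_confusion_conservation_over_repeats(self, small_pool):
        pool, vocab = small_pool
        n = min(pool.counts().values())
        result = cross_validate(pool, SMALL_SPEC, vocab, n_per_class=n, k=2,
                                repeats=2, seed=5)
        assert result.report.counts.sum() == 2 * n * 9


class TestHoldout:
    def test_perfect_model_oracle(self, small_pool):
        pool, vocab = small_pool

        class Oracle:
            spec = SMALL_SPEC
        # build a tiny holdout report through a real model but checking only
        # conservation; the perfect-model property is covered in sequential
        n = min(pool.counts().values())
        result = cross_validate(pool, SMALL_SPEC, vocab, n_per_class=n, k=2,
                                repeats=1, seed=5, keep_models=True)
        report = evaluate_holdout(result.models[0], result.remainings[0], vocab)
        n_models = len(result.models[0])
        assert report.counts.sum() == n_models * len(result.remainings[0])

    def test_empty_remaining_errors(self, small_pool):
        pool, vocab = small_pool
        model = build_model(SMALL_SPEC, len(vocab))
        with pytest.raises(ValueError, match="empty"):
            evaluate_holdout([model], Dataset([], CLASS_ORDER), vocab)


class _FixedPredictionModel(Model):
    """Test double: predicts a fixed label sequence regardless of input."""

    def __init__(self, spec, vocab_size, outputs):
        super().__init__(spec, vocab_size)
        self._outputs = list(outputs)
        self._cursor = 0

    def forward_batch(self, tokens, P, ts, train=False):
        n = tokens.shape[0]
        out = np.full((n, self.spec.n_classes), 0.1)
        for r in range(n):
            out[r, self._outputs[self._cursor]] = 0.9
            self._cursor += 1
        return out


class _OracleModel(Model):
    """Test double: always predicts the true class (communicated per call)."""

    def __init__(self, spec, vocab_size, truths):
        super().__init__(spec, vocab_size)
        self._truths = iter(truths)

    def forward_batch(self, tokens, P, ts, train=False):
        out = np.full((tokens.shape[0], self.spec.n_classes), 0.1)
        for r in range(out.shape[0]):
            out[r, next(self._truths)] = 0.9
        return out


class TestSequential:
    def _stream(self, labels, start=dt.datetime(2011, 1, 3, 21, 0), step_hours=3):
        instances = []
        for j, label in enumerate(labels):
            t0 = start + dt.timedelta(hours=j * step_hours)
            events = [
                SensorEvent(t0, "M001", "ON", label, "begin"),
                SensorEvent(t0 + dt.timedelta(seconds=5), "M001", "OFF", label, "end"),
            ]
            instances.append(ActivityInstance(label, events))
        return attach_context(instances)

    def test_oracle_model_reduces_to_ground_truth_context(self, small_pool):
        _, vocab = small_pool
        labels = ["Sleeping", "Bed_to_Toilet", "Sleeping", "Meal_Preparation",
                  "Eating", "Relax", "Leave_Home", "Enter_Home"]
        instances = self._stream(labels)
        truths = [CLASS_ORDER.index(l) for l in labels]
        model = _OracleModel(SMALL_SPEC, len(vocab), truths)
        report = evaluate_sequential(model, instances, vocab)
        assert np.allclose(np.diag(report.confusion)[np.array(truths)], 1.0)
        assert report.counts.sum() == len(labels)
        assert report.macro["recall"] == 1.0

    def test_prediction_error_propagates_to_next_context(self, small_pool):
        _, vocab = small_pool
        labels = ["Sleeping", "Relax", "Eating"]
        instances = self._stream(labels)
        # predict instance 2 wrongly as Work; instance 3 correctly
        outputs = [CLASS_ORDER.index("Sleeping"), CLASS_ORDER.index("Work"),
                   CLASS_ORDER.index("Eating")]
        seen_prev = []

        class Spy(_FixedPredictionModel):
            def forward_batch(self, tokens, P, ts, train=False):
                seen_prev.append(P[0].copy())
                return super().forward_batch(tokens, P, ts, train)

        model = Spy(SMALL_SPEC, len(vocab), outputs)
        evaluate_sequential(model, instances, vocab)
        # third instance received the erroneous "Work" one-hot, not "Relax"
        assert seen_prev[2][CLASS_ORDER.index("Work")] == 1.0
        assert seen_prev[2][CLASS_ORDER.index("Relax")] == 0.0

    def test_weekly_periods_reanchor_on_sleeping(self, small_pool):
        _, vocab = small_pool
        # 10 days of one instance per day: period must extend past the 7-day
        # boundary until the next Sleeping instance (day 9)
        labels = ["Sleeping"] + ["Relax"] * 7 + ["Sleeping", "Relax"]
        instances = self._stream(labels, step_hours=24)
        truths = [CLASS_ORDER.index(l) for l in labels]
        # oracle consumed per period in order: period 1 = first 9, period 2 = last 2
        model = _OracleModel(SMALL_SPEC, len(vocab), truths)
        report = evaluate_sequential(model, instances, vocab)
        assert report.counts.sum() == len(labels)

    def test_short_period_skipped_with_warning(self, small_pool):
        _, vocab = small_pool
        instances = self._stream(["Relax"])
        model = _FixedPredictionModel(SMALL_SPEC, len(vocab), [3])
        with pytest.warns(UserWarning, match="skipped"):
            report = evaluate_sequential(model, instances, vocab)
        assert report.counts.sum() == 0
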