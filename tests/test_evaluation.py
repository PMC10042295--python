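import numpy as np
import pytest

from ecg2img.errors import (
    LeakageError,
    ProtocolError,
    SamplingError,
    ShapeError,
    UndefinedMetricError,
)
from ecg2img.evaluation import (
    PredictionResult,
    aggregate_patient,
    confusion_and_rates,
    make_folds,
    roc_auc,
    run_cross_validation,
    score_report,
    undersample_majority,
)
from ecg2img.model import ImageDataset, ImageItem

from _oracles import confusion_counts, mann_whitney_auc


def fake_results(true_labels, predicted_labels, probs=None):
    probs = probs if probs is not None else [float(p) for p in predicted_labels]
    return [PredictionResult(patient_id=f"p{i}",
                             per_image_probs=(q, q, q),
                             aggregated_prob=q,
                             predicted_label=int(pl), true_label=int(tl))
            for i, (tl, pl, q) in enumerate(zip(true_labels,
                                                predicted_labels, probs))]


class TestUndersample:
    def test_sample_size_and_uniqueness(self):
        ids = [f"s{i}" for i in range(9457)]
        picked = undersample_majority(ids, 291, seed=0)
        assert len(picked) == 291
        assert len(set(picked)) == 291
        assert set(picked) <= set(ids)

    def test_identity_when_equal(self):
        ids = [f"s{i}" for i in range(10)]
        assert sorted(undersample_majority(ids, 10, seed=1)) == sorted(ids)

    def test_seed_determinism_and_variation(self):
        ids = [f"s{i}" for i in range(1000)]
        a = undersample_majority(ids, 100, seed=5)
        b = undersample_majority(ids, 100, seed=5)
        c = undersample_majority(ids, 100, seed=6)
        assert a == b
        assert a != c

    def test_oversample_rejected(self):
        with pytest.raises(SamplingError):
            undersample_majority(["a"], 2, seed=0)


class TestMakeFolds:
    def test_group_sizes_582(self):
        ids = [f"p{i}" for i in range(582)]
        folds = make_folds(ids, k=10, seed=0)
        sizes = sorted(np.bincount(list(folds.group_of.values())).tolist())
        assert sizes == [58] * 8 + [59] * 2

    def test_every_patient_tested_exactly_once(self):
        ids = [f"p{i}" for i in range(95)]
        folds = make_folds(ids, k=10, seed=3)
        tested = []
        for f in range(10):
            tested.extend(folds.fold_patients(f)["test"])
        assert sorted(tested) == sorted(ids)

    def test_roles_disjoint_and_cover(self):
        ids = [f"p{i}" for i in range(57)]
        folds = make_folds(ids, k=10, seed=2)
        for f in range(10):
            roles = folds.fold_patients(f)
            all_ids = roles["train"] + roles["val"] + roles["test"]
            assert sorted(all_ids) == sorted(ids)
            assert not set(roles["train"]) & set(roles["val"])
            assert not set(roles["train"]) & set(roles["test"])
            assert not set(roles["val"]) & set(roles["test"])
            assert len(roles["train"]) >= len(roles["val"])

    def test_k_too_small(self):
        with pytest.raises(ProtocolError):
            make_folds(["a", "b", "c"], k=2, seed=0)


class TestAggregatePatient:
    @pytest.mark.parametrize("probs, mean, label", [
        ((0.2, 0.4, 0.6), 0.4, 0),
        ((1.0, 1.0, 1.0), 1.0, 1),
        ((0.5, 0.5, 0.5), 0.5, 1),  # tie at threshold classifies positive
    ])
    def test_mean_and_threshold(self, probs, mean, label):
        res = aggregate_patient(probs, threshold=0.5)
        assert res.aggregated_prob == pytest.approx(mean)
        assert res.predicted_label == label

    def test_order_invariance(self, rng):
        probs = rng.uniform(0, 1, 3)
        a = aggregate_patient(tuple(probs))
        b = aggregate_patient(tuple(probs[::-1]))
        assert a.aggregated_prob == pytest.approx(b.aggregated_prob)
        assert a.predicted_label == b.predicted_label

    def test_wrong_count(self):
        with pytest.raises(ShapeError):
            aggregate_patient((0.5, 0.5))


class TestConfusionAndRates:
    def test_constructed_confusion_matrix(self):
        # 44 TP, 14 FN, 46 TN, 12 FP  ->  75.86 / 79.31 / 77.59
        t = [1] * 58 + [0] * 58
        p = [1] * 44 + [0] * 14 + [0] * 46 + [1] * 12
        rep = confusion_and_rates(fake_results(t, p))
        assert (rep.tps, rep.fns, rep.tns, rep.fps) == (44, 14, 46, 12)
        assert rep.sensitivity == pytest.approx(75.862, abs=1e-2)
        assert rep.specificity == pytest.approx(79.310, abs=1e-2)
        assert rep.accuracy == pytest.approx(77.586, abs=1e-2)

    def test_matches_brute_force_on_random_sets(self, rng):
        for _ in range(100):
            n = int(rng.integers(2, 60))
            t = rng.integers(0, 2, n)
            p = rng.integers(0, 2, n)
            rep = confusion_and_rates(fake_results(t, p))
            tp, tn, fp, fn = confusion_counts(t, p)
            assert (rep.tps, rep.tns, rep.fps, rep.fns) == (tp, tn, fp, fn)
            assert rep.n_patients == n
            if tp + fn:
                assert rep.sensitivity == pytest.approx(tp / (tp + fn) * 100)
            if tn + fp:
                assert rep.specificity == pytest.approx(tn / (tn + fp) * 100)
            assert rep.accuracy == pytest.approx((tp + tn) / n * 100)

    def test_all_correct(self):
        rep = confusion_and_rates(fake_results([0, 1, 1], [0, 1, 1]))
        assert (rep.sensitivity, rep.specificity, rep.accuracy) == \
            (100.0, 100.0, 100.0)

    def test_half_sensitivity(self):
        rep = confusion_and_rates(fake_results([1, 1, 0], [1, 0, 0]))
        assert rep.sensitivity == 50.0

    def test_undefined_sensitivity_flagged(self):
        rep = confusion_and_rates(fake_results([0, 0], [0, 1]))
        assert rep.sensitivity is None
        assert "sensitivity" in rep.undefined_metrics


class TestRocAuc:
    def test_perfect_separation(self):
        points, area = roc_auc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1])
        assert area == 1.0
        assert points[0] == (0.0, 0.0)
        assert points[-1] == (1.0, 1.0)

    def test_chance_level_on_random_labels(self):
        rng = np.random.default_rng(0)
        scores = rng.uniform(0, 1, 4000)
        labels = rng.integers(0, 2, 4000)
        _, area = roc_auc(scores, labels)
        assert abs(area - 0.5) < 0.05

    def test_matches_mann_whitney_oracle(self, rng):
        for trial in range(60):
            n = int(rng.integers(4, 21))
            labels = np.zeros(n, dtype=int)
            labels[:max(1, n // 3)] = 1
            rng.shuffle(labels)
            if trial % 2 == 0:
                scores = rng.uniform(0, 1, n)  # tie-free a.s.
            else:
                scores = rng.integers(0, 4, n) / 3.0  # heavy ties
            _, area = roc_auc(scores, labels)
            assert area == pytest.approx(mann_whitney_auc(scores, labels),
                                         abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(UndefinedMetricError):
            roc_auc([0.1, 0.9], [1, 1])

    def test_monotone_transform_invariance(self, rng):
        scores = rng.uniform(0, 1, 50)
        labels = rng.integers(0, 2, 50)
        labels[0], labels[1] = 0, 1
        _, a1 = roc_auc(scores, labels)
        _, a2 = roc_auc(np.exp(3 * scores), labels)
        assert a1 == pytest.approx(a2, abs=1e-12)


class _ConstantModel:
    """Scores a deterministic pseudo-random value per image; no training."""

    def __init__(self, fold):
        self.fold = fold

    def prepare(self, x):
        return np.asarray(x, dtype=np.float64)

    def forward(self, x):
        n = x.shape[0]
        h = x.reshape(n, -1).sum(axis=1) % 7.0
        return np.stack([np.zeros(n), h - 3.0], axis=1)

    def backward(self, grad):
        return grad

    def trainable_params(self):
        return [np.zeros(1)]

    def trainable_grads(self):
        return [np.zeros(1)]

    def predict_proba(self, images, batch_size=32):
        from ecg2img.nn import softmax
        return softmax(self.forward(self.prepare(images)))


class TestCrossValidation:
    def _dataset(self, n_patients, seed=0):
        rng = np.random.default_rng(seed)
        items = []
        for p in range(n_patients):
            label = p % 2
            for k in range(3):
                img = rng.integers(0, 256, (224, 224)).astype(np.uint8)
                items.append(ImageItem(image=img, patient_id=f"p{p:03d}",
                                       segment_index=k, label=label))
        return ImageDataset(items=items)

    def test_protocol_with_cheap_model(self):
        from ecg2img.model import TrainConfig
        ds = self._dataset(40)
        res = run_cross_validation(
            ds, TrainConfig(epochs=1), k=10, seed=1,
            model_factory=lambda f: _ConstantModel(f))
        assert len(res.fold_reports) == 10
        tested = [r.patient_id for fold in res.fold_results for r in fold]
        assert sorted(tested) == sorted(ds.patient_ids)
        accs = [r.accuracy for r in res.fold_reports]
        assert res.mean_accuracy == pytest.approx(float(np.mean(accs)))

    def test_pooled_counts_cover_cohort(self):
        from ecg2img.model import TrainConfig
        ds = self._dataset(30)
        res = run_cross_validation(
            ds, TrainConfig(epochs=1), k=10, seed=2,
            model_factory=lambda f: _ConstantModel(f))
        assert res.pooled_report.n_patients == 30
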