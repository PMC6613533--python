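"""Pixel classifier, thresholding baseline and validation metrics."""

import numpy as np
import pytest

import scaffdeg as sd

from conftest import (
    STANDARD_BAND_LABELS,
    STANDARD_CUTS,
    table2_package_order,
)


class TestSampleTrainingPixels:
    def test_balanced_sample(self, noiseless_stack, noiseless_fixture):
        _, mask = noiseless_fixture
        ts = sd.sample_training_pixels(noiseless_stack, mask, 100, seed=1)
        assert ts.X.shape == (400, 24)
        counts = np.bincount(ts.y, minlength=4)
        assert np.all(counts == 100)

    def test_same_seed_identical(self, noiseless_stack, noiseless_fixture):
        _, mask = noiseless_fixture
        a = sd.sample_training_pixels(noiseless_stack, mask, 50, seed=3)
        b = sd.sample_training_pixels(noiseless_stack, mask, 50, seed=3)
        assert np.array_equal(a.coords, b.coords)
        assert np.array_equal(a.y, b.y)

    def test_scarce_class_is_clamped(self, noiseless_stack, noiseless_fixture):
        _, mask = noiseless_fixture
        scarce = mask.copy()
        keep = np.argwhere(scarce == sd.LABEL_NUCLEI)[:37]
        scarce[scarce == sd.LABEL_NUCLEI] = sd.LABEL_ECM
        scarce[tuple(keep.T)] = sd.LABEL_NUCLEI
        ts = sd.sample_training_pixels(noiseless_stack, scarce, 100, seed=1)
        assert np.count_nonzero(ts.y == sd.LABEL_NUCLEI) == 37

    def test_missing_class_strict_raises(self, noiseless_stack,
                                         noiseless_fixture):
        _, mask = noiseless_fixture
        no_nuclei = np.where(mask == sd.LABEL_NUCLEI, sd.LABEL_ECM, mask)
        with pytest.raises(sd.ValidationError, match="nuclei"):
            sd.sample_training_pixels(noiseless_stack, no_nuclei, 10, seed=1)


@pytest.fixture(scope="module")
def trained(noiseless_stack, noiseless_fixture):
    _, mask = noiseless_fixture
    ts = sd.sample_training_pixels(noiseless_stack, mask, 200, seed=2)
    model = sd.RandomForestPixelSegmenter(n_trees=100, random_state=2).fit(ts)
    return model, ts


class TestClassifier:
    def test_training_accuracy_perfect_on_separable_data(self, trained):
        model, ts = trained
        assert (model.predict(ts.X) == ts.y).mean() == 1.0

    def test_deterministic_predictions(self, noiseless_stack,
                                       noiseless_fixture):
        _, mask = noiseless_fixture
        ts = sd.sample_training_pixels(noiseless_stack, mask, 100, seed=5)
        preds = [
            sd.RandomForestPixelSegmenter(n_trees=50, random_state=5)
            .fit(ts).predict_probability_maps(noiseless_stack)
            for _ in range(2)
        ]
        assert np.array_equal(preds[0], preds[1])

    def test_feature_name_mismatch_rejected(self, trained, noiseless_stack):
        model, _ = trained
        bad = sd.FeatureStack(
            data=noiseless_stack.data,
            feature_names=tuple(reversed(noiseless_stack.feature_names)))
        with pytest.raises(sd.ValidationError):
            model.predict_probability_maps(bad)

    def test_probability_maps_normalize(self, trained, noiseless_stack):
        model, _ = trained
        maps = model.predict_probability_maps(noiseless_stack)
        assert maps.shape == noiseless_stack.data.shape[:2] + (4,)
        np.testing.assert_allclose(maps.sum(axis=2), 1.0, atol=1e-9)
        assert maps.min() >= 0 and maps.max() <= 1

    def test_interior_pixels_get_confident_votes(self, trained,
                                                 noiseless_stack,
                                                 noiseless_fixture):
        from scipy.ndimage import binary_erosion

        model, _ = trained
        _, mask = noiseless_fixture
        maps = model.predict_probability_maps(noiseless_stack)
        deep = binary_erosion(mask == sd.LABEL_COLLAGEN, iterations=6)
        assert deep.any()
        assert maps[..., sd.LABEL_COLLAGEN][deep].min() >= 0.9

    def test_end_to_end_mask_matches_truth(self, trained, noiseless_stack,
                                           noiseless_fixture):
        model, _ = trained
        _, mask = noiseless_fixture
        pred = model.segment(noiseless_stack)
        assert (pred == mask).mean() >= 0.99

    def test_single_class_training_rejected(self, trained, noiseless_stack):
        with pytest.raises(sd.ValidationError):
            sd.RandomForestPixelSegmenter().fit(
                np.zeros((10, 24)), np.zeros(10, dtype=int))


class TestClassify:
    def test_argmax(self):
        maps = np.zeros((1, 1, 4))
        maps[0, 0] = [0.1, 0.7, 0.1, 0.1]
        assert sd.classify(maps)[0, 0] == 1

    def test_tie_breaks_toward_lowest_label(self):
        maps = np.zeros((1, 1, 4))
        maps[0, 0] = [0.5, 0.5, 0.0, 0.0]
        assert sd.classify(maps)[0, 0] == 0

    def test_invariant_to_positive_scaling(self):
        rng = np.random.default_rng(0)
        maps = rng.random((8, 8, 4))
        assert np.array_equal(sd.classify(maps), sd.classify(3.7 * maps))


class TestThresholdSegment:
    def test_constant_image_single_band(self):
        img = np.full((8, 8, 3), 50, dtype=np.uint8)
        assert np.all(sd.threshold_segment(img, [100]) == 0)

    def test_two_tone_exact_recovery(self):
        img = np.zeros((8, 8, 3), dtype=np.uint8)
        img[:, 4:] = 200
        img[:, :4] = 40
        bands = sd.threshold_segment(img, [120])
        assert np.all(bands[:, :4] == 0) and np.all(bands[:, 4:] == 1)

    def test_non_increasing_thresholds_rejected(self):
        with pytest.raises(sd.ValidationError):
            sd.threshold_segment(np.zeros((8, 8, 3)), [100, 100])

    def test_forest_beats_thresholding_on_textured_fixture(
            self, standard_fixture, standard_stack):
        micro, mask = standard_fixture
        ts = sd.sample_training_pixels(standard_stack, mask, 300, seed=4)
        model = sd.RandomForestPixelSegmenter(
            n_trees=100, random_state=4).fit(ts)
        forest_acc = (model.segment(standard_stack) == mask).mean()
        bands = sd.threshold_segment(micro, STANDARD_CUTS,
                                     band_labels=STANDARD_BAND_LABELS)
        threshold_acc = (bands == mask).mean()
        assert threshold_acc < forest_acc


class TestConfusionAndMetrics:
    def test_published_counts_reproduce_published_metrics(self):
        counts, m = sd.confusion_and_metrics(table2_package_order(), None)
        assert m.accuracy == pytest.approx(0.973, abs=5e-4)
        coll = m.per_class.loc["collagen"]
        assert coll.precision == pytest.approx(0.983, abs=5e-4)
        assert coll.tp_rate == pytest.approx(0.957, abs=5e-4)
        assert coll.mcc == pytest.approx(0.957, abs=5e-4)
        assert coll.f_measure == pytest.approx(0.970, abs=5e-4)
        assert m.per_class.loc["nuclei", "tp_rate"] == \
            pytest.approx(0.914, abs=5e-4)

    def test_diagonal_matrix_is_perfect(self):
        counts = np.diag([10, 20, 30, 40])
        _, m = sd.confusion_and_metrics(counts, None)
        assert np.all(m.per_class[["tp_rate", "precision", "f_measure",
                                   "mcc"]].to_numpy() == 1.0)
        assert np.all(m.per_class["fp_rate"].to_numpy() == 0.0)

    def test_two_class_hand_computation(self):
        # TP=8, FN=2, FP=1, TN=9 embedded in the 4-class layout
        counts = np.array([[9, 1, 0, 0], [2, 8, 0, 0],
                           [0, 0, 0, 0], [0, 0, 0, 0]])
        _, m = sd.confusion_and_metrics(counts, None)
        row = m.per_class.iloc[1]
        assert row.precision == pytest.approx(8 / 9)
        assert row.recall == pytest.approx(0.8)
        assert row.mcc == pytest.approx(70 / np.sqrt(9 * 10 * 10 * 11),
                                        abs=1e-9)
        # empty classes flagged, reported as 0
        assert m.per_class.iloc[2].tp_rate == 0.0
        assert m.undefined.iloc[2].tp_rate

    def test_permutation_consistency(self):
        rng = np.random.default_rng(1)
        truth = rng.integers(0, 4, 500)
        pred = rng.integers(0, 4, 500)
        perm = np.array([2, 3, 1, 0])
        _, m1 = sd.confusion_and_metrics(truth, pred)
        _, m2 = sd.confusion_and_metrics(perm[truth], perm[pred])
        inv = np.argsort(perm)
        np.testing.assert_allclose(
            m1.per_class.to_numpy(),
            m2.per_class.to_numpy()[perm], atol=1e-12)

    def test_mask_shape_mismatch_rejected(self):
        with pytest.raises(sd.ValidationError):
            sd.confusion_and_metrics(np.zeros((4, 4), dtype=int),
                                     np.zeros((4, 5), dtype=int))


class TestCrossvalidate:
    def test_separable_data_scores_high(self, noiseless_stack,
                                        noiseless_fixture):
        _, mask = noiseless_fixture
        ts = sd.sample_training_pixels(noiseless_stack, mask, 60, seed=6)
        m = sd.crossvalidate(ts, k=5, seed=6, n_trees=50)
        assert m.accuracy >= 0.99

    def test_leave_one_out_runs(self, noiseless_stack, noiseless_fixture):
        _, mask = noiseless_fixture
        ts = sd.sample_training_pixels(noiseless_stack, mask, 5, seed=7)
        m = sd.crossvalidate(ts, k=20, seed=7, n_trees=10)
        assert 0.0 <= m.accuracy <= 1.0

    def test_deterministic(self, noiseless_stack, noiseless_fixture):
        _, mask = noiseless_fixture
        ts = sd.sample_training_pixels(noiseless_stack, mask, 30, seed=8)
        m1 = sd.crossvalidate(ts, k=4, seed=8, n_trees=20)
        m2 = sd.crossvalidate(ts, k=4, seed=8, n_trees=20)
        assert np.array_equal(m1.confusion, m2.confusion)


class TestMisclassificationError:
    def test_identical_masks(self):
        m = np.zeros((10, 10), dtype=int)
        assert sd.misclassification_error(m, m, 1) == 0.0

    def test_sqrt_of_discordant_count(self):
        truth = np.zeros((10, 10), dtype=int)
        pred = truth.copy()
        pred.ravel()[:25] = 1
        assert sd.misclassification_error(truth, pred, 1) == 5.0

    def test_matches_brute_force_loop(self):
        rng = np.random.default_rng(2)
        truth = rng.integers(0, 4, (100, 100))
        pred = rng.integers(0, 4, (100, 100))
        count = sum((truth[i, j] == 2) != (pred[i, j] == 2)
                    for i in range(100) for j in range(100))
        assert sd.misclassification_error(truth, pred, 2) == \
            pytest.approx(np.sqrt(count))
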