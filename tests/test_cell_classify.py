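"""Classifier: truth labeling, features, training, invariances, evaluation."""

import dataclasses

import numpy as np
import pytest

import fociscreen as fs
from fociscreen.cell_classify import (
    CLASSES,
    FEATURE_NAMES,
    TrainingSet,
    records_to_frame,
)
from fociscreen.synthdata import make_planted_crop


class TestLabelTruth:
    @pytest.mark.parametrize(
        "gain, foci, threshold, expected",
        [
            (0.0, 9, 5, "non_signaling"),
            (1.0, 0, 5, "foci_negative"),
            (0.4, 9, 5, "foci_positive"),
            (0.4, 4, 5, "foci_negative"),
            (0.4, 5, 5, "foci_positive"),
            (2.0, 1, 1, "foci_positive"),
        ],
    )
    def test_rule(self, gain, foci, threshold, expected):
        assert fs.label_truth(gain, foci, threshold) == expected

    def test_negative_threshold_rejected(self):
        with pytest.raises(ValueError):
            fs.label_truth(1.0, 0, -1)


class TestFeaturize:
    def test_deterministic_and_fixed_length(self):
        crop, _ = make_planted_crop(3, seed=1, noise=True)
        v1, v2 = fs.featurize(crop), fs.featurize(crop)
        np.testing.assert_array_equal(v1, v2)
        assert len(v1) == len(FEATURE_NAMES)

    def test_flat_crop_signal_features_at_background(self):
        crop, _ = make_planted_crop(0, seed=0, noise=False)
        flat = fs.normalize_crop(
            dataclasses.replace(
                crop, green_raw=np.full_like(crop.green_raw, 100.0), green_norm=None
            )
        )
        v = dict(zip(FEATURE_NAMES, fs.featurize(flat)))
        assert v["raw_green_mean"] == pytest.approx(100.0)
        assert v["anchor_spread"] == pytest.approx(0.0)
        assert v["tophat_energy"] == pytest.approx(0.0)
        assert v["foci_count"] == 0.0

    def test_gain_scaling_moves_raw_mean_only(self):
        crop, _ = make_planted_crop(2, seed=4, noise=False)
        doubled = fs.normalize_crop(
            dataclasses.replace(crop, green_raw=crop.green_raw * 2.0, green_norm=None)
        )
        v0 = dict(zip(FEATURE_NAMES, fs.featurize(crop)))
        v1 = dict(zip(FEATURE_NAMES, fs.featurize(doubled)))
        assert v1["raw_green_mean"] == pytest.approx(2.0 * v0["raw_green_mean"])
        assert v1["anchor_spread"] == pytest.approx(2.0 * v0["anchor_spread"], rel=1e-6)
        for shape_feature in ("norm_variance", "norm_kurtosis", "tophat_energy", "foci_count"):
            assert v1[shape_feature] == pytest.approx(v0[shape_feature], rel=1e-6)


class TestCellClassifier:
    def test_missing_class_errors_with_counts(self, labeled_crops):
        crops, labels, _ = labeled_crops
        idx = [i for i, l in enumerate(labels) if l != "non_signaling"][:50]
        with pytest.raises(ValueError, match="non_signaling"):
            fs.CellClassifier().fit([crops[i] for i in idx], [labels[i] for i in idx])

    def test_probability_simplex_and_argmax_consistency(self, trained_classifier, labeled_crops):
        crops, _, _ = labeled_crops
        probs = trained_classifier.predict_proba(crops[450:520])
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-9)
        assert probs.min() >= 0.0
        preds = trained_classifier.predict(crops[450:520])
        np.testing.assert_array_equal(
            preds, np.asarray(CLASSES, dtype=object)[probs.argmax(axis=1)]
        )

    def test_same_seed_identical_parameters(self, labeled_crops):
        crops, labels, _ = labeled_crops
        a = fs.CellClassifier(random_state=7).fit(crops[:300], labels[:300])
        b = fs.CellClassifier(random_state=7).fit(crops[:300], labels[:300])
        lr_a = a.model_.named_steps["logisticregression"]
        lr_b = b.model_.named_steps["logisticregression"]
        np.testing.assert_array_equal(lr_a.coef_, lr_b.coef_)

    def test_heldout_macro_accuracy(self, trained_classifier, labeled_crops):
        crops, labels, _ = labeled_crops
        ev = fs.evaluate(trained_classifier, crops[450:], labels[450:])
        assert ev["macro_accuracy"] >= 0.90

    def test_conv_small_trains_and_reproduces(self, labeled_crops):
        crops, labels, _ = labeled_crops
        kwargs = dict(backend="conv_small", epochs=4, random_state=0)
        a = fs.CellClassifier(**kwargs).fit(crops[:300], labels[:300])
        ev = fs.evaluate(a, crops[450:600], labels[450:600])
        assert ev["macro_accuracy"] >= 0.8  # small net, small train set
        b = fs.CellClassifier(**kwargs).fit(crops[:300], labels[:300])
        np.testing.assert_allclose(
            a.predict_proba(crops[600:650]), b.predict_proba(crops[600:650]), atol=1e-9
        )

    def test_empty_crop_list(self, trained_classifier):
        assert fs.classify(trained_classifier, []) == []

    def test_classify_preserves_order_and_identity(self, trained_classifier, labeled_crops):
        crops, _, _ = labeled_crops
        subset = crops[450:470]
        records = fs.classify(trained_classifier, subset, foci_counts=list(range(20)))
        frame = records_to_frame(records)
        assert list(frame["cell_id"]) == [c.cell_id for c in subset]
        assert list(frame["foci_count"]) == list(range(20))


class TestTrainClassifier:
    def test_validation_metrics_recorded(self, labeled_crops):
        crops, labels, _ = labeled_crops
        tset = TrainingSet(
            crops=crops[:400],
            labels=labels[:400],
            split=["train"] * 300 + ["val"] * 100,
            provenance={"positivity_threshold": 5},
        )
        clf = fs.train_classifier(tset, seed=0)
        assert clf.validation_["macro_accuracy"] > 0.8
        assert clf.provenance_["positivity_threshold"] == 5


class TestEvaluate:
    def test_perfect_predictor_identity_matrix(self, labeled_crops, trained_classifier):
        crops, labels, _ = labeled_crops
        preds = trained_classifier.predict(crops[450:550])
        ev = fs.evaluate(trained_classifier, crops[450:550], preds)  # truth := preds
        cm = ev["confusion_matrix"].to_numpy()
        assert (cm.sum() == np.trace(cm)) and ev["macro_accuracy"] == 1.0

    def test_matrix_row_sums_equal_support(self, labeled_crops, trained_classifier):
        crops, labels, _ = labeled_crops
        ev = fs.evaluate(trained_classifier, crops[450:550], labels[450:550])
        support = {c: labels[450:550].count(c) for c in CLASSES}
        for i, c in enumerate(CLASSES):
            assert ev["confusion_matrix"].loc[c].sum() == support[c]

    def test_confusion_matrix_matches_brute_tally(self, labeled_crops, trained_classifier):
        crops, labels, _ = labeled_crops
        sub_c, sub_y = crops[450:480], labels[450:480]
        preds = trained_classifier.predict(sub_c)
        ev = fs.evaluate(trained_classifier, sub_c, sub_y)
        for i, t in enumerate(CLASSES):
            for j, p in enumerate(CLASSES):
                tally = sum(
                    1 for yt, yp in zip(sub_y, preds) if yt == t and yp == p
                )
                assert ev["confusion_matrix"].iloc[i, j] == tally

    def test_single_class_predictor_macro_third(self):
        # all-one-class predictions on a balanced set -> macro accuracy 1/3
        class Stub:
            def predict(self, crops):
                return np.asarray(["foci_positive"] * len(crops), dtype=object)

        labels = ["non_signaling"] * 5 + ["foci_negative"] * 5 + ["foci_positive"] * 5
        ev = fs.evaluate(Stub(), [None] * 15, labels)
        assert ev["macro_accuracy"] == pytest.approx(1 / 3)
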