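"""Artery/vein intensity features and the logistic classifier."""

import warnings

import numpy as np
import pytest

from retitort.av import (
    AVModel,
    classify_av,
    extract_features,
    train_av,
)
from retitort.core import FundusImage
from retitort.graph import VesselSegment


def make_segment(row=40.0, n=30, radius=3.0):
    pts = np.stack([np.full(n, row), np.linspace(10, 60, n)], axis=1)
    return VesselSegment(0, pts, np.full(n, radius))


class TestFeatures:
    def test_constant_image_collapses_statistics(self):
        img = FundusImage(np.full((80, 80), 0.7))
        f = extract_features(img, make_segment())
        for name in ("circ", "line"):
            assert getattr(f, f"{name}_mean") == pytest.approx(0.7)
            assert getattr(f, f"{name}_median") == pytest.approx(0.7)
            assert getattr(f, f"{name}_min") == pytest.approx(0.7)
            assert getattr(f, f"{name}_max") == pytest.approx(0.7)
            assert getattr(f, f"{name}_sd") == pytest.approx(0.0)

    def test_order_statistics_are_ordered(self, av_scene):
        for seg in av_scene.truth_graph.segments:
            f = extract_features(av_scene.image, seg)
            assert f.circ_min <= f.circ_median <= f.circ_max
            assert f.line_min <= f.line_median <= f.line_max
            assert f.circ_sd >= 0 and f.line_sd >= 0

    def test_vein_centerline_darker_than_artery(self, av_scene):
        feats = {
            s.av_label: extract_features(av_scene.image, s)
            for s in av_scene.truth_graph.segments[:2]
        }
        assert feats["vein"].line_mean < feats["artery"].line_mean

    def test_huge_circle_factor_approaches_global_statistics(self, av_scene):
        f = extract_features(av_scene.image, av_scene.truth_graph.segments[0],
                             circle_radius_factor=200)
        px = av_scene.image.pixels
        assert f.circ_mean == pytest.approx(px.mean(), rel=0.05)
        assert f.circ_sd == pytest.approx(px.std(), rel=0.05)
        assert f.circ_min == pytest.approx(px.min(), rel=0.05)
        assert f.circ_max == pytest.approx(px.max(), rel=0.05)

    def test_intensity_shift_moves_location_features_only(self, av_scene):
        seg = av_scene.truth_graph.segments[0]
        f0 = extract_features(av_scene.image, seg).as_array()
        f1 = extract_features(
            FundusImage(av_scene.image.pixels + 0.25), seg
        ).as_array()
        # location features shift by exactly 0.25; spreads unchanged
        shift = f1 - f0
        loc = [0, 2, 3, 4, 5, 7, 8, 9]
        spread = [1, 6]
        assert np.allclose(shift[loc], 0.25, atol=1e-12)
        assert np.allclose(shift[spread], 0.0, atol=1e-12)

    def test_segment_outside_image_rejected(self):
        img = FundusImage(np.zeros((40, 40)))
        with pytest.raises(ValueError, match="outside"):
            extract_features(img, make_segment(row=45.0))


def toy_training_set(n=60, separation=4.0, seed=0):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, 10))
    labels = ["artery" if i % 2 == 0 else "vein" for i in range(n)]
    X[:, 0] += np.array([separation if l == "artery" else 0.0 for l in labels])
    return X, labels


class TestTrainClassify:
    def test_separable_toy_reaches_perfect_training_accuracy(self):
        X, labels = toy_training_set(separation=10.0)
        model = train_av(X, labels)
        pred, _ = classify_av(model, X)
        assert pred == labels

    def test_single_class_rejected(self):
        X = np.random.default_rng(0).normal(size=(20, 10))
        with pytest.raises(ValueError, match="classes"):
            train_av(X, ["vein"] * 20)

    def test_tiny_training_set_rejected(self):
        X, labels = toy_training_set(n=6)
        with pytest.raises(ValueError):
            train_av(X[:6], labels[:6])

    def test_shuffled_labels_give_chance_level_heldout(self):
        rng = np.random.default_rng(42)
        accs = []
        for rep in range(20):
            X = rng.normal(size=(80, 10))
            labels = ["artery"] * 40 + ["vein"] * 40
            rng.shuffle(labels)
            model = train_av(X[:56], labels[:56], seed=rep)
            pred, _ = classify_av(model, X[56:])
            accs.append(np.mean([p == t for p, t in zip(pred, labels[56:])]))
        assert abs(np.mean(accs) - 0.5) < 0.1

    def test_probability_half_at_standardization_mean_with_zero_weights(self):
        model = AVModel(
            weights=np.zeros(10), intercept=0.0,
            feat_mean=np.arange(10.0), feat_scale=np.ones(10),
        )
        _, p = classify_av(model, np.arange(10.0)[None, :])
        assert p[0] == pytest.approx(0.5)

    def test_probability_monotone_in_positively_weighted_feature(self):
        w = np.zeros(10)
        w[3] = 1.5
        model = AVModel(w, 0.0, np.zeros(10), np.ones(10))
        x = np.zeros((3, 10))
        x[:, 3] = [-1.0, 0.0, 2.0]
        _, p = classify_av(model, x)
        assert p[0] < p[1] < p[2]

    def test_feature_dimension_mismatch_rejected(self):
        model = AVModel(np.zeros(10), 0.0, np.zeros(10), np.ones(10))
        with pytest.raises(ValueError, match="dimension"):
            classify_av(model, np.zeros((2, 7)))

    def test_classify_roundtrip_reproduces_training_accuracy(self):
        X, labels = toy_training_set(separation=1.5, seed=3)
        model = train_av(X, labels, seed=3)
        pred, _ = classify_av(model, X)
        acc1 = np.mean([p == t for p, t in zip(pred, labels)])
        pred2, _ = classify_av(model, X)
        acc2 = np.mean([p == t for p, t in zip(pred2, labels)])
        assert acc1 == acc2

    def test_affine_intensity_invariance_after_retraining(self, av_scene):
        from retitort.av import graph_features

        X0 = graph_features(av_scene.image, av_scene.truth_graph)
        X1 = graph_features(
            FundusImage(2.5 * av_scene.image.pixels + 0.4), av_scene.truth_graph
        )
        labels = [s.av_label for s in av_scene.truth_graph.segments]
        # pad the tiny graph to reach the minimum training size
        X0r, X1r = np.tile(X0, (2, 1)), np.tile(X1, (2, 1))
        m0 = train_av(X0r, labels * 2, seed=1)
        m1 = train_av(X1r, labels * 2, seed=1)
        _, p0 = classify_av(m0, X0)
        _, p1 = classify_av(m1, X1)
        assert np.allclose(p0, p1, atol=1e-6)

    def test_model_json_roundtrip(self):
        X, labels = toy_training_set()
        model = train_av(X, labels)
        again = AVModel.from_json(model.to_json())
        _, p0 = classify_av(model, X)
        _, p1 = classify_av(again, X)
        assert np.allclose(p0, p1, atol=1e-12)


class TestCohortAccuracy:
    def test_heldout_accuracy_on_synthetic_cohort(self):
        """70/30 split on extracted segments of a rendered cohort."""
        from retitort.pipeline import (
            PipelineParams,
            extract_graph_from_scene,
            transfer_truth_labels,
        )
        from retitort.av import graph_features
        from retitort.synthetic import demo_cohort_spec, simulate_cohort

        spec = demo_cohort_spec(seed=6, n_patients=10)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            pats = simulate_cohort(spec)
        params = PipelineParams()
        feats, labels = [], []
        for pat in pats:
            graph, _ = extract_graph_from_scene(pat.scene, params)
            if not graph.segments:
                continue
            av, _ = transfer_truth_labels(graph, pat.scene.truth_graph)
            X = graph_features(pat.scene.image, graph)
            for x, lab in zip(X, av):
                if lab in ("artery", "vein"):
                    feats.append(x)
                    labels.append(lab)
        X = np.array(feats)
        n_train = int(0.7 * len(X))
        model = train_av(X[:n_train], labels[:n_train], seed=0)
        pred, _ = classify_av(model, X[n_train:])
        acc = np.mean([p == t for p, t in zip(pred, labels[n_train:])])
        assert acc >= 0.90
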