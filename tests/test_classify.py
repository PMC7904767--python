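"""Classifier contract, oracle classifier, balanced sampling, top-k metrics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from capclean import (
    FrameSpec,
    OracleClassifier,
    TrainingPhase,
    build_balanced_dataset,
    generate_frame,
    predict,
    top_k_accuracy,
    train_reference_classifier,
)
from capclean.classify import CNNClassifier
from capclean.cnn import SmallCNN


class TestOracleClassifier:
    def test_one_hot_at_true_score(self):
        f5 = generate_frame(FrameSpec(visible_fraction=1.0, category="clean"))
        f1 = generate_frame(FrameSpec(visible_fraction=0.10, category="debris"))
        assert np.array_equal(predict(OracleClassifier(), f5), [0, 0, 0, 0, 1])
        assert np.array_equal(predict(OracleClassifier(), f1), [1, 0, 0, 0, 0])

    def test_smoothing_splits_over_neighbours(self):
        f3 = generate_frame(FrameSpec(visible_fraction=0.6, category="bile", seed=1))
        assert f3.true_score == 3
        p = predict(OracleClassifier(smoothing=0.2), f3)
        assert np.allclose(p, [0, 0.1, 0.8, 0.1, 0])

    def test_edge_score_sends_all_smoothing_to_single_neighbour(self):
        f5 = generate_frame(FrameSpec(visible_fraction=1.0, category="clean"))
        p = predict(OracleClassifier(smoothing=0.2), f5)
        assert np.allclose(p, [0, 0, 0, 0.2, 0.8])

    def test_requires_ground_truth(self):
        with pytest.raises(TypeError, match="ground truth"):
            predict(OracleClassifier(), np.zeros((64, 64, 3), dtype=np.uint8))


class TestBalancedDataset:
    def test_exact_counts_per_class(self, small_frame_set):
        ds = build_balanced_dataset(small_frame_set, n_per_class=5, seed=0)
        assert len(ds) == 25
        values, counts = np.unique(ds.labels, return_counts=True)
        assert list(values) == [1, 2, 3, 4, 5]
        assert (counts == 5).all()

    def test_minimal_sampling(self, small_frame_set):
        assert len(build_balanced_dataset(small_frame_set, n_per_class=1, seed=0)) == 5

    def test_shortage_error_names_class(self, small_frame_set):
        only_high = [f for f in small_frame_set if f.true_score >= 3]
        with pytest.raises(ValueError, match="class 1"):
            build_balanced_dataset(only_high, n_per_class=2, seed=0)


class TestTopKAccuracy:
    def test_perfect_one_hot(self):
        preds = np.eye(5)
        assert top_k_accuracy(preds, [1, 2, 3, 4, 5], 1) == 1.0

    def test_uniform_tie_break_takes_lowest_classes(self):
        """Uniform probabilities: the stable tie rule picks classes 1 and 2."""
        preds = np.full((5, 5), 0.2)
        labels = [1, 2, 3, 4, 5]
        assert top_k_accuracy(preds, labels, 1) == pytest.approx(1 / 5)
        assert top_k_accuracy(preds, labels, 2) == pytest.approx(2 / 5)

    @settings(deadline=None, max_examples=50)
    @given(st.integers(0, 2**31 - 1))
    def test_top2_at_least_top1(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(1, 30))
        preds = rng.dirichlet(np.ones(5), size=n)
        labels = rng.integers(1, 6, size=n)
        assert top_k_accuracy(preds, labels, 2) >= top_k_accuracy(preds, labels, 1)

    def test_misaligned_lengths_rejected(self):
        with pytest.raises(ValueError, match="misaligned"):
            top_k_accuracy(np.eye(5), [1, 2], 1)


class TestReferenceTraining:
    def _tiny_dataset(self, n_per_class=6):
        frames = []
        seeds = np.random.SeedSequence(9).generate_state(40, dtype=np.uint32)
        i = 0
        for lo, hi in [(0.0, 0.2), (0.3, 0.45), (0.55, 0.7), (0.78, 0.88), (0.92, 1.0)]:
            for j in range(n_per_class):
                vf = lo + (hi - lo) * j / n_per_class
                cat = "clean" if vf >= 0.9 else "debris"
                frames.append(
                    FrameSpec(visible_fraction=vf, category=cat, image_size=32, seed=int(seeds[i]))
                )
                i += 1
        rendered = [generate_frame(s) for s in frames]
        return build_balanced_dataset(rendered, n_per_class=n_per_class, seed=0)

    def test_fixed_seed_training_is_bit_identical(self):
        ds = self._tiny_dataset()
        phases = [TrainingPhase("head_only", 10, 8, 0.01), TrainingPhase("full_network", 5, 8, 1e-4)]
        c1, _ = train_reference_classifier(ds, phases, seed=4, channels=(4, 8))
        c2, _ = train_reference_classifier(ds, phases, seed=4, channels=(4, 8))
        assert np.array_equal(c1.net.head_w, c2.net.head_w)
        for l1, l2 in zip(c1.net.conv, c2.net.conv):
            assert np.array_equal(l1.w, l2.w)

    def test_probabilities_valid_over_random_frames(self):
        ds = self._tiny_dataset()
        clf, _ = train_reference_classifier(
            ds, [TrainingPhase("head_only", 10, 8, 0.01)], seed=0, channels=(4, 8)
        )
        rng = np.random.default_rng(0)
        frames = rng.integers(0, 256, size=(8, 32, 32, 3)).astype(np.uint8)
        probs = clf.predict_proba_batch(frames)
        assert (probs >= 0).all()
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-6)

    def test_input_shape_mismatch_rejected(self):
        ds = self._tiny_dataset()
        clf, _ = train_reference_classifier(
            ds, [TrainingPhase("head_only", 5, 8, 0.01)], seed=0, channels=(4, 8)
        )
        with pytest.raises(ValueError, match="expects 32x32"):
            clf.predict_proba(np.zeros((64, 64, 3), dtype=np.uint8))

    def test_empty_phase_list_rejected(self):
        with pytest.raises(ValueError, match="phase"):
            train_reference_classifier(self._tiny_dataset(), [], seed=0)

    def test_invalid_phase_parameters_rejected(self):
        with pytest.raises(ValueError):
            TrainingPhase("head_only", 0, 8, 0.01)
        with pytest.raises(ValueError):
            TrainingPhase("sideways", 5, 8, 0.01)
        with pytest.raises(ValueError):
            TrainingPhase("head_only", 5, 8, -0.1)

    def test_checkpoint_round_trip(self, tmp_path):
        ds = self._tiny_dataset()
        clf, _ = train_reference_classifier(
            ds, [TrainingPhase("head_only", 5, 8, 0.01)], seed=0, channels=(4, 8)
        )
        path = tmp_path / "model.npz"
        clf.save(path)
        loaded = CNNClassifier.load(path)
        x = ds.pixels[:4]
        assert np.array_equal(clf.predict_proba_batch(x), loaded.predict_proba_batch(x))

    def test_unknown_checkpoint_format_rejected(self, tmp_path):
        path = tmp_path / "bad.npz"
        import json

        np.savez(path, meta=np.frombuffer(json.dumps({"format": "other"}).encode(), dtype=np.uint8))
        with pytest.raises(ValueError, match="format"):
            SmallCNN.load(path)
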