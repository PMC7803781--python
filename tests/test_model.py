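"""Slice segmenter: loss, descent, determinism, serialisation, evaluation."""

import numpy as np
import pytest

import ventrivol as vv
import ventrivol.nn as nn
from ventrivol.dataset import SliceLabel, ThickSlice
from ventrivol.model import SliceSegmenter, TrainConfig, corpus_hash, evaluate_slices, train
from ventrivol.volume_io import CANVAS, VENTRICLE


@pytest.fixture(scope="module")
def trained(small_dataset):
    model, metrics = train(small_dataset, TrainConfig(epochs=3, seed=0))
    return model, metrics


class TestLoss:
    def test_uniform_weights_reduce_to_plain_cross_entropy(self):
        rng = np.random.default_rng(0)
        logits = rng.normal(size=(2, 3, 8, 8)).astype(np.float32)
        target = rng.integers(0, 3, (2, 8, 8))
        loss, _ = nn.weighted_softmax_ce(logits, target, np.ones(3, np.float32))
        # independent plain CE
        z = logits - logits.max(axis=1, keepdims=True)
        p = np.exp(z) / np.exp(z).sum(axis=1, keepdims=True)
        nll = []
        for n in range(2):
            for i in range(8):
                for j in range(8):
                    nll.append(-np.log(p[n, target[n, i, j], i, j]))
        assert loss == pytest.approx(np.mean(nll), rel=1e-5)

    def test_class_weights_rescale_gradient(self):
        rng = np.random.default_rng(1)
        logits = rng.normal(size=(1, 3, 4, 4)).astype(np.float32)
        target = np.full((1, 4, 4), 2)
        _, g1 = nn.weighted_softmax_ce(logits, target, np.ones(3, np.float32))
        _, g2 = nn.weighted_softmax_ce(logits, target,
                                       np.array([1, 1, 5], np.float32))
        # single-class target: weights cancel in the normalised mean
        assert np.allclose(g1, g2, atol=1e-7)

    def test_conv_gradients_match_finite_differences(self):
        rng = np.random.default_rng(2)
        conv = nn.Conv2d(2, 3, 3, rng)
        x = rng.random((1, 2, 6, 6)).astype(np.float32)
        d = rng.random((1, 3, 6, 6)).astype(np.float32)
        y = conv.forward(x, True)
        dx = conv.backward(d)
        eps = 1e-3
        for idx in [(0, 0, 0, 0), (0, 1, 3, 2), (0, 0, 5, 5)]:
            xp, xm = x.copy(), x.copy()
            xp[idx] += eps
            xm[idx] -= eps
            num = ((conv.forward(xp, False) * d).sum()
                   - (conv.forward(xm, False) * d).sum()) / (2 * eps)
            assert dx[idx] == pytest.approx(num, rel=2e-2, abs=1e-3)


class TestTraining:
    def test_loss_descends(self, trained):
        _, metrics = trained
        assert metrics[-1].train_loss < metrics[0].train_loss

    def test_training_is_deterministic_given_seed(self, small_dataset):
        m1, k1 = train(small_dataset, TrainConfig(epochs=1, seed=4))
        m2, k2 = train(small_dataset, TrainConfig(epochs=1, seed=4))
        assert k1[0].train_loss == k2[0].train_loss
        for a, b in zip(m1.net.state_arrays(), m2.net.state_arrays()):
            assert np.array_equal(a, b)

    def test_test_split_not_mutated_by_training(self, small_dataset):
        before = corpus_hash(small_dataset.test_labels)
        train(small_dataset, TrainConfig(epochs=1, seed=5))
        assert corpus_hash(small_dataset.test_labels) == before

    def test_empty_training_set_rejected(self, small_dataset):
        import dataclasses

        empty = dataclasses.replace(small_dataset, train_images=[], train_labels=[])
        with pytest.raises(ValueError):
            train(empty, TrainConfig(epochs=1))

    def test_divergent_learning_rate_aborts_with_diagnostics(self, small_dataset):
        with pytest.raises(RuntimeError, match="loss"):
            train(small_dataset, TrainConfig(epochs=3, learning_rate=1e4, seed=0))

    def test_weighted_loss_improves_minority_recall(self, small_dataset):
        """Median-frequency weighting should not hurt ventricle recall."""
        import dataclasses

        unweighted = dataclasses.replace(small_dataset)
        unweighted.class_weights = vv.ClassWeights(
            alpha={0: 1.0, 1: 1.0, 2: 1.0}, frequencies={}, median_frequency=1.0
        )
        rec_w, rec_u = [], []
        for seed in (0, 1, 2):
            for ds, out in ((small_dataset, rec_w), (unweighted, rec_u)):
                model, _ = train(ds, TrainConfig(epochs=2, seed=seed))
                preds = model.predict_batch(ds.test_images)
                tp = fn = 0
                for p, t in zip(preds, ds.test_labels):
                    truth = t.pixels == VENTRICLE
                    tp += int((truth & (p.pixels == VENTRICLE)).sum())
                    fn += int((truth & (p.pixels != VENTRICLE)).sum())
                out.append(tp / max(tp + fn, 1))
        assert np.median(rec_w) >= np.median(rec_u)


class TestPredict:
    def test_all_zero_input_yields_valid_class_map(self, trained):
        model, _ = trained
        out = model.predict(ThickSlice(np.zeros(CANVAS + (3,), np.uint8), 0))
        assert out.pixels.shape == CANVAS
        assert set(np.unique(out.pixels)) <= {0, 1, 2}

    def test_prediction_is_deterministic(self, trained, small_dataset):
        model, _ = trained
        img = small_dataset.test_images[0]
        assert np.array_equal(model.predict(img).pixels, model.predict(img).pixels)

    def test_canvas_mismatch_rejected(self, trained):
        model, _ = trained
        with pytest.raises(ValueError):
            ThickSlice(np.zeros((100, 100, 3), np.uint8), 0)
        bad = ThickSlice.__new__(ThickSlice)
        bad.pixels = np.zeros((100, 100, 3), np.uint8)
        bad.centre_index = 0
        bad.source_id = ""
        bad.pad_info = None
        with pytest.raises(ValueError):
            model.predict(bad)

    def test_serialisation_round_trip_bit_exact(self, trained, small_dataset, tmp_path):
        model, _ = trained
        path = str(tmp_path / "model.npz")
        model.save(path)
        loaded = SliceSegmenter.load(path)
        img = small_dataset.test_images[0]
        assert np.array_equal(model.predict(img).pixels, loaded.predict(img).pixels)


class TestEvaluateSlices:
    @staticmethod
    def _const_model(pred_pixels):
        class Fake:
            def predict_batch(self, images):
                return [SliceLabel(pred_pixels.copy(), i) for i, _ in enumerate(images)]

        return Fake()

    def test_perfect_prediction_scores_one(self):
        px = np.zeros(CANVAS, np.uint8)
        px[40:80, 40:80] = VENTRICLE
        model = self._const_model(px)
        imgs = [ThickSlice(np.zeros(CANVAS + (3,), np.uint8), 0)]
        labs = [SliceLabel(px.copy(), 0)]
        iou, dsc = evaluate_slices(model, imgs, labs)
        assert iou == 1.0 and dsc == 1.0

    def test_half_shifted_square_gives_third_iou_half_dsc(self):
        pred = np.zeros(CANVAS, np.uint8)
        pred[40:80, 40:80] = VENTRICLE
        truth = np.zeros(CANVAS, np.uint8)
        truth[40:80, 60:100] = VENTRICLE  # shifted by half width
        model = self._const_model(pred)
        iou, dsc = evaluate_slices(
            model,
            [ThickSlice(np.zeros(CANVAS + (3,), np.uint8), 0)],
            [SliceLabel(truth, 0)],
        )
        assert iou == pytest.approx(1 / 3)
        assert dsc == pytest.approx(1 / 2)

    def test_iou_never_exceeds_dsc(self, trained, small_dataset):
        model, _ = trained
        iou, dsc = evaluate_slices(model, small_dataset.test_images,
                                   small_dataset.test_labels)
        assert iou <= dsc

    def test_both_empty_slices_skipped_truth_empty_counts_zero(self):
        pred = np.zeros(CANVAS, np.uint8)
        pred[0, 0] = VENTRICLE
        model = self._const_model(pred)
        imgs = [ThickSlice(np.zeros(CANVAS + (3,), np.uint8), i) for i in range(2)]
        truth_nonempty = np.zeros(CANVAS, np.uint8)
        truth_nonempty[0, 0] = VENTRICLE
        labs = [SliceLabel(truth_nonempty, 0), SliceLabel(np.zeros(CANVAS, np.uint8), 1)]
        iou, _ = evaluate_slices(model, imgs, labs)
        # slice 1: truth empty, prediction nonempty -> IoU 0; mean = 0.5
        assert iou == pytest.approx(0.5)


def test_vgg16_sized_model_constructs_and_predicts():
    from ventrivol.model import _PLANS, _build

    net = _build(_PLANS["vgg16"], np.random.default_rng(0))
    out = net.forward(np.zeros((1, 3, 200, 200), np.float32))
    assert out.shape == (1, 3, 200, 200)
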