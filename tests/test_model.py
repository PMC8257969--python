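"""Model assembly, context windows, training behavior, causality."""

import numpy as np
import pytest

from touchtrace.detrend import DetectorSeries
from _toys import simple_detrend, toy_dataset, toy_features
from touchtrace.features import GRID_BINS, HourlyFeatureSeries
from touchtrace.model import (
    MDNModel,
    ModelConfig,
    TrainConfig,
    build_model,
    load_model,
    make_context_windows,
    predict_series,
    save_model,
    train_model,
)
from touchtrace.nn.autodiff import Tensor


class TestContextWindows:
    def test_centered_uses_t_minus_4_to_t_plus_4(self):
        feats, det, detr = toy_dataset(100)
        win = make_context_windows(feats, det, detr, "centered")
        w = win[0]
        assert w.target_hour == 4
        np.testing.assert_array_equal(w.frame_hours, np.arange(0, 9))

    def test_100_hour_series_yields_92_centered_windows(self):
        feats, det, detr = toy_dataset(100)
        assert len(make_context_windows(feats, det, detr, "centered")) == 92

    def test_preceding_never_reaches_target_hour(self):
        feats, det, detr = toy_dataset(100)
        win = make_context_windows(feats, det, detr, "preceding")
        assert len(win) == 91
        for i in (0, 40, 90):
            w = win[i]
            assert w.frame_hours.max() == w.target_hour - 1

    def test_misaligned_grids_rejected(self):
        feats, det, detr = toy_dataset(100)
        det2 = DetectorSeries(hours=det.hours + 1, counts=det.counts)
        with pytest.raises(ValueError, match="misaligned"):
            make_context_windows(feats, det2, detr, "centered")

    def test_all_absent_windows_flagged(self):
        feats, det, detr = toy_dataset(60)
        feats.present[:, :] = False
        feats.present[30, 0] = True
        win = make_context_windows(feats, det, detr, "centered")
        flags = win.any_present
        # windows whose context covers hour 30 are the only evaluable ones
        assert flags.sum() == 9
        assert not flags[0]


class TestModelShape:
    def test_output_shape_contract(self):
        model = build_model(ModelConfig(n_output_channels=4), seed=0)
        frames = Tensor(np.random.default_rng(0).random((11, 2, 50, 50)).astype(np.float32))
        gather = np.random.default_rng(1).integers(0, 11, (3, 9))
        model.set_training(False)
        raws = model.forward_deduplicated(frames, gather)
        assert len(raws) == 4
        for raw in raws:
            assert raw.shape == (3, 9)

    def test_invalid_channel_count_rejected(self):
        with pytest.raises(ValueError):
            ModelConfig(n_output_channels=3)

    def test_mixture_params_always_valid(self):
        model = build_model(ModelConfig(), seed=1)
        raw = np.random.default_rng(2).standard_normal((40, 2, 9)) * 5
        p = model.raw_to_params(raw)
        assert np.all(p.stds > 0)
        assert np.all(p.weights >= 0)
        np.testing.assert_allclose(p.weights.sum(axis=-1), 1.0, atol=1e-6)

    def test_resnet50_embedding_is_1024(self):
        model = build_model(ModelConfig(extractor="resnet50"), seed=0)
        assert model.extractor.embedding_dim == 1024
        model.set_training(False)
        frames = Tensor(np.random.default_rng(3).random((2, 2, 50, 50)).astype(np.float32))
        emb = model.extractor(frames)
        assert emb.shape == (2, 1024)


class TestTraining:
    def test_nll_decreases_on_easy_data(self):
        feats, det, detr = toy_dataset(240, coupled=True)
        win = make_context_windows(feats, det, detr, "centered")
        model = build_model(ModelConfig(n_output_channels=2), seed=0)
        hist = train_model(model, win, feats,
                           TrainConfig(epochs=5, seed=0, batch_size=32))
        assert hist["train_nll"][-1] < hist["train_nll"][0]

    def test_constant_targets_predicted_exactly(self):
        feats, det, detr = toy_dataset(240, coupled=False)
        det.counts[:] = 17
        detr = simple_detrend(det)
        win = make_context_windows(feats, det, detr, "centered")
        model = build_model(ModelConfig(n_output_channels=2), seed=0)
        hist = train_model(model, win, feats,
                           TrainConfig(epochs=3, seed=0, batch_size=32))
        pred = predict_series(model, feats, win)
        cut = hist["split_index"]
        # z-scoring maps a constant target to 0 with std 1; the mode must
        # come back at the constant on held-out windows
        assert np.all(np.abs(pred.point[cut:, 0] - 17) < 0.05 * 1.0 + 0.05)

    def test_empty_training_set_rejected(self):
        feats, det, detr = toy_dataset(100)
        win = make_context_windows(feats, det, detr, "centered")
        empty = win.__class__(
            frame_idx=win.frame_idx[:0], presence=win.presence[:0],
            target_idx=win.target_idx[:0], hours=win.hours[:0],
            targets=win.targets[:0], alignment=win.alignment,
        )
        model = build_model(ModelConfig(n_output_channels=2), seed=0)
        with pytest.raises(ValueError):
            train_model(model, empty, feats, TrainConfig(epochs=1))

    def test_training_deterministic_under_seed(self):
        feats, det, detr = toy_dataset(150)
        win = make_context_windows(feats, det, detr, "centered")
        outs = []
        for _ in range(2):
            model = build_model(ModelConfig(n_output_channels=2), seed=3)
            train_model(model, win, feats, TrainConfig(epochs=2, seed=3, batch_size=32))
            outs.append(predict_series(model, feats, win).point)
        np.testing.assert_array_equal(outs[0], outs[1])


class TestCausality:
    def test_future_perturbation_leaves_preceding_output_unchanged(self):
        feats, det, detr = toy_dataset(120, seed=4)
        win = make_context_windows(feats, det, detr, "preceding")
        model = build_model(ModelConfig(n_output_channels=2), seed=0)
        train_model(model, win, feats, TrainConfig(epochs=1, seed=0, batch_size=32))
        pred1 = predict_series(model, feats, win)
        # corrupt hour t and everything after, per target hour t0 = first target
        t0 = int(win.hours[0])
        feats2 = toy_dataset(120, seed=4)[0]
        rng = np.random.default_rng(9)
        feats2.jid_all[t0:] = rng.random(feats2.jid_all[t0:].shape).astype(np.float32)
        feats2.jid_social[t0:] = rng.random(feats2.jid_social[t0:].shape).astype(np.float32)
        win_first = make_context_windows(feats2, det, detr, "preceding")
        pred2 = predict_series(model, feats2, win_first)
        # the first window reads only hours < t0, so its outputs are
        # bit-identical despite every hour >= t0 being replaced
        np.testing.assert_array_equal(pred1.point[0], pred2.point[0])
        np.testing.assert_array_equal(
            pred1.params.means[0], pred2.params.means[0]
        )

    def test_centered_alignment_does_read_the_future(self):
        feats, det, detr = toy_dataset(120, seed=4)
        win = make_context_windows(feats, det, detr, "centered")
        model = build_model(ModelConfig(n_output_channels=2), seed=0)
        train_model(model, win, feats, TrainConfig(epochs=1, seed=0, batch_size=32))
        pred1 = predict_series(model, feats, win)
        t0 = int(win.hours[0])
        feats2 = toy_dataset(120, seed=4)[0]
        feats2.jid_all[t0 + 1] += 0.5
        pred2 = predict_series(model, feats2, win)
        assert not np.array_equal(pred1.point[0], pred2.point[0])


class TestPredict:
    def test_predictions_finite_everywhere(self):
        feats, det, detr = toy_dataset(120)
        win = make_context_windows(feats, det, detr, "centered")
        model = build_model(ModelConfig(n_output_channels=2), seed=0)
        train_model(model, win, feats, TrainConfig(epochs=1, seed=0, batch_size=32))
        pred = predict_series(model, feats, win)
        assert np.isfinite(pred.point).all()
        assert pred.all_absent.shape == (len(win),)

    def test_untrained_model_refuses_prediction(self):
        feats, det, detr = toy_dataset(100)
        win = make_context_windows(feats, det, detr, "centered")
        model = build_model(ModelConfig(n_output_channels=2), seed=0)
        with pytest.raises(ValueError):
            predict_series(model, feats, win)

    def test_save_load_roundtrip_identical_predictions(self, tmp_path):
        feats, det, detr = toy_dataset(120)
        win = make_context_windows(feats, det, detr, "centered")
        model = build_model(ModelConfig(n_output_channels=2), seed=0)
        train_model(model, win, feats, TrainConfig(epochs=1, seed=0, batch_size=32))
        pred1 = predict_series(model, feats, win)
        save_model(model, tmp_path / "model")
        model2 = load_model(tmp_path / "model")
        pred2 = predict_series(model2, feats, win)
        np.testing.assert_array_equal(pred1.point, pred2.point)
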