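"""Adam updates, augmentation and training-loop bookkeeping."""

import numpy as np
import pytest

from sdhseg.estimator import UNetSegmenter
from sdhseg.exceptions import NonFiniteGradient
from sdhseg.losses import LossWeights
from sdhseg.models import ModelSpec
from sdhseg.training import AdamState, TrainConfig, adam_step, augment_pair, train


class TestAdamStep:
    def test_first_step_hand_values(self):
        state = AdamState.init(0.0, eta=0.001)
        state, theta = adam_step(state, 0.0, 1.0)
        assert state.t == 1
        assert state.m[0] == pytest.approx(0.1, abs=1e-15)
        assert state.v[0] == pytest.approx(0.001, abs=1e-15)
        m_hat = state.m[0] / (1 - 0.9**1)
        v_hat = state.v[0] / (1 - 0.999**1)
        assert m_hat == pytest.approx(1.0, abs=1e-10)
        assert v_hat == pytest.approx(1.0, abs=1e-10)
        assert theta == pytest.approx(-0.001 / (1 + 1e-8), abs=1e-10)

    def test_second_step_bias_correction_cancels(self):
        state = AdamState.init(0.0, eta=0.001)
        state, theta = adam_step(state, 0.0, 1.0)
        state, theta = adam_step(state, theta, 1.0)
        m_hat = state.m[0] / (1 - 0.9**2)
        v_hat = state.v[0] / (1 - 0.999**2)
        assert m_hat == pytest.approx(1.0, abs=1e-10)
        assert v_hat == pytest.approx(1.0, abs=1e-10)
        assert theta == pytest.approx(-0.002 / (1 + 1e-8), abs=1e-9)

    def test_zero_gradient_leaves_parameters_unchanged(self):
        state = AdamState.init(np.ones(3))
        state, p = adam_step(state, np.ones(3), np.zeros(3))
        assert np.array_equal(p, np.ones(3))
        assert np.all(state.m[0] == 0) and np.all(state.v[0] == 0)

    @pytest.mark.parametrize("t", [1, 3, 10])
    def test_constant_gradient_has_unit_bias_corrected_moments(self, t):
        state = AdamState.init(0.0)
        theta = 0.0
        g = 2.5
        for _ in range(t):
            state, theta = adam_step(state, theta, g)
        assert state.m[0] / (1 - 0.9**state.t) == pytest.approx(g, abs=1e-10)
        assert state.v[0] / (1 - 0.999**state.t) == pytest.approx(g**2, abs=1e-9)

    def test_non_finite_gradient_rejected(self):
        state = AdamState.init(0.0)
        with pytest.raises(NonFiniteGradient):
            adam_step(state, 0.0, np.nan)


class TestAugmentPair:
    def test_deterministic_under_fixed_stream(self):
        img = np.random.default_rng(0).random((16, 16)).astype(np.float32)
        mask = (img > 0.5).astype(np.uint8)
        a = augment_pair(img, mask, np.random.default_rng(5))
        b = augment_pair(img, mask, np.random.default_rng(5))
        assert np.array_equal(a[0], b[0]) and np.array_equal(a[1], b[1])

    def test_mask_stays_binary_and_aligned(self):
        rng = np.random.default_rng(1)
        img = rng.random((20, 20)).astype(np.float32)
        mask = np.zeros((20, 20), np.uint8)
        mask[5:9, 4:12] = 1
        for _ in range(10):
            im2, mk2 = augment_pair(img, mask, rng)
            assert set(np.unique(mk2)) <= {0, 1}
            assert mk2.sum() == mask.sum()  # flips preserve area
            assert im2.min() >= 0.0 and im2.max() <= 1.0

    def test_double_horizontal_flip_is_identity(self):
        img = np.random.default_rng(2).random((8, 8)).astype(np.float32)
        assert np.array_equal(img[:, ::-1][:, ::-1], img)

    def test_resize_to_target(self):
        rng = np.random.default_rng(3)
        img = rng.random((20, 20)).astype(np.float32)
        mask = (img > 0.7).astype(np.uint8)
        im2, mk2 = augment_pair(img, mask, rng, size=(16, 16))
        assert im2.shape == (16, 16) and mk2.shape == (16, 16)


TINY = dict(architecture="unet", depth=2, base_channels=4)


class TestTrainLoop:
    def test_step_bookkeeping_and_history_schema(self, tiny_dataset):
        cfg = TrainConfig(seed=0, epochs=1, batch_size=2, image_size=(32, 32),
                          model=ModelSpec(**TINY))
        sub = (tiny_dataset.train.images[:4], tiny_dataset.train.masks[:4])
        model, history = train(cfg, sub, (tiny_dataset.val.images, tiny_dataset.val.masks))
        assert len(history) == 1
        rec = history[0]
        assert {"epoch", "bce", "sdhl", "total", "val_dice", "val_iou"} <= set(rec)
        # 4 samples, batch 2 -> 2 optimisation steps feed the epoch means
        assert rec["total"] == pytest.approx(rec["total"])

    def test_same_seed_reproduces_training_exactly(self, tiny_dataset):
        est_kw = dict(**TINY, epochs=2, batch_size=8, seed=7, patience=None)
        runs = []
        for _ in range(2):
            est = UNetSegmenter(**est_kw)
            est.fit(tiny_dataset.train.images, tiny_dataset.train.masks,
                    validation=(tiny_dataset.val.images, tiny_dataset.val.masks))
            runs.append(est)
        assert runs[0].history_ == runs[1].history_
        for a, b in zip(runs[0].model_.parameters(), runs[1].model_.parameters()):
            assert np.array_equal(a.data, b.data)

    def test_loss_decreases_over_training(self, tiny_dataset):
        est = UNetSegmenter(**TINY, epochs=6, batch_size=8, seed=3, patience=None)
        est.fit(tiny_dataset.train.images, tiny_dataset.train.masks)
        totals = [rec["total"] for rec in est.history_]
        assert totals[-1] < totals[0]

    def test_bce_only_history_has_no_boundary_field(self, tiny_dataset):
        est = UNetSegmenter(**TINY, loss="bce", epochs=1, batch_size=8, seed=0)
        est.fit(tiny_dataset.train.images, tiny_dataset.train.masks)
        assert "sdhl" not in est.history_[0] and "bce" in est.history_[0]

    def test_predict_and_score_shapes(self, tiny_dataset):
        est = UNetSegmenter(**TINY, epochs=1, batch_size=8, seed=0)
        est.fit(tiny_dataset.train.images, tiny_dataset.train.masks)
        preds = est.predict(tiny_dataset.test.images)
        assert preds.shape == tiny_dataset.test.masks.shape
        assert set(np.unique(preds)) <= {0, 1}
        assert 0.0 <= est.score(tiny_dataset.test.images, tiny_dataset.test.masks) <= 1.0

    def test_sklearn_param_interface(self):
        est = UNetSegmenter(epochs=3)
        params = est.get_params()
        assert params["epochs"] == 3 and params["lambda1"] == 0.6
        est.set_params(lambda2=0.5)
        assert est.lambda2 == 0.5

    def test_unfitted_predict_raises(self):
        with pytest.raises(RuntimeError):
            UNetSegmenter().predict(np.zeros((1, 32, 32)))

    def test_invalid_loss_name_rejected(self, tiny_dataset):
        with pytest.raises(ValueError):
            TrainConfig(loss="dice")


class TestAblationRun:
    def test_five_variants_one_row_each_with_bounded_metrics(self, tiny_dataset, tmp_path):
        from sdhseg.training import ablation_run

        cfg = TrainConfig(seed=0, epochs=1, batch_size=8, image_size=(32, 32),
                          model=ModelSpec(**TINY))
        frame = ablation_run(cfg, tiny_dataset.train, tiny_dataset.val, tiny_dataset.test,
                             csv_path=tmp_path / "ab.csv", json_path=tmp_path / "ab.json")
        assert list(frame.index) == ["hdl", "bce", "hdl+bce", "sdhl", "sdhl+bce"]
        cols = ["accuracy", "precision", "recall", "dice", "iou"]
        assert frame[cols].ge(0).all().all() and frame[cols].le(1).all().all()
        assert (tmp_path / "ab.csv").exists() and (tmp_path / "ab.json").exists()


def test_weights_default_mix():
    w = LossWeights()
    assert (w.lambda1, w.lambda2) == (0.6, 0.4)
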