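"""3D U-Net: architecture contracts, training behaviour, CV orchestration."""

import copy

import numpy as np
import pytest

from conftest import SMALL_GEOM, TINY_GEOM, small_spec
from ldq.geometry import GeometryMismatchError
from ldq.phantom import PhantomSpec, generate_phantom
from ldq.unet import (
    LeakageError,
    UNetConfig,
    UNetSegmenter,
    build_model,
    mc_cross_validate,
    predict,
    train,
)

TINY_CFG = UNetConfig(levels=2, base_filters=2, learning_rate=1e-2, max_epochs=3, patience=3)


def _tiny_pair(seed, subject_id):
    spec = PhantomSpec(geometry=TINY_GEOM, seed=seed, subject_id=subject_id)
    vol, lmap, _ = generate_phantom(spec)
    return vol, lmap


class TestBuildModel:
    def test_parameter_count_matches_closed_form_for_minimal_net(self):
        # levels=1, base=1, growth=2, 2 output channels, 2 convs per block.
        # Closed form: conv = out*(in*27) + out weights+biases; instance
        # norm adds 2 per filter; head is 1x1x1.
        cfg = UNetConfig(levels=1, base_filters=1, out_channels=2, convs_per_block=2)

        def conv(i, o, k=27):
            return o * i * k + o

        expected = (
            conv(1, 1) + 2 + conv(1, 1) + 2          # encoder block (conv + IN)
            + conv(1, 2) + 4 + conv(2, 2) + 4        # bottleneck
            + conv(2, 1, k=1)                        # 1x1 up-convolution (2 -> 1)
            + conv(2, 1) + 2 + conv(1, 1) + 2        # decoder (1 up + 1 skip -> 1)
            + conv(1, 2, k=1)                        # head
        )
        _, n = build_model(cfg)
        assert n == expected

    def test_forward_shape_contract(self):
        model, _ = build_model(UNetConfig(levels=2, base_filters=2))
        out = model.forward(np.zeros((1, 16, 16, 8), dtype=np.float32), train=False)
        assert out.shape == (9, 16, 16, 8)

    def test_doubling_base_filters_roughly_quadruples_parameters(self):
        _, n8 = build_model(UNetConfig(levels=2, base_filters=8))
        _, n16 = build_model(UNetConfig(levels=2, base_filters=16))
        assert 3.5 <= n16 / n8 <= 4.5

    def test_indivisible_shape_reports_required_padding(self):
        model, _ = build_model(UNetConfig(levels=3, base_filters=2))
        with pytest.raises(GeometryMismatchError, match="pad"):
            model.forward(np.zeros((1, 20, 16, 8), dtype=np.float32))

    def test_count_is_deterministic_function_of_config(self):
        cfg = UNetConfig(levels=2, base_filters=4, seed=1)
        _, a = build_model(cfg)
        _, b = build_model(UNetConfig(levels=2, base_filters=4, seed=99))
        assert a == b  # seed changes weights, not the count


class TestTrain:
    def test_leakage_guard_lists_offending_ids(self):
        vol, lmap = _tiny_pair(0, "dup")
        model, _ = build_model(TINY_CFG)
        with pytest.raises(LeakageError, match="dup"):
            train(model, [(vol, lmap)], [(vol, lmap)], TINY_CFG)

    def test_same_seed_identical_history(self):
        a_train = [_tiny_pair(0, "t0"), _tiny_pair(1, "t1")]
        a_val = [_tiny_pair(2, "v0")]
        h = []
        for _ in range(2):
            model, _ = build_model(TINY_CFG)
            _, hist = train(model, list(a_train), list(a_val), TINY_CFG)
            h.append(hist)
        assert h[0].train_loss == h[1].train_loss
        assert h[0].val_loss == h[1].val_loss

    def test_early_stopping_contract(self):
        # patience epochs after the best epoch, then stop and restore argmin
        cfg = UNetConfig(levels=2, base_filters=2, learning_rate=0.5, max_epochs=40, patience=3)
        model, _ = build_model(cfg)
        _, hist = train(model, [_tiny_pair(0, "t0")], [_tiny_pair(2, "v0")], cfg)
        assert hist.best_epoch == int(np.argmin(hist.val_loss))
        if hist.stopped_early:
            assert len(hist.val_loss) == hist.best_epoch + cfg.patience + 1

    def test_overfit_smoke_loss_decreases_and_dice_high(self):
        # One phantom as train and (renamed copy as) validation: the loss
        # must fall steadily and, given enough gradient steps (one per
        # epoch with a single training volume), the network must reproduce
        # the mask essentially perfectly.
        from ldq.eval_stats import dice
        from ldq.unet import predict

        spec = small_spec(seed=21, subject_id="train")
        vol, lmap, _ = generate_phantom(spec)
        val_vol = copy.deepcopy(vol)
        val_vol.subject_id = "val"
        cfg = UNetConfig(levels=3, base_filters=8, learning_rate=1e-2, max_epochs=400, patience=400, seed=3)
        model, _ = build_model(cfg)
        model, hist = train(model, [(vol, lmap)], [(val_vol, lmap)], cfg)
        first5 = hist.train_loss[:5]
        assert all(b < a for a, b in zip(first5, first5[1:]))
        assert hist.best_epoch == int(np.argmin(hist.val_loss))
        pred = predict(model, vol)
        for code in lmap.codes:
            assert dice(pred, lmap, code) >= 0.90


class TestPredict:
    def test_prediction_is_valid_label_map(self):
        vol, lmap = _tiny_pair(0, "t0")
        model, _ = build_model(TINY_CFG)
        pred = predict(model, vol)
        assert set(np.unique(pred.labels)) <= set(range(9))
        assert pred.geometry.matches(vol.geometry)

    def test_geometry_mismatch_suggests_homogenisation(self):
        vol, _ = _tiny_pair(0, "t0")
        model, _ = build_model(TINY_CFG)
        with pytest.raises(GeometryMismatchError, match="homogenise"):
            predict(model, vol, geometry=SMALL_GEOM)


class TestEstimator:
    def test_sklearn_params_round_trip(self):
        seg = UNetSegmenter(levels=2, base_filters=4)
        params = seg.get_params()
        assert params["levels"] == 2
        seg2 = UNetSegmenter(**params)
        assert seg2.get_params() == params

    def test_fit_predict_surface(self):
        pairs = [_tiny_pair(i, f"s{i}") for i in range(4)]
        X = [v for v, _ in pairs]
        y = [m for _, m in pairs]
        seg = UNetSegmenter(levels=2, base_filters=2, max_epochs=2, patience=2)
        seg.fit(X, y)
        assert seg.n_params_ > 0
        assert seg.history_.best_epoch >= 0
        pred = seg.predict(X[0])
        assert pred.geometry.matches(X[0].geometry)

    def test_predict_before_fit_raises(self):
        with pytest.raises(RuntimeError):
            UNetSegmenter().predict([])


class TestMonteCarloCV:
    def test_pooled_validation_counts_and_coverage(self):
        dataset = [_tiny_pair(i, f"s{i:02d}") for i in range(6)]
        models, pooled = mc_cross_validate(
            dataset, n_folds=3, n_val=2, seed=0, config=TINY_CFG, augment="none"
        )
        assert len(models) == 3
        assert len(pooled) == 6  # n_folds x n_val
        assert {p["subject"] for p in pooled} == {f"s{i:02d}" for i in range(6)}

    def test_linear_augmentation_applied_only_to_training(self):
        dataset = [_tiny_pair(i, f"s{i:02d}") for i in range(4)]
        models, pooled = mc_cross_validate(
            dataset, n_folds=2, n_val=2, seed=1, config=TINY_CFG, augment="linear"
        )
        assert len(pooled) == 4

    def test_unknown_augment_mode_rejected(self):
        with pytest.raises(ValueError):
            mc_cross_validate([], augment="bogus")
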