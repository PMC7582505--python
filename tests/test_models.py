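"""Architecture contracts, parameter arithmetic, training behaviour."""

import numpy as np
import pytest

import eegmotor.nn as nn
from eegmotor.features import LabeledDataset
from eegmotor.models import (CnnConfig, ResNetConfig, build_model, load_model,
                             predict_scores, save_model, train_model)


def _pool2(h, w):
    return h // 2, w // 2


def cnn_parameter_oracle(cfg: CnnConfig, input_shape=(270, 32, 2)) -> int:
    """Layer-by-layer shape arithmetic, independent of the engine."""
    h, w, c = input_shape
    k1h, k1w = cfg.conv1_kernel
    total = (k1h * k1w * c + 1) * cfg.conv1_filters
    h, w = h - k1h + 1, w - k1w + 1
    h, w = _pool2(h, w)
    k2h, k2w = cfg.conv2_kernel
    total += (k2h * k2w * cfg.conv1_filters + 1) * cfg.conv2_filters
    h, w = h - k2h + 1, w - k2w + 1
    h, w = _pool2(h, w)
    flat = h * w * cfg.conv2_filters
    for a, b in zip((flat, 100, 25, 10, 5), (100, 25, 10, 5, 1)):
        total += (a + 1) * b
    return total


class TestConfigs:
    def test_kernel_outside_grid_rejected(self):
        with pytest.raises(ValueError, match="conv1_kernel"):
            CnnConfig(conv1_kernel=(3, 3)).validate()

    def test_off_grid_dropout_rejected(self):
        with pytest.raises(ValueError, match="dropout"):
            CnnConfig(dropout_rate=0.07).validate()

    @pytest.mark.parametrize("field,value", [
        ("conv1_filters", 30), ("batch_size", 32), ("iterations", 50)])
    def test_cnn_grid_membership(self, field, value):
        with pytest.raises(ValueError):
            CnnConfig(**{field: value}).validate()

    def test_resnet_grid_membership(self):
        with pytest.raises(ValueError, match="stage1_filters"):
            ResNetConfig(stage1_filters=12).validate()
        with pytest.raises(ValueError, match="second_kernel"):
            ResNetConfig(block_second_kernel=(4, 4)).validate()


class TestBuild:
    def test_cnn_final_layer_has_one_unit(self):
        net = build_model(CnnConfig()).instantiate(0)
        assert net.output_shape == (1,)
        assert net.layers[-1].units == 1

    def test_cnn_parameter_count_matches_oracle(self):
        for cfg in (CnnConfig(),
                    CnnConfig(conv1_filters=50, conv1_kernel=(10, 4),
                              conv2_filters=100)):
            model = build_model(cfg)
            assert model.n_parameters() == cnn_parameter_oracle(cfg)

    def test_resnet_has_exactly_three_stages(self):
        cfg = ResNetConfig(blocks_per_stage=(2, 1, 1), stage1_filters=8)
        net = build_model(cfg).instantiate(0)
        blocks = [l for l in net.layers if isinstance(l, nn.ResidualBlock)]
        assert len(blocks) == 4
        # downsampling only at stage transitions; filters double per stage
        strides = [b.stride for b in blocks]
        filters = [b.filters for b in blocks]
        assert strides == [1, 1, 2, 2]
        assert filters == [8, 8, 16, 32]

    def test_resnet_parameter_count_matches_oracle(self):
        cfg = ResNetConfig(blocks_per_stage=(1, 1, 1), stage1_filters=8,
                           block_second_kernel=(3, 3))
        net = build_model(cfg).instantiate(0)

        def conv(kh, kw, cin, cout):
            return kh * kw * cin * cout + cout

        def bn(c):
            return 2 * c

        def block(cin, f, k2, projected):
            n = conv(3, 3, cin, f) + bn(f) + conv(k2, k2, f, f) + bn(f)
            if projected:
                n += conv(1, 1, cin, f) + bn(f)
            return n

        expected = conv(3, 3, 2, 8) + bn(8)            # stem
        expected += block(8, 8, 3, projected=False)     # stage 1
        expected += block(8, 16, 3, projected=True)     # stage 2
        expected += block(16, 32, 3, projected=True)    # stage 3
        expected += (32 + 1) * 100 + (100 + 1) * 10 + (10 + 1) * 1
        assert net.n_parameters() == expected

    def test_wrong_config_type_rejected(self):
        with pytest.raises(TypeError):
            build_model({"conv1_filters": 25})


class TestGradients:
    def test_backward_matches_finite_differences(self, rng):
        net = nn.Network(
            [nn.Conv2D(3, (2, 2)), nn.MaxPool2D((2, 2)), nn.ELU(),
             nn.ResidualBlock(4, (3, 3), stride=2),
             nn.GlobalAveragePool(), nn.Dense(5), nn.ELU(), nn.Dense(1)],
            (9, 8, 2), seed=0)
        x = rng.standard_normal((4, 9, 8, 2)).astype(np.float32)
        y = rng.standard_normal(4).astype(np.float32)

        def loss():
            p = net.forward(x, training=True)[:, 0]
            return float(np.mean((p - y) ** 2))

        p = net.forward(x, training=True)[:, 0]
        net.backward((2 * (p - y) / len(y)).astype(np.float32)[:, None])
        grads = [g.copy() for _, g in net.param_pairs()]
        eps = 1e-3
        check_rng = np.random.default_rng(1)
        for (param, _), grad in zip(net.param_pairs(), grads):
            flat, gflat = param.ravel(), grad.ravel()
            for idx in check_rng.choice(flat.size,
                                        size=min(4, flat.size),
                                        replace=False):
                old = flat[idx]
                flat[idx] = old + eps
                lp = loss()
                flat[idx] = old - eps
                lm = loss()
                flat[idx] = old
                num = (lp - lm) / (2 * eps)
                assert abs(num - gflat[idx]) <= 2e-2 * max(0.1, abs(num))


@pytest.fixture(scope="module")
def overfit_model(tiny_train):
    """A small CNN trained to interpolate the 40-trial tiny pool."""
    return train_model(build_model(CnnConfig(iterations=200)), tiny_train,
                       seed=0)


class TestTraining:
    def test_same_seed_gives_identical_loss_traces(self, tiny_train):
        model = build_model(CnnConfig())
        sub = tiny_train.subset(np.arange(20))
        a = train_model(model, sub, seed=3)
        b = train_model(model, sub, seed=3)
        assert np.array_equal(a.loss_trace, b.loss_trace)
        assert all(np.array_equal(u, v) for u, v in
                   zip(a.network.get_weights(), b.network.get_weights()))

    def test_overfits_tiny_set_and_predicts_training_labels(
            self, overfit_model, tiny_train):
        # capacity sanity: a net this size must interpolate 40 trials
        pred = overfit_model.predict(tiny_train.features)
        train_mae = float(np.mean(np.abs(pred - tiny_train.scores)))
        assert train_mae < 2.0
        assert abs(pred[0] - tiny_train.scores[0]) < 2.0

    def test_empty_dataset_rejected(self, tiny_train):
        empty = tiny_train.subset(np.array([], dtype=int))
        with pytest.raises(ValueError, match="empty"):
            train_model(build_model(CnnConfig()), empty, seed=0)

    def test_constant_labels_give_constant_prediction(self, tiny_train, rng):
        healthy = tiny_train.subset(
            np.flatnonzero(tiny_train.groups == "healthy"))
        trained = train_model(build_model(CnnConfig()), healthy, seed=0)
        probe = rng.standard_normal((3, 270, 32, 2)).astype(np.float32)
        assert np.allclose(trained.predict(probe), 66.0, atol=0.5)

    def test_prediction_count_matches_input(self, overfit_model, tiny_train):
        scores = predict_scores(overfit_model, tiny_train.features[:7])
        assert scores.shape == (7,)

    def test_clipping_flag_bounds_scores(self, overfit_model, tiny_train):
        clipped = overfit_model.predict(tiny_train.features, clip=True)
        assert clipped.min() >= 0.0 and clipped.max() <= 66.0

    def test_shape_mismatch_rejected(self, overfit_model, rng):
        with pytest.raises(ValueError, match="shape"):
            overfit_model.predict(rng.standard_normal((2, 265, 32, 2)))


class TestPersistence:
    def test_save_load_round_trip(self, overfit_model, tiny_train, tmp_path):
        save_model(overfit_model, tmp_path / "model")
        back = load_model(tmp_path / "model")
        assert back.config == overfit_model.config
        x = tiny_train.features[:5]
        assert np.allclose(back.predict(x), overfit_model.predict(x))
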