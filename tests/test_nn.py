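"""Neural module: loss formulas, gradients, architecture contracts and
smoke-scale training behavior."""

import numpy as np
import pytest

from glottalmidline.nn import (
    MidlineNet, RecurrentMidlineNet, GlottisNet,
    MidlineNetSpec, RecurrentSpec, GlottisNetSpec, build,
    mae, mse, logcosh, huber, dice,
    TrainConfig, make_keypoint_dataset, train, evaluate)
from glottalmidline.nn.autodiff import Tensor
from glottalmidline.nn.layers import count_parameters, ConvLSTM2D


class TestLosses:
    def test_zero_at_identity(self):
        y = np.array([1.0, -2.0, 3.0])
        for loss in (mae, mse, logcosh):
            assert loss(y, y).data == pytest.approx(0.0)

    def test_mae_mse_hand_values(self):
        y, yh = np.array([1.0, 2.0]), np.array([0.0, 0.0])
        assert mae(y, yh).data == pytest.approx(1.5)
        assert mse(y, yh).data == pytest.approx(2.5)

    def test_huber_piecewise(self):
        assert huber(np.array([2.0]), np.array([0.0]), delta=1.0).data == \
            pytest.approx(1.5)                      # linear branch
        assert huber(np.array([0.5]), np.array([0.0]), delta=1.0).data == \
            pytest.approx(0.125)                    # quadratic branch

    def test_logcosh_matches_reference(self):
        r = np.array([0.3, -1.7, 2.0])
        assert logcosh(r, np.zeros(3)).data == \
            pytest.approx(np.sum(np.log(np.cosh(r))))

    def test_dice_perfect_binary_overlap_is_zero(self):
        y = np.zeros((8, 8))
        y[2:5, 2:5] = 1                             # n foreground
        assert dice(y, y).data == pytest.approx(0.0)

    def test_dice_smoothing_formula(self):
        y = np.array([1.0, 1.0, 0.0])
        yh = np.array([1.0, 0.0, 0.0])
        assert dice(y, yh).data == pytest.approx(1 - (2 * 1 + 1) / (3 + 1))


class TestGradients:
    def _check(self, model, make_loss, param, index, eps=1e-6):
        loss = make_loss()
        loss.backward()
        g = param.grad[index]
        param.data[index] += eps
        l2 = make_loss().data
        param.data[index] -= 2 * eps
        l1 = make_loss().data
        param.data[index] += eps
        assert g == pytest.approx((l2 - l1) / (2 * eps), rel=1e-4, abs=1e-7)

    def test_convnet_gradient(self):
        rng = np.random.default_rng(0)
        net = MidlineNet(MidlineNetSpec(blocks=2, filters=4), seed=0)
        x, y = rng.random((2, 1, 8, 8)), rng.random((2, 4))
        self._check(net, lambda: mse(y, net(Tensor(x))),
                    net.convs[0][0].weight, (0, 0, 1, 1))
        self._check(net, lambda: mae(y, net(Tensor(x))),
                    net.head.weight, (2, 1))

    def test_convlstm_gradient(self):
        rng = np.random.default_rng(1)
        cell = ConvLSTM2D(1, 3, rng=rng)
        xs = [Tensor(rng.random((1, 1, 6, 6))) for _ in range(3)]
        self._check(cell, lambda: (cell(xs) ** 2).mean(),
                    cell.wh.weight, (1, 0, 0, 0))

    def test_glottisnet_gradient(self):
        rng = np.random.default_rng(2)
        net = GlottisNet(GlottisNetSpec(depth=2, base_filters=2), seed=0)
        x = rng.random((1, 1, 8, 8))
        seg_t = (rng.random((1, 1, 8, 8)) > 0.5).astype(float)
        kp_t = rng.random((1, 4))

        def loss():
            seg, kp = net(Tensor(x))
            return dice(Tensor(seg_t), seg) + mse(kp_t, kp)

        self._check(net, loss, net.enc[0][0].weight, (0, 0, 0, 0))
        self._check(net, loss, net.kp_head.weight, (3, 2))


class TestArchitectureContracts:
    def test_midlinenet_parameter_count(self):
        spec = MidlineNetSpec()                     # full published size
        net = MidlineNet(spec)
        n = count_parameters(net)
        assert n == spec.parameter_count()
        assert 50_000 <= n <= 150_000               # ~0.1M at one decimal

    def test_midlinenet_output_is_four_keypoint_values(self):
        net = MidlineNet(MidlineNetSpec(blocks=2, filters=4))
        out = net(Tensor(np.zeros((3, 1, 16, 16))))
        assert out.data.shape == (3, 4)

    def test_recurrent_spec_hyperparameter_ranges(self):
        spec = RecurrentSpec()
        assert 128 <= spec.filters <= 256
        assert 15 <= spec.seq_len <= 21

    def test_recurrent_forward_shape(self):
        net = RecurrentMidlineNet(RecurrentSpec(blocks=2, filters=4,
                                                seq_len=15))
        frames = [Tensor(np.zeros((2, 1, 8, 8))) for _ in range(4)]
        assert net(frames).data.shape == (2, 4)

    def test_glottisnet_dual_outputs(self):
        net = GlottisNet(GlottisNetSpec(depth=2, base_filters=4))
        seg, kp = net(Tensor(np.zeros((2, 1, 16, 16))))
        assert seg.data.shape == (2, 1, 16, 16)    # same H x W as input
        assert kp.data.shape == (2, 4)
        assert np.all((seg.data > 0) & (seg.data < 1))

    def test_build_dispatch(self):
        assert isinstance(build(MidlineNetSpec(blocks=1, filters=2)),
                          MidlineNet)
        assert isinstance(build(RecurrentSpec(blocks=1, filters=2)),
                          RecurrentMidlineNet)
        assert isinstance(build(GlottisNetSpec(depth=1, base_filters=2)),
                          GlottisNet)
        with pytest.raises(TypeError):
            build(object())


@pytest.fixture(scope="module")
def smoke_data():
    """Small paired datasets (single-frame and 21-frame inputs) built
    from the same simulated sequences."""
    single = make_keypoint_dataset(14, seed=21, half_range=0,
                                   image_size=32, peaks_per_sequence=2)
    summed = make_keypoint_dataset(14, seed=21, half_range=10,
                                   image_size=32, peaks_per_sequence=2)
    return single, summed


class TestTraining:
    def test_training_loss_decreases(self, smoke_data):
        _, summed = smoke_data
        net = MidlineNet(MidlineNetSpec(blocks=3, filters=8), seed=0)
        cfg = TrainConfig(epochs=3, learning_rate=1e-3, seed=0)
        hist = train(net, summed, cfg)
        losses = hist["train_loss"]
        assert losses[0] > losses[1] > losses[2]
        assert hist["best_epoch"] == int(np.argmin(hist["val_loss"]))

    def test_determinism_under_fixed_seeds(self, smoke_data):
        _, summed = smoke_data
        hists = []
        for _ in range(2):
            net = MidlineNet(MidlineNetSpec(blocks=2, filters=4), seed=3)
            hists.append(train(net, summed,
                               TrainConfig(epochs=2, learning_rate=1e-3,
                                           seed=5))["train_loss"])
        assert hists[0] == hists[1]

    def test_shuffled_labels_learn_nothing_useful(self, smoke_data):
        _, summed = smoke_data
        cfg = TrainConfig(epochs=60, learning_rate=2e-3, seed=0)

        net_true = MidlineNet(MidlineNetSpec(blocks=3, filters=8), seed=0)
        hist_true = train(net_true, summed, cfg)

        rng = np.random.default_rng(0)
        shuffled = summed.subset(np.arange(len(summed)))
        shuffled.keypoints = shuffled.keypoints[
            rng.permutation(len(shuffled))]
        net_sh = MidlineNet(MidlineNetSpec(blocks=3, filters=8), seed=0)
        hist_sh = train(net_sh, shuffled, cfg)

        assert hist_true["val_loss"][hist_true["best_epoch"]] < \
            hist_sh["val_loss"][hist_sh["best_epoch"]]

    def test_evaluate_reports_point_and_split_quality(self, smoke_data):
        single, _ = smoke_data
        net = MidlineNet(MidlineNetSpec(blocks=2, filters=4), seed=0)
        ev = evaluate(net, single)
        assert set(ev.columns) == {"mape_P", "mape_A", "miou"}
        assert len(ev) == len(single)
        ok = ev["miou"].dropna()
        assert ((ok >= 0) & (ok <= 1)).all()

    def test_non_finite_loss_aborts_with_context(self, smoke_data):
        _, summed = smoke_data
        net = MidlineNet(MidlineNetSpec(blocks=2, filters=4), seed=0)
        net.head.weight.data[:] = np.inf
        with pytest.raises(FloatingPointError, match="epoch"):
            train(net, summed, TrainConfig(epochs=1, seed=0))

    def test_glottisnet_multitask_smoke(self, smoke_data):
        _, summed = smoke_data
        net = GlottisNet(GlottisNetSpec(depth=2, base_filters=4), seed=0)
        cfg = TrainConfig(epochs=2, learning_rate=1e-3, seed=0)
        hist = train(net, summed, cfg)
        assert hist["train_loss"][1] < hist["train_loss"][0]
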