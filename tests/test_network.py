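"""Architecture contracts: shapes, attention bounds, MOFRW identities."""

import numpy as np
import pytest

from mexflow import FlowNet, InputError, NetConfig, ce_loss
from mexflow.autodiff import Tensor
from mexflow.network import (
    ChannelAttention,
    InceptionBlock,
    MOFRW,
    MSFF,
    SpatialAttention,
    load_checkpoint,
    save_checkpoint,
)


@pytest.fixture(scope="module")
def net():
    return FlowNet(NetConfig(n_classes=5, seed=0)).eval()


def _rng_tensor(shape, seed=0, scale=1.0):
    return Tensor(np.random.default_rng(seed).random(shape).astype(np.float32)
                  * scale)


class TestInception:
    def test_output_channels_are_4k(self):
        rng = np.random.default_rng(0)
        blk = InceptionBlock(1, 6, rng)
        out = blk(_rng_tensor((2, 1, 28, 28)))
        assert out.shape == (2, 24, 28, 28)
        blk2 = InceptionBlock(24, 16, rng)
        out2 = blk2(_rng_tensor((2, 24, 14, 14)))
        assert out2.shape == (2, 64, 14, 14)

    def test_zero_input_deterministic_bias_response(self):
        blk = InceptionBlock(1, 4, np.random.default_rng(3))
        x = Tensor(np.zeros((1, 1, 12, 12), dtype=np.float32))
        a = blk(x).data
        b = blk(x).data
        assert np.array_equal(a, b)


class TestSpatialAttention:
    def test_gate_is_open_interval_and_shape_preserved(self):
        sam = SpatialAttention(7, np.random.default_rng(0))
        x = _rng_tensor((2, 8, 14, 14), scale=3.0)
        out, attn = sam(x)
        assert out.shape == x.shape
        assert attn.shape == (2, 1, 14, 14)
        assert np.all(attn.data > 0) and np.all(attn.data < 1)

    def test_zero_input_gives_zero_output(self):
        sam = SpatialAttention(7, np.random.default_rng(0))
        out, _ = sam(Tensor(np.zeros((1, 4, 10, 10), dtype=np.float32)))
        assert np.all(out.data == 0)

    def test_perturbation_is_local_to_receptive_field(self):
        sam = SpatialAttention(3, np.random.default_rng(2))
        x = np.random.default_rng(0).random((1, 2, 16, 16)).astype(np.float32)
        _, a0 = sam(Tensor(x))
        x2 = x.copy()
        x2[0, 0, 8, 8] *= 2.0
        _, a1 = sam(Tensor(x2))
        diff = np.abs(a1.data - a0.data)[0, 0]
        changed = np.argwhere(diff > 1e-12)
        # 3x3 conv on mean/max maps: only the immediate neighbourhood moves
        assert changed.size > 0
        assert np.all(np.abs(changed - [8, 8]).max(axis=1) <= 1)


class TestChannelAttention:
    def test_output_length_and_range(self):
        cam = ChannelAttention(16, 4, np.random.default_rng(0))
        z = cam(_rng_tensor((3, 16, 7, 7)))
        assert z.shape == (3, 16)
        assert np.all(z.data > 0) and np.all(z.data < 1)

    def test_deterministic_in_eval(self):
        cam = ChannelAttention(8, 4, np.random.default_rng(1))
        x = _rng_tensor((2, 8, 5, 5))
        assert np.array_equal(cam(x).data, cam(x).data)

    def test_reduction_clamped_with_warning(self):
        with pytest.warns(UserWarning):
            ChannelAttention(2, 4, np.random.default_rng(0))

    def test_gap_entry_strictly_increases_with_channel_scale(self):
        x = np.random.default_rng(0).random((1, 8, 6, 6)).astype(np.float32)
        gap0 = x.mean(axis=(2, 3))
        x2 = x.copy()
        x2[0, 3] *= 2.0
        gap1 = x2.mean(axis=(2, 3))
        assert gap1[0, 3] > gap0[0, 3]
        assert np.allclose(np.delete(gap1, 3, axis=1), np.delete(gap0, 3, axis=1))


class TestMSFF:
    def test_output_shape_doubles_current_channels(self):
        msff = MSFF(24, 64, 7, np.random.default_rng(0))
        out = msff(_rng_tensor((2, 24, 14, 14)), _rng_tensor((2, 64, 7, 7)))
        assert out.shape == (2, 128, 7, 7)

    def test_zero_inputs_give_zero_output(self):
        msff = MSFF(8, 16, 3, np.random.default_rng(0))
        z1 = Tensor(np.zeros((1, 8, 8, 8), dtype=np.float32))
        z2 = Tensor(np.zeros((1, 16, 4, 4), dtype=np.float32))
        # biases are zero-initialised, so the whole module is zero-preserving
        assert np.allclose(msff(z1, z2).data, 0, atol=1e-7)

    def test_wrong_spatial_ratio_rejected(self):
        msff = MSFF(8, 16, 3, np.random.default_rng(0))
        with pytest.raises(InputError):
            msff(_rng_tensor((1, 8, 12, 12)), _rng_tensor((1, 16, 4, 4)))

    def test_output_sensitive_to_both_levels(self):
        msff = MSFF(8, 16, 3, np.random.default_rng(4))
        prev = Tensor(np.random.default_rng(0).random(
            (1, 8, 8, 8)).astype(np.float32), requires_grad=True)
        curr = Tensor(np.random.default_rng(1).random(
            (1, 16, 4, 4)).astype(np.float32), requires_grad=True)
        msff(prev, curr).sum().backward()
        assert np.abs(prev.grad).max() > 0
        assert np.abs(curr.grad).max() > 0


class TestMOFRW:
    def test_weights_form_probability_simplex(self):
        mod = MOFRW(16, 4, np.random.default_rng(0))
        maps = [_rng_tensor((2, 16, 7, 7), seed=s) for s in range(3)]
        att = mod.branch_weights(*maps)
        assert att.shape == (3, 2, 16)
        assert np.allclose(att.data.sum(axis=0), 1.0, atol=1e-6)
        assert np.all(att.data > 0) and np.all(att.data < 1)

    def test_identical_branches_give_one_third_and_4over3_residual(self):
        mod = MOFRW(8, 4, np.random.default_rng(1))
        f = _rng_tensor((2, 8, 5, 5))
        att = mod.branch_weights(f, f, f)
        assert np.allclose(att.data, 1.0 / 3.0, atol=1e-6)
        out = mod(f, f, f)
        stacked = np.concatenate([f.data] * 3, axis=1)
        assert np.allclose(out.data, (4.0 / 3.0) * stacked, atol=1e-5)

    def test_residual_identity(self):
        mod = MOFRW(8, 4, np.random.default_rng(2))
        maps = [_rng_tensor((1, 8, 5, 5), seed=s) for s in range(3)]
        out = mod(*maps)
        att = mod.branch_weights(*maps).data
        expected_delta = np.concatenate(
            [maps[i].data * att[i][:, :, None, None] for i in range(3)], axis=1)
        f_input = np.concatenate([m.data for m in maps], axis=1)
        assert np.allclose(out.data - f_input, expected_delta, atol=1e-6)

    def test_shape_mismatch_rejected(self):
        mod = MOFRW(8, 4, np.random.default_rng(0))
        with pytest.raises(InputError):
            mod(_rng_tensor((1, 8, 5, 5)), _rng_tensor((1, 8, 5, 5)),
                _rng_tensor((1, 8, 4, 4)))


class TestFlowNet:
    def test_logits_shape_and_finite(self, net):
        x = np.random.default_rng(0).random((8, 3, 28, 28)).astype(np.float32)
        logits = net(x)
        assert logits.shape == (8, 5)
        assert np.all(np.isfinite(logits.data))

    def test_channel_arithmetic(self, net):
        x = Tensor(np.random.default_rng(0).random(
            (2, 3, 28, 28)).astype(np.float32))
        f_u, f_v, f_os = net.branch_maps(x)
        assert f_u.shape == (2, 128, 7, 7)
        feat = net.features(x)
        assert feat.shape == (2, 384, 7, 7)

    def test_eval_forward_is_bit_deterministic(self, net):
        x = np.random.default_rng(1).random((4, 3, 28, 28)).astype(np.float32)
        assert np.array_equal(net(x).data, net(x).data)

    def test_batch_permutation_equivariance(self, net):
        x = np.random.default_rng(2).random((6, 3, 28, 28)).astype(np.float32)
        perm = np.array([3, 0, 5, 1, 4, 2])
        out = net(x).data
        out_perm = net(x[perm]).data
        assert np.allclose(out[perm], out_perm, atol=1e-5)

    def test_wrong_channel_count_rejected(self, net):
        with pytest.raises(InputError):
            net(np.zeros((2, 4, 28, 28), dtype=np.float32))

    def test_end_to_end_gradient_matches_numeric(self):
        # float64 input for a clean second-order finite difference
        net = FlowNet(NetConfig(n_classes=3, seed=5)).eval()
        x = np.random.default_rng(0).random((2, 3, 28, 28))
        y = np.array([0, 2])
        xt = Tensor(x, requires_grad=True)
        ce_loss(net(xt), y).backward()
        pix = (0, 1, 14, 14)
        eps = 1e-5
        xp, xm = x.copy(), x.copy()
        xp[pix] += eps
        xm[pix] -= eps
        num = (float(ce_loss(net(Tensor(xp)), y))
               - float(ce_loss(net(Tensor(xm)), y))) / (2 * eps)
        assert num == pytest.approx(xt.grad[pix], rel=1e-3, abs=1e-9)

    def test_checkpoint_roundtrip(self, net, tmp_path):
        path = tmp_path / "model.npz"
        save_checkpoint(net, path)
        clone = load_checkpoint(path)
        x = np.random.default_rng(3).random((2, 3, 28, 28)).astype(np.float32)
        assert np.array_equal(net(x).data, clone.eval()(x).data)
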