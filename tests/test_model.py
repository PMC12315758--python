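import numpy as np
import pytest

from mridenoise.model import (CBU, CandidateSet, Fondue, NetworkConfig,
                              SlabBatch, build_fondue, build_mcdncnn,
                              build_unet_vinn, combine_candidates,
                              denoise_slab, load_checkpoint, maxout,
                              save_checkpoint, vinn_rescale)
from mridenoise.nn import Tensor
from mridenoise.nn import autograd as ag

from conftest import zero_residual_heads


def _slab(h=64, w=64, res=1.0, seed=0, bs=1):
    rng = np.random.default_rng(seed)
    return SlabBatch(rng.random((bs, 7, h, w), dtype=np.float32),
                     native_res=res)


class TestMaxout:
    def test_idempotent_and_dominant(self, rng):
        x = Tensor(rng.random((2, 3, 8, 8)))
        np.testing.assert_array_equal(maxout(x, x).data, x.data)
        y = Tensor(x.data + 1.0)
        np.testing.assert_array_equal(maxout(x, y).data, y.data)

    def test_matches_elementwise_oracle(self, rng):
        a = rng.standard_normal((3, 4, 6, 6)).astype(np.float32)
        b = rng.standard_normal((3, 4, 6, 6)).astype(np.float32)
        out = maxout(Tensor(a), Tensor(b)).data
        oracle = np.where(a >= b, a, b)
        np.testing.assert_array_equal(out, oracle)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            maxout(Tensor(np.zeros((1, 2, 4, 4))), Tensor(np.zeros((1, 2, 4, 5))))


class TestVinnRescale:
    def test_unit_factor_keeps_shape(self, rng):
        x = Tensor(rng.random((1, 2, 32, 32)))
        out = vinn_rescale(x, 1.0, 1.0, "to_internal")
        assert out.data.shape == x.data.shape
        np.testing.assert_allclose(out.data, x.data, atol=1e-6)

    def test_half_factor_halves_dims(self, rng):
        x = Tensor(rng.random((1, 1, 256, 256)))
        out = vinn_rescale(x, 0.5, 1.0, "to_internal")
        assert out.data.shape == (1, 1, 128, 128)

    @pytest.mark.parametrize("r_out", [0.5, 0.7, 1.2])
    def test_round_trip_restores_shape(self, rng, r_out):
        x = Tensor(rng.random((1, 2, 48, 40)))
        down = vinn_rescale(x, r_out, 1.0, "to_internal")
        up = vinn_rescale(down, r_out, 1.0, "to_native", target_hw=(48, 40))
        assert up.data.shape == x.data.shape

    def test_too_small_output_rejected(self, rng):
        x = Tensor(rng.random((1, 1, 16, 16)))
        with pytest.raises(ValueError):
            vinn_rescale(x, 0.1, 1.0, "to_internal")


class TestCBU:
    def test_spatial_shape_preserved(self, rng):
        blk = CBU(7, 5, "input", False, np.random.default_rng(0))
        out = blk(Tensor(rng.random((2, 7, 20, 24), ).astype(np.float32)))
        assert out.data.shape == (2, 5, 20, 24)

    def test_output_kind_collapses_to_one_channel(self, rng):
        blk = CBU(5, 5, "output", False, np.random.default_rng(0))
        out = blk(Tensor(rng.random((1, 5, 16, 16)).astype(np.float32)))
        assert out.data.shape == (1, 1, 16, 16)

    def test_batchnorm_adds_only_norm_parameters(self):
        plain = CBU(5, 5, "standard", False, np.random.default_rng(0))
        normed = CBU(5, 5, "standard", True, np.random.default_rng(0))
        conv_params = lambda m: sum(p.data.size for n, p in
                                    m.named_parameters() if "conv" in n)
        assert conv_params(plain) == conv_params(normed)
        # extra parameters are exactly the gamma/beta pairs of three layers
        assert normed.n_parameters() - plain.n_parameters() == 3 * 2 * 5


class TestFondue:
    def test_six_candidates_full_shape(self, tiny_net):
        cands = tiny_net.forward(_slab(64, 64))
        assert len(cands.ys) == 6
        for y in cands.ys:
            assert y.data.shape == (1, 1, 64, 64)

    def test_input_channels_enforced(self, tiny_net):
        rng = np.random.default_rng(0)
        bad = SlabBatch(rng.random((1, 5, 32, 32), dtype=np.float32))
        with pytest.raises(ValueError):
            tiny_net.forward(bad)

    @pytest.mark.parametrize("hw", [64, 96])
    @pytest.mark.parametrize("res", [0.7, 1.0, 1.2])
    def test_shape_preservation_across_resolutions(self, tiny_net, hw, res):
        out = denoise_slab(tiny_net, _slab(hw, hw, res=res))
        assert out.data.shape == (1, 1, hw, hw)

    def test_zero_residual_identity(self):
        net = build_fondue(NetworkConfig(n_filt=4, seed=0))
        zero_residual_heads(net)
        slab = _slab(32, 32)
        out = denoise_slab(net, slab)
        np.testing.assert_array_equal(out.data, slab.middle)

    def test_parameter_count_deterministic(self):
        a = build_fondue(NetworkConfig(n_filt=6, seed=0))
        b = build_fondue(NetworkConfig(n_filt=6, seed=1))
        assert a.n_parameters() == b.n_parameters()

    def test_constant_filters_without_doubling(self):
        net = build_fondue(NetworkConfig(n_filt=6, seed=0))
        for name, p in net.named_parameters():
            if "conv" in name and "collapse" not in name and p.data.ndim == 4:
                assert p.data.shape[0] == 6

    def test_filter_doubling_per_pooling_level(self):
        net = build_fondue(NetworkConfig(n_filt=8, seed=0,
                                         filter_doubling=True))
        assert net.row_filt == [8, 8, 16, 32, 64, 128, 256]
        w = dict(net.named_parameters())
        assert w["cbu_3_0.conv1.weight"].data.shape[0] == 32
        assert w["cbu_6_0.conv1.weight"].data.shape[0] == 256
        out = denoise_slab(net, _slab(32, 32))
        assert out.data.shape == (1, 1, 32, 32)

    def test_repeat_forward_is_bit_reproducible(self, tiny_net):
        slab = _slab(48, 48, seed=5)
        a = denoise_slab(tiny_net, slab).data
        b = denoise_slab(tiny_net, slab).data
        np.testing.assert_array_equal(a, b)

    def test_checkpoint_round_trip(self, tmp_path, tiny_net):
        slab = _slab(32, 32, seed=3)
        before = denoise_slab(tiny_net, slab).data
        path = str(tmp_path / "ckpt.npz")
        save_checkpoint(path, tiny_net, extra={"note": "test"})
        net2, extra = load_checkpoint(path)
        assert extra["note"] == "test"
        after = denoise_slab(net2, slab).data
        np.testing.assert_array_equal(before, after)


class TestCombineCandidates:
    def _cands(self, ys, lams):
        return CandidateSet(ys=[Tensor(y) for y in ys],
                            lambdas=[Tensor(np.float32(l), requires_grad=True)
                                     for l in lams])

    def test_identical_maps_fixed_point(self, rng):
        y = rng.random((1, 1, 8, 8))
        out = combine_candidates(self._cands([y] * 6, [1.0] * 6))
        np.testing.assert_allclose(out.data, y, atol=1e-7)

    def test_selection_by_single_weight(self, rng):
        ys = [rng.random((1, 1, 8, 8)) for _ in range(6)]
        out = combine_candidates(self._cands(ys, [1, 0, 0, 0, 0, 0]))
        np.testing.assert_allclose(out.data, ys[0], atol=1e-7)

    def test_matches_weighted_mean_oracle(self, rng):
        ys = [rng.standard_normal((1, 1, 8, 8)) for _ in range(6)]
        lams = rng.standard_normal(6) + 2.0
        out = combine_candidates(self._cands(ys, lams))
        oracle = sum(l * y for l, y in zip(lams, ys)) / lams.sum()
        np.testing.assert_allclose(out.data, oracle, atol=1e-6)

    def test_zero_weight_sum_rejected(self, rng):
        ys = [rng.random((1, 1, 4, 4)) for _ in range(6)]
        with pytest.raises(FloatingPointError):
            combine_candidates(self._cands(ys, [1, -1, 1, -1, 1, -1]))


class TestComparators:
    def test_mcdncnn_layer_and_filter_contract(self):
        net = build_mcdncnn(NetworkConfig(n_filt=64, seed=0))
        assert net.n_conv_layers() == 17
        hidden = [p for n, p in net.named_parameters()
                  if "conv" in n and "weight" in n and p.data.ndim == 4]
        assert len(hidden) == 17
        for w in hidden[:-1]:
            assert w.data.shape[0] == 64

    def test_mcdncnn_zeroed_output_is_identity(self):
        net = build_mcdncnn(NetworkConfig(n_filt=8, seed=0))
        net.conv_out.weight.data[...] = 0.0
        net.conv_out.bias.data[...] = 0.0
        slab = _slab(32, 32)
        out = denoise_slab(net, slab)
        np.testing.assert_array_equal(out.data, slab.middle)

    def test_unet_vinn_bottleneck_and_levels(self):
        net = build_unet_vinn(NetworkConfig(seed=0), base_filters=32)
        assert net.LEVELS == 5
        assert net.bottleneck_filters == 512

    def test_unet_vinn_shape_preservation(self):
        net = build_unet_vinn(NetworkConfig(seed=0), base_filters=4)
        out = denoise_slab(net, _slab(96, 96))
        assert out.data.shape == (1, 1, 96, 96)


def test_lambda_parameters_receive_gradient(tiny_net):
    slab = _slab(32, 32)
    pred = denoise_slab(tiny_net, slab)
    loss = ag.mean(ag.square(pred))
    loss.backward()
    for lam in tiny_net.lambdas:
        assert lam.grad is not None
        assert np.isfinite(lam.grad).all()
    tiny_net.zero_grad()
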