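"""Network blocks: shape contracts, residual identity, attention oracle."""

import numpy as np
import pytest

from mediseg.backbone import (
    AttentionGate,
    Backbone,
    BackboneConfig,
    Downsample,
    ResidualBlock,
    Upsample,
    backbone_forward,
)
from mediseg.nn.layers import sigmoid, softmax_channels
from mediseg.resample import linear_matrix, resize_linear

RNG = lambda s=0: np.random.default_rng(s)

SMALL = BackboneConfig(in_channels=1, base_channels=4, num_levels=3,
                       num_classes=2, use_attention=True)


class TestResidualBlock:
    def test_identity_at_zero_residual(self):
        blk = ResidualBlock(4, 4, RNG(0))
        blk.conv2.params["w"][:] = 0  # F ends at 0 (norm beta is 0)
        blk.conv2.params["b"][:] = 0
        x = RNG(1).normal(size=(4, 8, 8, 8)).astype(np.float32)
        out = blk.forward(x)
        assert np.allclose(out, x, atol=1e-5)

    def test_shape_contract_with_projection(self):
        blk = ResidualBlock(8, 16, RNG(0))
        x = RNG(1).normal(size=(8, 16, 16, 8)).astype(np.float32)
        assert blk.forward(x).shape == (16, 16, 16, 8)

    def test_gradient_matches_finite_difference(self):
        # float64 end-to-end check through conv + norm + relu + shortcut
        blk = ResidualBlock(2, 2, RNG(0)).to_dtype(np.float64)
        x = RNG(2).normal(size=(2, 6, 6, 6))
        out = blk.forward(x)
        g = np.ones_like(out)
        blk.zero_grad()
        dx = blk.backward(g)
        rng = RNG(3)
        for _ in range(4):
            i = tuple(rng.integers(0, s) for s in x.shape)
            eps = 1e-6
            xp, xm = x.copy(), x.copy()
            xp[i] += eps
            xm[i] -= eps
            num = (blk.forward(xp).sum() - blk.forward(xm).sum()) / (2 * eps)
            assert num == pytest.approx(dx[i], rel=1e-5, abs=1e-7)


class TestResampling:
    def test_downsample_halves_and_upsample_doubles(self):
        x = RNG(0).normal(size=(4, 32, 32, 8)).astype(np.float32)
        down = Downsample(4, 8, RNG(1))
        y = down.forward(x)
        assert y.shape == (8, 16, 16, 4)
        up = Upsample(8, 4, RNG(2))
        z = up.forward(y)
        assert z.shape == (4, 32, 32, 8)

    def test_repeated_halving(self):
        shape = np.array([64, 64, 32])
        for _ in range(3):
            shape = shape // 2
        assert tuple(shape) == (8, 8, 4)

    def test_odd_dim_raises_naming_axis(self):
        down = Downsample(2, 2, RNG(0))
        x = np.zeros((2, 8, 8, 7), dtype=np.float32)
        with pytest.raises(ValueError, match="axis D"):
            down.forward(x)

    def test_constant_map_upsampling_stays_constant(self):
        up = Upsample(3, 3, RNG(0))
        x = np.full((3, 4, 4, 4), 2.0, dtype=np.float32)
        y = resize_linear(x, (8, 8, 8))
        assert np.allclose(y, 2.0)
        assert up.forward(x).shape == (3, 8, 8, 8)

    def test_adjoint_identity(self):
        # <M x, y> == <x, M^T y> for the interpolation matrices
        rng = RNG(5)
        for n_in, n_out in [(8, 16), (16, 8), (5, 9)]:
            M = linear_matrix(n_in, n_out)
            x = rng.normal(size=n_in)
            y = rng.normal(size=n_out)
            assert (M @ x) @ y == pytest.approx(x @ (M.T @ y), rel=1e-12)


def _attention_oracle(gate, x, g):
    """Straight-line re-implementation of the additive attention formula."""
    wt = gate.theta.params["w"]
    bt = gate.theta.params["b"]
    wp = gate.phi.params["w"]
    bp = gate.phi.params["b"]
    wq = gate.psi.params["w"]
    bq = gate.psi.params["b"]
    cs = g.shape[1:]
    f_int = wt.shape[0]
    t = np.zeros((f_int, *cs))
    p = np.zeros((f_int, *cs))
    for f in range(f_int):
        for i in range(cs[0]):
            for j in range(cs[1]):
                for k in range(cs[2]):
                    # stride-2 1x1x1 conv on x picks every other voxel
                    t[f, i, j, k] = (wt[f, :, 0, 0, 0] * x[:, 2 * i, 2 * j, 2 * k]).sum() + bt[f]
                    p[f, i, j, k] = (wp[f, :, 0, 0, 0] * g[:, i, j, k]).sum() + bp[f]
    a = np.maximum(t + p, 0.0)
    s = np.zeros((1, *cs))
    for i in range(cs[0]):
        for j in range(cs[1]):
            for k in range(cs[2]):
                s[0, i, j, k] = (wq[0, :, 0, 0, 0] * a[:, i, j, k]).sum() + bq[0]
    s = 1.0 / (1.0 + np.exp(-s))
    alpha = resize_linear(s, x.shape[1:])
    return x * alpha


class TestAttentionGate:
    def test_alpha_one_is_identity(self):
        gate = AttentionGate(4, 8, RNG(0))
        gate.psi.params["b"][:] = 40.0  # sigmoid saturates to exactly 1.0
        gate.psi.params["w"][:] = 0.0
        x = RNG(1).normal(size=(4, 8, 8, 8)).astype(np.float32)
        g = RNG(2).normal(size=(8, 4, 4, 4)).astype(np.float32)
        assert np.array_equal(gate.forward(x, g), x)

    def test_alpha_zero_silences_skip(self):
        gate = AttentionGate(4, 8, RNG(0))
        gate.psi.params["b"][:] = -40.0
        gate.psi.params["w"][:] = 0.0
        x = RNG(1).normal(size=(4, 8, 8, 8)).astype(np.float32)
        g = RNG(2).normal(size=(8, 4, 4, 4)).astype(np.float32)
        assert np.allclose(gate.forward(x, g), 0.0, atol=1e-12)

    def test_matches_straight_line_oracle(self):
        gate = AttentionGate(3, 5, RNG(7)).to_dtype(np.float64)
        x = RNG(8).normal(size=(3, 8, 8, 8))
        g = RNG(9).normal(size=(5, 4, 4, 4))
        ours = gate.forward(x, g)
        oracle = _attention_oracle(gate, x, g)
        assert np.allclose(ours, oracle, atol=1e-10)

    def test_alpha_bounded_in_unit_interval(self):
        gate = AttentionGate(4, 8, RNG(3))
        x = 10 * RNG(4).normal(size=(4, 8, 8, 8)).astype(np.float32)
        g = 10 * RNG(5).normal(size=(8, 4, 4, 4)).astype(np.float32)
        gate.forward(x, g)
        _, _, _, alpha = gate._cache
        assert alpha.min() >= 0.0 and alpha.max() <= 1.0

    def test_incompatible_grids_rejected(self):
        gate = AttentionGate(4, 8, RNG(0))
        with pytest.raises(ValueError, match="half"):
            gate.forward(np.zeros((4, 8, 8, 8), dtype=np.float32),
                         np.zeros((8, 8, 8, 8), dtype=np.float32))


class TestBackbone:
    def test_output_shape_and_softmax_normalization(self):
        probs = backbone_forward(RNG(0).random((1, 32, 32, 16)).astype(np.float32),
                                 SMALL, seed=1)
        assert probs.shape == (2, 32, 32, 16)
        assert np.abs(probs.sum(axis=0) - 1.0).max() < 1e-6
        assert probs.min() >= 0.0

    @pytest.mark.parametrize("shape", [(16, 16, 8), (32, 16, 16), (24, 24, 16)])
    def test_shape_contract_on_varied_inputs(self, shape):
        cfg = BackboneConfig(in_channels=1, base_channels=2, num_levels=3)
        probs = backbone_forward(RNG(1).random((1, *shape)).astype(np.float32), cfg, seed=0)
        assert probs.shape == (2, *shape)

    def test_indivisible_shape_rejected_before_compute(self):
        net = Backbone(SMALL, seed=0)
        with pytest.raises(ValueError, match="divisible"):
            net.forward(np.zeros((1, 30, 32, 16), dtype=np.float32))

    def test_attention_off_equals_gates_forced_open(self):
        cfg_att = SMALL
        cfg_plain = BackboneConfig(in_channels=1, base_channels=4, num_levels=3,
                                   num_classes=2, use_attention=False)
        net_a = Backbone(cfg_att, seed=5)
        net_p = Backbone(cfg_plain, seed=6)
        # share all non-gate weights, then force every alpha to 1
        state = net_a.state_dict()
        shared = {k: v for k, v in state.items() if ".att" not in k}
        net_p.load_state_dict(shared)
        for att in net_a.att:
            att.psi.params["w"][:] = 0.0
            att.psi.params["b"][:] = 40.0
        x = RNG(7).normal(size=(1, 16, 16, 8)).astype(np.float32)
        assert np.allclose(net_a.forward(x), net_p.forward(x), atol=1e-5)

    def test_parameter_count_deterministic(self):
        a = Backbone(SMALL, seed=3)
        b = Backbone(SMALL, seed=3)
        assert a.num_parameters() == b.num_parameters()
        for (na, _, _), (nb, _, _) in zip(a.named_parameters(), b.named_parameters()):
            assert na == nb
        sa, sb = a.state_dict(), b.state_dict()
        assert all(np.array_equal(sa[k], sb[k]) for k in sa)


def test_config_yaml_round_trip():
    cfg = BackboneConfig(in_channels=3, base_channels=8, num_levels=3)
    assert BackboneConfig.from_yaml(cfg.to_yaml()) == cfg


def test_config_validation():
    with pytest.raises(ValueError):
        BackboneConfig(num_classes=1)
    with pytest.raises(ValueError):
        BackboneConfig(num_levels=1)
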