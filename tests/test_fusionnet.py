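"""Fusion operators: Kronecker structure, back-projection, model reductions."""

import numpy as np
import pytest

from prommf._tensor import Tensor
from prommf.fusionnet import (
    DMLPNet,
    FusionConfig,
    FusionNet,
    back_project,
    build_model,
    classify,
    concat_fuse,
    dmlp_forward,
    kron_fuse,
    late_fusion,
    progressive_fuse,
    unimodal_heads,
)
from prommf.nn import bce_with_logits


class TestKronFuse:
    def test_d2_hand_outer_product(self):
        """(1,2,1)^T (3,4,1) flattened row-major."""
        out = kron_fuse(np.array([1.0, 2.0]), np.array([3.0, 4.0]))
        assert np.array_equal(out, [3, 4, 1, 6, 8, 2, 3, 4, 1])

    def test_zero_inputs_leave_only_unit_corner(self):
        out = kron_fuse(np.zeros(32), np.zeros(32))
        assert out.shape == (1089,)
        assert out[-1] == 1.0 and np.all(out[:-1] == 0)

    def test_sparse_input_lands_in_last_column(self):
        h = np.zeros(32)
        h[0] = 2.0
        out = kron_fuse(h, np.zeros(32)).reshape(33, 33)
        nz = np.argwhere(out != 0)
        assert {tuple(i) for i in nz} == {(0, 32), (32, 32)}
        assert out[0, 32] == 2.0 and out[32, 32] == 1.0

    @pytest.mark.parametrize("seed", range(5))
    def test_last_row_and_column_preserve_unimodal_vectors(self, seed):
        rng = np.random.default_rng(seed)
        h, g = rng.normal(size=32), rng.normal(size=32)
        m = kron_fuse(h, g).reshape(33, 33)
        assert np.array_equal(m[32], np.append(g, 1.0))
        assert np.array_equal(m[:, 32], np.append(h, 1.0))
        assert np.linalg.matrix_rank(m) == 1

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            kron_fuse(np.array([np.inf, 0.0]), np.zeros(2))


class TestConcatFuse:
    def test_layout_image_block_first(self):
        h = np.arange(1.0, 33.0)
        g = np.arange(33.0, 65.0)
        out = concat_fuse(h, g)
        assert out.shape == (64,)
        assert np.array_equal(out[:32], h) and np.array_equal(out[32:], g)


class TestLateFusion:
    def test_weight_one_returns_image(self):
        assert late_fusion(0.7, 0.1, w=1.0) == 0.7

    def test_equal_probabilities_are_fixed_point(self):
        for w in (0.0, 0.3, 1.0):
            assert late_fusion(0.42, 0.42, w) == pytest.approx(0.42)

    def test_hand_arithmetic(self):
        assert late_fusion(0.2, 0.9, w=0.3) == pytest.approx(0.69)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            late_fusion(0.5, 0.5, w=1.5)
        with pytest.raises(ValueError):
            late_fusion(1.2, 0.5, w=0.5)


def _net(rng, mode="kron", progressive=True, iterations=2, d=2, omic_dim=5,
         share=True):
    cfg = FusionConfig(mode=mode, progressive=progressive, iterations=iterations,
                       unimodal_dim=d, classifier_hidden=4, omic_hidden=6,
                       share_backprojection_weights=share, proj_dim=4, attn_dim=3)
    return FusionNet(omic_dim=omic_dim, config=cfg, in_dim=8, rng=rng)


class TestProgressiveFusion:
    @pytest.mark.parametrize("mode", ["kron", "concat"])
    @pytest.mark.parametrize("iterations", [1, 2, 3, 4, 5])
    def test_zero_backprojection_reduces_to_single_pass(self, rng, mode, iterations):
        net = _net(rng, mode=mode, iterations=iterations, d=3)
        for k in net.params:
            if k.startswith("backproj"):
                net.params[k].data[:] = 0.0
        h, g = rng.normal(size=3), rng.normal(size=3)
        fused = progressive_fuse(h, g, net)
        single = kron_fuse(h, g) if mode == "kron" else concat_fuse(h, g)
        assert np.array_equal(fused, single)

    def test_one_iteration_matches_hand_trace(self, rng):
        """fuse -> back-project -> add -> fuse, traced step by step in NumPy."""
        net = _net(rng, iterations=1, d=2)
        # hand-set small back-projection weights
        W_img = rng.normal(size=(2, 9))
        b_img = rng.normal(size=2)
        W_om = rng.normal(size=(2, 9))
        b_om = rng.normal(size=2)
        net.params["backproj_img0.weight"].data = W_img.copy()
        net.params["backproj_img0.bias"].data = b_img.copy()
        net.params["backproj_omic0.weight"].data = W_om.copy()
        net.params["backproj_omic0.bias"].data = b_om.copy()
        h, g = np.array([1.0, 2.0]), np.array([3.0, 4.0])
        f0 = kron_fuse(h, g)
        hhat = W_img @ f0 + b_img
        ghat = W_om @ f0 + b_om
        expected = kron_fuse(h + hhat, g + ghat)
        assert np.allclose(progressive_fuse(h, g, net), expected, atol=1e-12)

    def test_two_iterations_compose_the_one_step_rule(self, rng):
        """T=2 with shared weights equals applying the T=1 update twice."""
        net = _net(rng, iterations=2, d=2)
        for k in net.params:
            if k.startswith("backproj"):
                net.params[k].data = rng.normal(size=net.params[k].data.shape) * 0.1
        h, g = rng.normal(size=2), rng.normal(size=2)

        def one_step(h0, g0, f):
            hhat, ghat = back_project(f, net)
            return h0 + hhat, g0 + ghat

        f = kron_fuse(h, g)
        h1, g1 = one_step(h, g, f)
        f1 = kron_fuse(h1, g1)
        h2, g2 = one_step(h, g, f1)  # context always added to the originals
        expected = kron_fuse(h2, g2)
        assert np.allclose(progressive_fuse(h, g, net), expected, atol=1e-12)

    def test_iteration_bounds_enforced(self):
        with pytest.raises(ValueError, match="1..5"):
            FusionConfig(iterations=6).validate()
        with pytest.raises(ValueError, match="1..5"):
            FusionConfig(iterations=0).validate()

    def test_backproject_affine_contract(self, rng):
        net = _net(rng, d=2)
        for k in net.params:
            if k.startswith("backproj") and k.endswith("bias"):
                net.params[k].data = rng.normal(size=2)
        hhat0, ghat0 = back_project(np.zeros(9), net)
        assert np.allclose(hhat0, net.params["backproj_img0.bias"].data)
        assert np.allclose(ghat0, net.params["backproj_omic0.bias"].data)


class TestHeads:
    def test_unimodal_heads_are_nonnegative_and_relu_kills_negatives(self, rng):
        net = _net(rng)
        h_hist, h_om = unimodal_heads(rng.normal(size=4), rng.normal(size=5), net)
        assert np.all(h_hist >= 0) and np.all(h_om >= 0)
        # force negative pre-activations: outputs exactly zero
        for k in ("img_head.weight", "img_head.bias", "omic_fc2.weight",
                  "omic_fc2.bias"):
            net.params[k].data = -np.abs(net.params[k].data) - 1.0
        h_hist, h_om = unimodal_heads(np.abs(rng.normal(size=4)),
                                      rng.normal(size=5), net)
        assert np.all(h_hist == 0) and np.all(h_om == 0)

    def test_classifier_zero_weights_give_half(self, rng):
        net = _net(rng)
        for k in net.params:
            if k.startswith("head."):
                net.params[k].data[:] = 0.0
        assert classify(rng.normal(size=9), net) == pytest.approx(0.5)

    def test_classifier_saturates_and_is_deterministic_in_eval(self, rng):
        net = _net(rng)
        net.params["head.fc2.bias"].data[:] = 20.0
        x = rng.normal(size=9)
        p1, p2 = classify(x, net), classify(x, net)
        assert p1 > 0.999 and p1 == p2

    def test_dmlp_zero_weights_and_determinism(self, rng):
        net = DMLPNet(in_dim=6, hidden=(8, 4), rng=rng)
        x = rng.normal(size=6)
        net.eval()
        assert dmlp_forward(x, net) == dmlp_forward(x, net)
        for p in net.params.values():
            p.data[:] = 0.0
        assert dmlp_forward(x, net) == pytest.approx(0.5)


class TestGradientFlow:
    @pytest.mark.parametrize("mode", ["kron", "concat"])
    def test_every_parameter_group_receives_gradient(self, rng, mode):
        """No dead branches: one backward pass touches all weights."""
        net = _net(rng, mode=mode, iterations=2)
        # move off the zero init so back-projection grads can flow
        for k in net.params:
            if k.startswith("backproj"):
                net.params[k].data = rng.normal(size=net.params[k].data.shape) * 0.05
        bag = rng.normal(size=(5, 8))
        omic = rng.normal(size=5)
        net.train()
        z = net.logit(bag, omic, rng)
        loss = bce_with_logits(z, 1.0)
        loss.backward()
        missing = [k for k, p in net.params.items() if p.grad is None]
        assert missing == []
        assert all(np.all(np.isfinite(p.grad)) for p in net.params.values())


class TestRegistry:
    def test_known_names_build(self, rng):
        for name in ("AMIL", "DMLP", "MMF_Kron", "MMF_Con", "ProMMF_Kron",
                     "ProMMF_Con"):
            m = build_model(name, omic_dim=5, in_dim=8,
                            config=FusionConfig(proj_dim=4, attn_dim=3), rng=rng)
            assert m.n_parameters() > 0

    def test_unknown_name_lists_registry(self):
        with pytest.raises(KeyError, match="ProMMF_Kron"):
            build_model("GMBAN", omic_dim=5)

    def test_prommf_kron_fusion_state_respects_structure(self, rng):
        net = _net(rng, d=3)
        states = net.forward_states(rng.normal(size=(4, 8)), rng.normal(size=5))
        assert len(states) == 3  # initial fusion + 2 refinement iterations
        for st in states:
            m = st.h_fusion.reshape(4, 4)
            assert np.allclose(m[-1], np.append(st.h_omic, 1.0))
            assert np.allclose(m[:, -1], np.append(st.h_histology, 1.0))
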