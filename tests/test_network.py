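"""Architecture contracts of the synthesis network."""

import numpy as np
import pytest

from tausynth.nn import autodiff as ad
from tausynth.nn.autodiff import Tensor
from tausynth.nn.layers import AttentionGate, CondConv3d, ConvBlocks
from tausynth.model import (NetworkConfig, RegionalPromptInputs, SynthesisModel,
                            build_regional_tensors, preprocess_mri)
from tausynth.tabular import AuxiliaryEstimates

GRID = (16, 16, 16)


@pytest.fixture(scope="module")
def model():
    return SynthesisModel(NetworkConfig(grid=GRID, encoder_channels=(4, 8),
                                        prompt_channels=2, head_channels=4), seed=0)


@pytest.fixture(scope="module")
def inputs():
    rng = np.random.default_rng(1)
    mri = rng.random((2,) + GRID) + 0.1
    cond = rng.normal(size=(2, 5))
    prompts = RegionalPromptInputs(rng.random((2, 1) + GRID),
                                   0.1 * rng.random((2, 1) + GRID),
                                   np.array([0, 1]))
    return mri, cond, prompts


class TestConvBlocks:
    def test_spatial_shape_preserved_and_deterministic_in_eval(self):
        rng = np.random.default_rng(0)
        blk = ConvBlocks(rng, 3, 5, dropout=0.2, drop_rng=np.random.default_rng(1))
        blk.eval()
        x = np.random.default_rng(2).normal(size=(1, 3, 6, 6, 6))
        a = blk(Tensor(x)).data
        b = blk(Tensor(x)).data
        assert a.shape == (1, 5, 6, 6, 6)
        np.testing.assert_allclose(a, b, atol=1e-7)

    def test_dropout_active_only_in_training(self):
        rng = np.random.default_rng(0)
        blk = ConvBlocks(rng, 2, 2, dropout=0.5, drop_rng=np.random.default_rng(1))
        blk.train()
        x = np.random.default_rng(2).normal(size=(1, 2, 6, 6, 6))
        a = blk(Tensor(x)).data
        b = blk(Tensor(x)).data
        assert not np.allclose(a, b)


class TestAttentionGate:
    def test_coefficients_in_unit_interval_and_symmetry(self):
        rng = np.random.default_rng(3)
        gate = AttentionGate(rng, 4, 4)
        skip = Tensor(rng.normal(size=(1, 4, 8, 8, 8)))
        g = Tensor(rng.normal(size=(1, 4, 8, 8, 8)))
        coef = gate.coefficients(skip, g).data
        assert np.all(coef >= 0.0) and np.all(coef <= 1.0)
        # constant skip + zero gate -> spatially constant coefficients
        const = Tensor(np.ones((1, 4, 8, 8, 8)))
        zero = Tensor(np.zeros((1, 4, 8, 8, 8)))
        cc = gate.coefficients(const, zero).data
        assert np.ptp(cc) < 1e-12

    def test_gating_never_amplifies(self):
        rng = np.random.default_rng(4)
        gate = AttentionGate(rng, 2, 2)
        skip = Tensor(rng.normal(size=(1, 2, 8, 8, 8)))
        g = Tensor(rng.normal(size=(1, 2, 8, 8, 8)))
        out = gate(skip, g).data
        assert np.all(np.abs(out) <= np.abs(skip.data) + 1e-12)

    def test_level_mismatch_fails(self):
        rng = np.random.default_rng(5)
        gate = AttentionGate(rng, 2, 2)
        with pytest.raises(ValueError, match="mismatch"):
            gate(Tensor(np.zeros((1, 2, 8, 8, 8))), Tensor(np.zeros((1, 2, 4, 4, 4))))


class TestCondConv:
    def test_routing_weights_sum_to_one(self):
        rng = np.random.default_rng(6)
        cc = CondConv3d(rng, 2, 3, cond_dim=5, n_experts=4)
        r = cc.routing(Tensor(rng.normal(size=(7, 5)))).data
        np.testing.assert_allclose(r.sum(axis=1), 1.0, atol=1e-12)
        assert np.all(r >= 0)

    def test_conditioning_changes_output_identical_conditioning_does_not(self):
        rng = np.random.default_rng(7)
        cc = CondConv3d(rng, 2, 2, cond_dim=5)
        one = rng.normal(size=(1, 2, 6, 6, 6))
        x = Tensor(np.concatenate([one, one]))  # identical inputs per sample
        same = np.tile(rng.normal(size=(1, 5)), (2, 1))
        out_same = cc(x, Tensor(same)).data
        np.testing.assert_allclose(out_same[0], out_same[1], atol=1e-10)
        diff = same.copy()
        diff[1] += 3.0
        out_diff = cc(x, Tensor(diff)).data
        assert not np.allclose(out_diff[0], out_diff[1])

    def test_conditioning_dim_mismatch_fails(self):
        rng = np.random.default_rng(8)
        cc = CondConv3d(rng, 2, 2, cond_dim=5)
        with pytest.raises(ValueError, match="conditioning dim"):
            cc(Tensor(np.zeros((1, 2, 4, 4, 4))), Tensor(np.zeros((1, 3))))


class TestPreprocess:
    def test_identity_at_grid(self, rng):
        v = rng.random(GRID) + 0.1
        assert np.array_equal(preprocess_mri(v, GRID), v)

    def test_axial_pad_shape_contract(self, rng):
        v = rng.random((16, 16, 12)) + 0.1
        assert preprocess_mri(v, GRID).shape == GRID

    def test_nearest_neighbour_value_subset(self, rng):
        v = rng.random((20, 18, 14)) + 0.1
        out = preprocess_mri(v, GRID)
        assert np.isin(out, v).all()

    def test_empty_or_nonpositive_fails(self):
        with pytest.raises(ValueError):
            preprocess_mri(np.zeros((0, 4, 4)), GRID)
        with pytest.raises(ValueError, match="positive"):
            preprocess_mri(np.zeros((8, 8, 8)), GRID)


class TestRegionalTensors:
    def test_scatter_and_roundtrip(self, atlas16):
        est = AuxiliaryEstimates(
            tau_hat={r: 1.0 + 0.1 * r for r in atlas16.roi_ids},
            sigma_hat={r: 0.05 * r for r in atlas16.roi_ids},
            meta_temp_hat=1.5, abeta_prob=0.9, abeta_status=1, mmse_hat=28.0)
        pr = build_regional_tensors([est], atlas16)
        bg = atlas16.label_volume == 0
        assert np.all(pr.gamma_hat[0, 0][bg] == 0.0)
        assert np.all(pr.s_hat[0, 0][bg] == 0.0)
        for rid in atlas16.roi_ids:
            vox = atlas16.label_volume == rid
            assert np.all(pr.gamma_hat[0, 0][vox] == est.tau_hat[rid])
            assert pr.gamma_hat[0, 0][vox].mean() == pytest.approx(est.tau_hat[rid], abs=1e-12)
        assert pr.covariate_index[0] == 1

    def test_missing_roi_estimate_fails(self, atlas16):
        est = AuxiliaryEstimates(tau_hat={1: 1.0}, sigma_hat={1: 0.1},
                                 meta_temp_hat=1.0, abeta_prob=0.5,
                                 abeta_status=0, mmse_hat=29.0)
        with pytest.raises(ValueError, match="missing ROIs"):
            build_regional_tensors([est], atlas16)


class TestForward:
    def test_output_shape_and_nonnegativity(self, model, inputs):
        mri, cond, prompts = inputs
        out = model.predict(mri, cond, prompts)
        assert out.shape == (2,) + GRID
        assert out.min() >= 0.0

    def test_eval_mode_deterministic(self, model, inputs):
        mri, cond, prompts = inputs
        a = model.predict(mri, cond, prompts)
        b = model.predict(mri, cond, prompts)
        assert np.array_equal(a, b)

    def test_zero_initialized_modulation_is_residual_identity(self, model, inputs):
        _, _, prompts = inputs
        model.eval()
        f = model.modulate_prompt(prompts).data
        expected = np.broadcast_to(model.prompt.data, f.shape)
        assert np.array_equal(f, expected)

    def test_conditioning_sensitivity(self, model, inputs):
        mri, cond, prompts = inputs
        base = model.predict(mri, cond, prompts)
        pert = cond.copy()
        pert[:, 4] += 3.0  # MetaTempTau-hat channel
        assert not np.allclose(base, model.predict(mri, pert, prompts))

    def test_gamma_sensitivity_after_one_gradient_step(self, inputs):
        """The prompt path starts as a no-op; a single optimization step makes
        the output depend on the regional tau tensors."""
        from tausynth.nn.optim import AdamW

        mri, cond, prompts = inputs
        net = SynthesisModel(NetworkConfig(grid=GRID, encoder_channels=(4, 8),
                                           prompt_channels=2, head_channels=4), seed=3)
        net.train()
        out = net.forward(mri, cond, prompts)
        target = np.ones_like(out.data)
        loss = ((out - Tensor(target)) * (out - Tensor(target))).mean()
        opt = AdamW(net.parameters(), lr=1e-2)
        loss.backward()
        mod_grads = [p.grad for p in net.mod_blocks.parameters() if p.grad is not None]
        assert any(np.abs(g).max() > 0 for g in mod_grads)
        opt.step()
        net.eval()
        a = net.predict(mri, cond, prompts)
        bumped = RegionalPromptInputs(prompts.gamma_hat + 1.0, prompts.s_hat,
                                      prompts.covariate_index)
        assert not np.allclose(a, net.predict(mri, cond, bumped))

    def test_ablated_variant_ignores_covariates(self, inputs):
        mri, cond, prompts = inputs
        net = SynthesisModel(NetworkConfig(grid=GRID, encoder_channels=(4, 8),
                                           ablated=True), seed=0)
        a = net.predict(mri)
        assert a.shape == (2,) + GRID and a.min() >= 0
        assert np.array_equal(a, net.predict(mri))

    def test_covariate_index_out_of_range_fails(self, model, inputs):
        mri, cond, prompts = inputs
        bad = RegionalPromptInputs(prompts.gamma_hat, prompts.s_hat, np.array([0, 5]))
        with pytest.raises(ValueError, match="out of range"):
            model.modulate_prompt(bad)

    def test_alternative_gamma_reading_runs(self, inputs):
        mri, cond, prompts = inputs
        net = SynthesisModel(NetworkConfig(grid=GRID, encoder_channels=(4, 8),
                                           prompt_channels=2, head_channels=4,
                                           modulation_includes_gamma=False), seed=1)
        out = net.predict(mri, cond, prompts)
        assert out.shape == (2,) + GRID and out.min() >= 0


def test_checkpoint_roundtrip(tmp_path, model, inputs):
    mri, cond, prompts = inputs
    a = model.predict(mri, cond, prompts)
    path = tmp_path / "model.npz"
    model.save(path)
    back = SynthesisModel.load(path)
    assert np.array_equal(back.predict(mri, cond, prompts), a)


def test_checkpoint_rejects_foreign_file(tmp_path):
    p = tmp_path / "bad.npz"
    np.savez(p, a=np.ones(3))
    with pytest.raises((ValueError, KeyError)):
        SynthesisModel.load(p)


def test_grid_divisibility_enforced():
    with pytest.raises(ValueError, match="divisible"):
        NetworkConfig(grid=(12, 12, 12), encoder_channels=(4, 8, 16, 32))
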