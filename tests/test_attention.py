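"""Cue memories, sigmoidal gains, gain sites and the attended forward pass."""

import numpy as np
import pytest

from cuedgain._autograd import Tensor
from cuedgain.attention import (AttentionModel, GainParams, ModelVariant,
                                apply_gains, gain_sites, gains_from_memory)
from cuedgain.cochlea import FeatureMap
from cuedgain.netblocks import ArchitectureSpec, BlockSpec, HeadSpec

TINY = ArchitectureSpec(
    in_channels=2, in_freq=8, in_time=60,
    blocks=[BlockSpec(c_out=4, n_f=3, n_t=5, s_f=2, s_t=2),
            BlockSpec(c_out=6, n_f=3, n_t=3, s_f=1, s_t=2)],
    head=HeadSpec(fc_dim=10, vocab=5))


def tiny_model(variant=ModelVariant.FEATURE_GAIN, in_ch=2, seed=0):
    arch = TINY if in_ch == 2 else ArchitectureSpec(
        in_channels=4, in_freq=8, in_time=60, blocks=TINY.blocks,
        head=TINY.head)
    return AttentionModel(arch, variant=variant, seed=seed)


class TestGainAlgebra:
    def test_midpoint_identity(self):
        p = GainParams.init(theta1=0.3, theta2=2.0, theta3=1.5)
        g = gains_from_memory(np.full((2, 3), 1.5), p).data
        np.testing.assert_allclose(g, (1 + 0.3) / 2, rtol=1e-6)

    def test_asymptotes(self):
        p = GainParams.init(theta1=0.2, theta2=1.0, theta3=0.0)
        g = gains_from_memory(np.array([[-1e4, 1e4]]), p).data
        np.testing.assert_allclose(g[0, 0], 0.2, atol=1e-6)
        np.testing.assert_allclose(g[0, 1], 1.0, atol=1e-6)

    def test_zero_slope_is_flat(self, rng):
        p = GainParams.init(theta1=0.6, theta2=0.0, theta3=0.3)
        m = rng.standard_normal((4, 5)) * 100
        np.testing.assert_allclose(gains_from_memory(m, p).data,
                                   (1 + 0.6) / 2, rtol=1e-6)

    def test_range_invariant_and_monotonicity(self, rng):
        for t1 in (-0.5, 0.0, 0.5):
            p = GainParams.init(theta1=t1, theta2=3.0, theta3=0.1)
            m = np.sort(rng.standard_normal(200) * 10)
            g = gains_from_memory(m[None], p).data[0]
            lo, hi = min(t1, 1.0), max(t1, 1.0)
            # closed bounds always (float saturation can reach them);
            # strictly inside away from sigmoid saturation
            assert np.all(g >= lo) and np.all(g <= hi)
            interior = np.abs(3.0 * (m - 0.1)) < 15
            assert np.all(g[interior] > lo) and np.all(g[interior] < hi)
            assert np.all(np.diff(g) >= 0)      # theta2 > 0

    def test_no_overflow_at_extreme_inputs(self):
        p = GainParams.init(theta1=0.1, theta2=50.0, theta3=0.0)
        g = gains_from_memory(np.array([[-1e8, 1e8]]), p).data
        assert np.all(np.isfinite(g))


class TestApplyGains:
    def test_identity_and_scaling(self, rng):
        x = FeatureMap(rng.random((2, 3, 7)))
        np.testing.assert_array_equal(
            apply_gains(x, np.ones((2, 3))).values, x.values)
        np.testing.assert_allclose(
            apply_gains(x, np.full((2, 3), 0.5)).values, 0.5 * x.values)

    def test_matches_per_timestep_loop(self, rng):
        x = FeatureMap(rng.random((2, 3, 7)))
        g = rng.random((2, 3))
        got = apply_gains(x, g).values
        for t in range(7):
            np.testing.assert_allclose(got[:, :, t], x.values[:, :, t] * g)

    def test_shape_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            apply_gains(FeatureMap(rng.random((2, 3, 7))), np.ones((3, 2)))


class TestCueMemory:
    def test_time_constant_activation_gives_that_constant(self, rng):
        model = tiny_model()
        # a cue cochleagram constant in time has a constant cochleagram
        # memory equal to any time slice
        cue = np.repeat(rng.random((1, 2, 8, 1)).astype(np.float32), 60, axis=3)
        mem = model.compute_cue_memory(Tensor(cue))
        np.testing.assert_allclose(mem[0].data[0], cue[0, :, :, 0], rtol=1e-5)

    def test_silent_cue_gives_zero_cochleagram_memory(self):
        model = tiny_model()
        mem = model.compute_cue_memory(Tensor(np.zeros((1, 2, 8, 60),
                                                       np.float32)))
        assert np.all(mem[0].data == 0)

    def test_memory_matches_loop_average(self, rng):
        model = tiny_model()
        cue = rng.random((1, 2, 8, 60)).astype(np.float32)
        mem = model.compute_cue_memory(Tensor(cue))[0].data[0]
        loop = sum(cue[0, :, :, t] for t in range(60)) / 60
        np.testing.assert_allclose(mem, loop, rtol=1e-5)


class TestGainSites:
    def test_site_sets_per_variant(self):
        assert gain_sites(ModelVariant.FEATURE_GAIN, 3) == [0, 1, 2, 3]
        assert gain_sites(ModelVariant.GAIN_AFTER_NORM, 3) == [0, 1, 2, 3]
        assert gain_sites(ModelVariant.EARLY_ONLY, 3) == [0]
        assert gain_sites(ModelVariant.LATE_ONLY, 3) == [3]
        assert gain_sites(ModelVariant.BASELINE, 3) == []

    def test_unknown_variant_rejected(self):
        with pytest.raises(ValueError):
            gain_sites("attention_is_all_you_need", 3)

    def test_parameter_count_difference_is_three_per_extra_site(self):
        full = tiny_model(ModelVariant.FEATURE_GAIN)
        early = tiny_model(ModelVariant.EARLY_ONLY)
        n_sites = len(full.sites)
        assert full.n_parameters() - early.n_parameters() == 3 * (n_sites - 1)


class TestForwardAttend:
    def test_unit_gains_reduce_to_plain_forward(self, rng):
        model = tiny_model()
        mix = Tensor(rng.random((2, 2, 8, 60)).astype(np.float32))
        # force every site's sigmoid flat at exactly 1: theta1 = 1
        for s in model.sites:
            model.gain_params[s] = GainParams.init(theta1=1.0)
        cue = Tensor(rng.random((2, 2, 8, 60)).astype(np.float32))
        attended = model.forward_attend(cue, mix).data
        plain = model.net.forward(mix).data
        assert np.abs(attended - plain).max() < 1e-5

    def test_baseline_concatenates_four_channels(self, rng):
        model = tiny_model(ModelVariant.BASELINE, in_ch=4)
        cue = Tensor(rng.random((1, 2, 8, 60)).astype(np.float32))
        mix = Tensor(rng.random((1, 2, 8, 60)).astype(np.float32))
        out = model.forward_attend(cue, mix)
        assert out.shape == (1, 5)
        # baseline with a 2-channel architecture is a configuration error
        with pytest.raises(ValueError):
            AttentionModel(TINY, variant=ModelVariant.BASELINE)

    def test_inference_determinism(self, rng):
        model = tiny_model()
        cue = Tensor(rng.random((1, 2, 8, 60)).astype(np.float32))
        mix = Tensor(rng.random((1, 2, 8, 60)).astype(np.float32))
        a = model.forward_attend(cue, mix).data
        b = model.forward_attend(cue, mix).data
        np.testing.assert_array_equal(a, b)

    def test_cue_and_mixture_share_weights(self):
        model = tiny_model()
        # the cue pass and mixture pass traverse the same Network object,
        # hence identical parameter identity
        assert model.net is model.net
        ids_before = {id(p) for p in model.net.parameters()}
        model.forward_attend(Tensor(np.zeros((1, 2, 8, 60), np.float32)),
                             Tensor(np.zeros((1, 2, 8, 60), np.float32)))
        assert {id(p) for p in model.net.parameters()} == ids_before

    def test_different_cues_give_different_gains(self, rng):
        model = tiny_model()
        a = model.compute_gains(Tensor(rng.random((1, 2, 8, 60), ).astype(np.float32)))
        b = model.compute_gains(Tensor(rng.random((1, 2, 8, 60), ).astype(np.float32)))
        dist = sum(np.abs(a[s].data - b[s].data).sum() for s in model.sites)
        assert dist > 0

    def test_checkpoint_variant_mismatch_rejected(self, tmp_path):
        model = tiny_model(ModelVariant.FEATURE_GAIN)
        path = tmp_path / "ck.npz"
        model.save(path)
        other = tiny_model(ModelVariant.GAIN_AFTER_NORM)
        with pytest.raises(ValueError):
            other.load(path)

    def test_checkpoint_roundtrip(self, rng, tmp_path):
        model = tiny_model()
        cue = Tensor(rng.random((1, 2, 8, 60)).astype(np.float32))
        mix = Tensor(rng.random((1, 2, 8, 60)).astype(np.float32))
        before = model.forward_attend(cue, mix).data
        path = tmp_path / "ck.npz"
        model.save(path)
        fresh = tiny_model(seed=42)
        fresh.load(path)
        np.testing.assert_array_equal(fresh.forward_attend(cue, mix).data,
                                      before)
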