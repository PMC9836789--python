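"""GeM pooling semantics, the multireceptive-field block, and model assembly."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lesionfusion import nn
from lesionfusion.fusion import (GeMParams, MultiReceptiveField, TwoStreamClassifier,
                                 pool_avg, pool_gem, pool_max)
from tests.conftest import tiny_model


class TestPoolingOps:
    def test_max_and_avg_on_known_values(self):
        fm = np.array([1.0, 2.0, 3.0, 4.0]).reshape(2, 2, 1)
        assert pool_max(fm).values[0] == 4.0
        assert pool_avg(fm).values[0] == 2.5

    def test_constant_channel_is_fixed_point_of_all_variants(self):
        fm = np.full((3, 3, 2), 7.0)
        for op in (pool_max, pool_avg):
            np.testing.assert_allclose(op(fm).values, 7.0)
        np.testing.assert_allclose(pool_gem(fm, GeMParams(p=3)).values, 7.0, rtol=1e-4)

    def test_pooling_matches_bruteforce_oracle(self, rng):
        """All three reductions agree with explicit loops over positions."""
        fm = np.abs(rng.normal(size=(7, 7, 5)))
        p = GeMParams(p=4.0, eps=1e-6)
        for k in range(5):
            values = [fm[i, j, k] for i in range(7) for j in range(7)]
            assert pool_max(fm).values[k] == max(values)
            assert np.isclose(pool_avg(fm).values[k], sum(values) / 49)
            brute = (sum((v + p.eps) ** p.p for v in values) / 49) ** (1 / p.p)
            assert np.isclose(pool_gem(fm, p).values[k], brute, rtol=1e-6)

    def test_gem_p1_equals_average(self, rng):
        fm = np.abs(rng.normal(size=(7, 7, 16)))
        np.testing.assert_allclose(pool_gem(fm, GeMParams(p=1.0)).values,
                                   pool_avg(fm).values, atol=1e-5)

    def test_gem_p64_approaches_max(self):
        # closed form: ((10**64)/4)**(1/64) = 10 * 4**(-1/64) ~ 9.786
        fm = np.array([0.0, 0.0, 0.0, 10.0]).reshape(2, 2, 1)
        val = pool_gem(fm, GeMParams(p=64.0)).values[0]
        assert abs(val - 10.0) / 10.0 < 0.05
        assert np.isclose(val, 10 * 4 ** (-1 / 64), rtol=1e-3)

    def test_gem_worked_example_p4(self):
        # ((1+16+81+256)/4)**0.25 = 88.5**0.25 ~ 3.0667
        fm = np.array([1.0, 2.0, 3.0, 4.0]).reshape(2, 2, 1)
        val = pool_gem(fm, GeMParams(p=4.0)).values[0]
        assert np.isclose(val, 88.5 ** 0.25, rtol=1e-4)

    def test_default_exponent_is_four(self):
        assert GeMParams().p == 4.0

    def test_contract_violations(self, rng):
        with pytest.raises(ValueError, match="p >= 1"):
            GeMParams(p=0.5)
        with pytest.raises(ValueError, match="non-negative"):
            pool_gem(np.array([[-1.0]]).reshape(1, 1, 1), GeMParams())
        with pytest.raises(ValueError, match="empty"):
            pool_max(np.empty((0, 3, 2)))

    @given(p=st.sampled_from([1.0, 2.0, 3.0, 4.0, 5.0, 8.0, 16.0]),
           seed=st.integers(0, 50))
    @settings(max_examples=40, deadline=None)
    def test_avg_le_gem_le_max_elementwise(self, p, seed):
        fm = np.abs(np.random.default_rng(seed).normal(size=(7, 7, 8)))
        gem = pool_gem(fm, GeMParams(p=p)).values
        assert np.all(gem >= pool_avg(fm).values - 1e-4)
        assert np.all(gem <= pool_max(fm).values + 1e-4)

    def test_gem_nondecreasing_in_p(self, rng):
        fm = np.abs(rng.normal(size=(7, 7, 32)))
        previous = None
        for p in (1.0, 2.0, 3.0, 4.0, 5.0, 8.0, 16.0):
            current = pool_gem(fm, GeMParams(p=p)).values
            if previous is not None:
                assert np.all(current >= previous - 1e-5)
            previous = current

    def test_spatial_permutation_invariance(self, rng):
        fm = np.abs(rng.normal(size=(6, 6, 4)))
        flat = fm.reshape(36, 4)
        perm = flat[rng.permutation(36)].reshape(6, 6, 4)
        for op in (pool_max, pool_avg, lambda f: pool_gem(f, GeMParams())):
            np.testing.assert_allclose(op(fm).values, op(perm).values, rtol=1e-6)

    def test_batched_input_reduces_to_per_channel_vectors(self, rng):
        fm = np.abs(rng.normal(size=(3, 7, 7, 12)))
        assert pool_gem(fm, GeMParams()).values.shape == (3, 12)


class TestMultiReceptiveField:
    def test_preserves_shape_at_published_width(self, rng):
        mrf = MultiReceptiveField(in_channels=1536, branch_channels=512)
        x = nn.Tensor(np.abs(rng.normal(size=(1, 1536, 7, 7))).astype(np.float32))
        with nn.no_grad():
            out = mrf(x)
        assert out.data.shape == (1, 1536, 7, 7)

    def test_zero_input_zero_biases_gives_zero_output(self):
        mrf = MultiReceptiveField(in_channels=8, branch_channels=4, allow_small=True)
        for p in mrf.parameters():
            if p.data.ndim == 1:
                p.data[:] = 0
        with nn.no_grad():
            out = mrf(nn.Tensor(np.zeros((1, 8, 7, 7), dtype=np.float32)))
        np.testing.assert_array_equal(out.data, 0.0)

    def test_small_spatial_extent_rejected_by_default(self, rng):
        mrf = MultiReceptiveField(in_channels=4, branch_channels=2)
        x = nn.Tensor(np.zeros((1, 4, 5, 5), dtype=np.float32))
        with pytest.raises(ValueError, match="spatial extent"):
            mrf(x)


class TestAssembledModel:
    def test_softmax_rows_sum_to_one(self, rng):
        model = tiny_model()
        x = rng.random((2, 3, 32, 32)).astype(np.float32)
        probs = model.predict_proba(x)
        assert probs.shape == (2, 7)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-5)

    def test_gem_p1_head_matches_explicit_average_pooling(self, rng):
        model = tiny_model(gem_p=1.0)
        x = rng.random((1, 3, 32, 32)).astype(np.float32)
        model.eval()
        model.capture_fusion = True
        with nn.no_grad():
            logits = model(nn.Tensor(x))
        fused = model.fusion_activations.data
        pooled = fused.mean(axis=(2, 3))  # explicit average pooling
        manual = pooled @ model.head.weight.data.T + model.head.bias.data
        np.testing.assert_allclose(logits.data, manual, atol=1e-3)

    def test_ablating_mrf_strictly_reduces_parameters(self):
        full = tiny_model(use_mrf=True)
        ablated = tiny_model(use_mrf=False)
        assert nn.count_parameters(ablated) < nn.count_parameters(full)

    def test_mismatched_stream_spatial_sizes_rejected(self):
        from lesionfusion.backbones import ResidualVGG16Stream

        class FakeStream:
            output_spatial = 3
            output_channels = 8
        vgg = ResidualVGG16Stream(input_size=32, channels=(8, 8),
                                  convs_per_block=(1, 1))
        with pytest.raises(ValueError, match="mismatched spatial"):
            TwoStreamClassifier([vgg, FakeStream()], allow_small=True)
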