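import math

import numpy as np
import pytest

from mnlnet.mnl_layers import (MultiScaleNonLocal, SignalPooling,
                               attention_normalize, multi_pool, pad_to_length,
                               pool_branch_spec, signal_pooling_concat,
                               similarity)


class TestPoolBranchGeometry:
    @pytest.mark.parametrize("w", [4, 5, 7, 80, 178])
    @pytest.mark.parametrize("p", [1, 2, 4])
    def test_length_conservation(self, w, p):
        s = pool_branch_spec(w, p)
        assert s.o == (w - p) + 1
        assert s.l == math.ceil((w - s.o) / 4)
        assert s.o + s.l + s.r == w
        assert s.l >= 0 and s.r >= 0

    def test_window_larger_than_input(self):
        with pytest.raises(ValueError):
            pool_branch_spec(3, 4)


class TestMultiPool:
    def test_window_two(self):
        assert np.array_equal(multi_pool([1.0, 3.0, 2.0, 5.0], 2), [3, 3, 5])

    def test_window_one_is_identity(self):
        x = np.array([4.0, -1.0, 2.0])
        assert np.array_equal(multi_pool(x, 1), x)

    def test_window_equals_length_gives_global_max(self):
        assert np.array_equal(multi_pool([1.0, 3.0, 2.0, 5.0], 4), [5.0])

    def test_channelwise(self, rng):
        x = rng.standard_normal((6, 3))
        out = multi_pool(x, 2)
        for t in range(5):
            assert np.array_equal(out[t], x[t:t + 2].max(axis=0))


class TestPadToLength:
    def test_examples(self):
        assert np.array_equal(pad_to_length([3.0, 3.0, 5.0], 4), [0, 3, 3, 5])
        assert np.array_equal(pad_to_length([5.0], 4), [0, 5, 0, 0])

    def test_identity_when_equal(self):
        x = np.array([1.0, 2.0])
        assert np.array_equal(pad_to_length(x, 2), x)

    def test_too_long_rejected(self):
        with pytest.raises(ValueError):
            pad_to_length(np.ones(5), 4)


class TestSignalPoolingConcat:
    def test_worked_example_columns(self):
        cat = signal_pooling_concat(np.array([1.0, 3.0, 2.0, 5.0])[:, None])
        expected = np.column_stack([[1, 3, 2, 5], [0, 3, 3, 5], [0, 5, 0, 0]])
        assert np.array_equal(cat, expected)

    def test_zero_input_stays_zero(self):
        assert np.array_equal(signal_pooling_concat(np.zeros((6, 2))),
                              np.zeros((6, 6)))


class TestSignalPoolingLayer:
    def test_shape_preserving_with_reduce(self, rng):
        layer = SignalPooling(80, reduce="conv", rng=rng)
        x = rng.standard_normal((3, 4, 80))
        assert layer.forward(x).shape == (3, 4, 80)

    def test_concat_mode_matches_functional_form(self, rng):
        layer = SignalPooling(5, reduce="none")
        x = rng.standard_normal((2, 7, 5))
        out = layer.forward(x)
        for b in range(2):
            assert np.allclose(out[b], signal_pooling_concat(x[b]))

    def test_input_shorter_than_largest_window(self, rng):
        layer = SignalPooling(2)
        with pytest.raises(ValueError):
            layer.forward(rng.standard_normal((1, 3, 2)))


class TestSimilarity:
    def test_identity_embeddings(self):
        eye = np.eye(2)
        assert np.array_equal(similarity(eye, eye), np.eye(2))

    def test_single_channel_dot_product(self):
        r = similarity(np.array([[1.0], [2.0]]), np.array([[3.0], [4.0]]))
        assert r.shape == (1, 1) and r[0, 0] == 11.0

    def test_matches_double_loop(self, rng):
        phi = rng.standard_normal((5, 3))
        delta = rng.standard_normal((5, 3))
        r = similarity(phi, delta)
        brute = np.zeros((3, 3))
        for i in range(3):
            for j in range(3):
                for t in range(5):
                    brute[i, j] += phi[t, i] * delta[t, j]
        assert np.allclose(r, brute, atol=1e-12)

    def test_bilinear_in_first_argument(self, rng):
        phi = rng.standard_normal((4, 2))
        delta = rng.standard_normal((4, 2))
        assert np.allclose(similarity(3.5 * phi, delta),
                           3.5 * similarity(phi, delta))

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            similarity(np.ones((3, 2)), np.ones((4, 2)))


class TestAttentionNormalize:
    def test_closed_form_two_by_two(self):
        r_hat = attention_normalize(np.array([[1.0, 0.0], [0.0, 1.0]]))
        e = np.e
        row = [e / (e + 1), 1 / (e + 1)]
        assert np.allclose(r_hat, [row, row[::-1]], atol=1e-6)

    def test_constant_matrix_uniform_rows(self):
        r_hat = attention_normalize(np.full((4, 4), 7.3))
        assert np.allclose(r_hat, 0.25)

    def test_rows_sum_to_one_and_positive(self, rng):
        r_hat = attention_normalize(rng.standard_normal((6, 6)) * 10)
        assert np.allclose(r_hat.sum(axis=-1), 1.0, atol=1e-6)
        assert np.all(r_hat > 0) and np.all(r_hat < 1)


def nonlocal_oracle(x, layer):
    """Explicit-loop forward pass of the channel-attention non-local layer."""
    w, c = x.shape
    ch = layer.c_hat
    wp = layer.conv_phi.weight.value[0]; bp = layer.conv_phi.bias.value
    wd = layer.conv_delta.weight.value[0]; bd = layer.conv_delta.bias.value
    wr = layer.conv_rho.weight.value[0]; br = layer.conv_rho.bias.value
    wi = layer.conv_inner.weight.value[0]; bi = layer.conv_inner.bias.value
    wo = layer.conv_outer.weight.value[0]; bo = layer.conv_outer.bias.value

    def pointwise(inp, wmat, bias):
        out = [[bias[f] + sum(inp[t][cc] * wmat[cc][f] for cc in range(len(inp[0])))
                for f in range(len(bias))] for t in range(len(inp))]
        return out

    phi = pointwise(x.tolist(), wp.tolist(), bp.tolist())
    delta = pointwise(x.tolist(), wd.tolist(), bd.tolist())
    rho = pointwise(x.tolist(), wr.tolist(), br.tolist())
    r = [[sum(phi[t][i] * delta[t][j] for t in range(w)) for j in range(ch)]
         for i in range(ch)]
    r_hat = []
    for i in range(ch):
        m = max(r[i])
        exps = [math.exp(v - m) for v in r[i]]
        tot = sum(exps)
        r_hat.append([v / tot for v in exps])
    attended = [[sum(rho[t][j] * r_hat[i][j] for j in range(ch))
                 for i in range(ch)] for t in range(w)]
    inner = pointwise(attended, wi.tolist(), bi.tolist())
    z = [[inner[t][cc] + x[t, cc] for cc in range(c)] for t in range(w)]
    return np.array(pointwise(z, wo.tolist(), bo.tolist()))


class TestMultiScaleNonLocal:
    def test_shape_preserving(self, rng):
        layer = MultiScaleNonLocal(80, rng=rng)
        assert layer.c_hat == 40  # default c/2
        x = rng.standard_normal((2, 4, 80))
        assert layer.forward(x).shape == (2, 4, 80)

    def test_identity_embeddings_reproduce_input(self, rng):
        layer = MultiScaleNonLocal(3, c_hat=3, rng=rng)
        for conv in (layer.conv_phi, layer.conv_delta, layer.conv_rho):
            conv.weight.value[0] = np.eye(3)
            conv.bias.value[:] = 0.0
        x = rng.standard_normal((1, 5, 3))
        layer.forward(x)
        phi = layer.conv_phi.forward(x)
        assert np.allclose(phi, x)

    def test_zero_inner_identity_outer_is_residual_passthrough(self, rng):
        layer = MultiScaleNonLocal(4, c_hat=2, rng=rng)
        layer.conv_inner.weight.value[:] = 0.0
        layer.conv_inner.bias.value[:] = 0.0
        layer.conv_outer.weight.value[0] = np.eye(4)
        layer.conv_outer.bias.value[:] = 0.0
        x = rng.standard_normal((3, 6, 4))
        assert np.allclose(layer.forward(x), x, atol=1e-12)

    def test_matches_explicit_loop_oracle(self, rng):
        layer = MultiScaleNonLocal(8, c_hat=4, rng=rng)
        x = rng.standard_normal((1, 4, 8))
        out = layer.forward(x)
        assert np.allclose(out[0], nonlocal_oracle(x[0], layer), atol=1e-5)

    def test_deterministic_forward(self, rng):
        layer = MultiScaleNonLocal(6, c_hat=3, rng=rng)
        x = rng.standard_normal((2, 5, 6))
        assert np.array_equal(layer.forward(x), layer.forward(x))

    def test_position_mode_shape(self, rng):
        layer = MultiScaleNonLocal(6, c_hat=3, mode="position", rng=rng)
        x = rng.standard_normal((2, 5, 6))
        assert layer.forward(x).shape == (2, 5, 6)
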