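"""Edge-filter kernels, sparse convolution, and peak location."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from octfp import edge_filter as ef


def dense_oracle(line, L):
    """Independent dense-convolution reference with the normalized ramp."""
    half = L // 2
    k0 = np.concatenate([np.arange(1, half + 1), -np.arange(half, 0, -1)])
    k0 = k0 * (2.0 / L) / (L / 2 + 1)
    full = np.convolve(np.asarray(line, float), k0)
    return full[half - 1 : half - 1 + len(line)]


class TestKernels:
    def test_frozen_family_L4(self):
        k = ef.make_kernels(4)
        assert k.taps0.tolist() == [1, 2, -2, -1]
        assert k.taps1.tolist() == [1, 1, -4, 1, 1]
        assert k.taps2.tolist() == [1, 0, -5, 5, 0, -1]
        assert k.norm == pytest.approx(1 / 6)

    @pytest.mark.parametrize("L", [2, 4, 8, 16, 32, 64])
    def test_difference_rule_and_sparsity(self, L):
        k = ef.make_kernels(L)
        assert len(k.taps0) == L and len(k.taps1) == L + 1 and len(k.taps2) == L + 2
        # each level is the zero-padded first difference of the previous
        np.testing.assert_array_equal(k.taps1, np.diff(k.taps0, prepend=0, append=0))
        np.testing.assert_array_equal(k.taps2, np.diff(k.taps1, prepend=0, append=0))
        # ramp is antisymmetric, all levels sum to zero
        np.testing.assert_array_equal(k.taps0, -k.taps0[::-1])
        for taps in (k.taps0, k.taps1, k.taps2):
            assert taps.sum() == 0
        assert np.count_nonzero(k.taps2) == 4
        assert sorted(np.abs(k.taps2[k.taps2 != 0]).tolist()) == [1, 1, L + 1, L + 1]

    @pytest.mark.parametrize("L", [0, 3, 7, -2])
    def test_invalid_sizes_rejected(self, L):
        with pytest.raises(ValueError):
            ef.make_kernels(L)

    def test_normalize_idempotent(self):
        k = ef.normalize(ef.make_kernels(8))
        assert ef.normalize(k) is k


class TestSparseConvolve:
    @pytest.mark.parametrize("L", [2, 4, 8, 16, 32])
    @pytest.mark.parametrize("n", [64, 137, 512])
    def test_matches_dense_oracle(self, L, n):
        rng = np.random.default_rng(L * 1000 + n)
        line = rng.uniform(0, 255, n)
        got = ef.sparse_convolve(line, L)
        want = dense_oracle(line, L)
        assert np.abs(got - want).max() <= 1e-6 * 255

    @pytest.mark.parametrize("z0", [1, 7, 40])
    def test_start_index_equivalence(self, z0):
        rng = np.random.default_rng(z0)
        line = rng.uniform(0, 255, 100)
        np.testing.assert_allclose(
            ef.sparse_convolve(line, 8, z0=z0),
            ef.sparse_convolve(line, 8, z0=0),
            atol=1e-8,
        )

    def test_integer_lines_exact(self):
        rng = np.random.default_rng(0)
        line = rng.integers(0, 256, 300).astype(np.uint8)
        got = ef.sparse_convolve(line, 16)
        want = dense_oracle(line, 16)
        assert np.abs(got - want).max() <= 1e-9 * 255

    def test_short_line_rejected(self):
        with pytest.raises(ValueError):
            ef.sparse_convolve(np.zeros(8), 8)

    @pytest.mark.parametrize("L", [2, 4, 8, 16, 32, 64])
    def test_unit_step_peak_is_half(self, L):
        step = np.zeros(200)
        step[100:] = 1.0
        resp = ef.sparse_convolve(step, L)
        assert resp.max() == pytest.approx(0.5, abs=1e-9)

    @given(
        st.integers(min_value=1, max_value=15).map(lambda h: 2 * h),
        st.floats(min_value=-5, max_value=5),
        st.floats(min_value=-5, max_value=5),
        st.integers(min_value=0, max_value=2**31 - 1),
    )
    def test_linearity(self, L, a, b, seed):
        rng = np.random.default_rng(seed)
        s1 = rng.uniform(0, 255, 80)
        s2 = rng.uniform(0, 255, 80)
        lhs = ef.sparse_convolve(a * s1 + b * s2, L)
        rhs = a * ef.sparse_convolve(s1, L) + b * ef.sparse_convolve(s2, L)
        np.testing.assert_allclose(lhs, rhs, atol=1e-7 * 255 * (abs(a) + abs(b) + 1))

    @given(st.integers(min_value=1, max_value=20).map(lambda h: 2 * h))
    def test_constant_line_zero_response(self, L):
        # zero-sum kernels null constant input except where zero padding
        # at the line ends intrudes into the kernel support
        resp = ef.sparse_convolve(np.full(100, 37.0), L)
        assert np.abs(resp[L:-L]).max() <= 1e-9 * 255


class TestLineEdgeResponse:
    def test_clean_step_located(self):
        line = np.zeros(128)
        line[60:] = 200.0
        pos, peak = ef.line_edge_response(line, 8, region=(10, 120))
        assert pos is not None and peak > 0
        assert pos == pytest.approx(60, abs=1.0)

    def test_bright_band_located(self):
        z = np.arange(128)
        line = 200.0 * np.exp(-0.5 * ((z - 47.3) / 1.0) ** 2)
        pos, _ = ef.line_edge_response(line, 8)
        # the response peak sits a little above a band-type boundary (the
        # response is antisymmetric about the band center)
        assert pos == pytest.approx(47.3, abs=1.5)

    def test_monotone_ramp_rejected(self):
        pos, _ = ef.line_edge_response(np.linspace(0, 255, 128), 8)
        assert pos is None

    def test_constant_line_rejected(self):
        pos, _ = ef.line_edge_response(np.full(128, 9.0), 8)
        assert pos is None

    def test_boundary_peak_rejected(self):
        # a line starting bright looks like a step at z=0 under zero
        # padding; that artifact must not count as an edge
        line = np.full(128, 100.0)
        line[64:] = 0.0  # genuine step-down -> negative response there
        pos, _ = ef.line_edge_response(line, 8, region=(0, 30))
        assert pos is None

    def test_empty_region_rejected(self):
        with pytest.raises(ValueError):
            ef.line_edge_response(np.zeros(64), 4, region=(50, 20))
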