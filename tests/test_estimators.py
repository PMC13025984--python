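"""Codelength estimators: LZ76, BDM, codecs, quantization and entropy oracles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from algoreg import universe, workbench
from algoreg.estimators import (
    BDMEstimator,
    CodecEstimator,
    LZ76Estimator,
    QuantizationSpec,
    bernoulli_entropy,
    codec_codelength,
    gaussian_entropy_rate,
    get_estimator,
    lz76_codelength,
    lz76_complexity,
    quantize,
)


def lz76_reference(s):
    """Independent quadratic-time re-derivation of the exhaustive history.

    Grows each phrase symbol by symbol, testing reproducibility by scanning
    every earlier start position explicitly; the terminal phrase is counted
    even when reproducible.
    """
    s = tuple(s)
    n, i, c = len(s), 0, 0
    while i < n:
        k = 0
        while i + k < n:
            ext = s[i : i + k + 1]
            found = any(
                s[j : j + k + 1] == ext for j in range(i) if j + k + 1 <= n
            )
            if not found:
                break
            k += 1
        c += 1
        if i + k >= n:
            break
        i += k + 1
    return c


class TestQuantize:
    spec = QuantizationSpec(levels=4, lower=0.0, upper=1.0)

    def test_examples(self):
        assert quantize([0.5] * 5, self.spec) == (2,) * 5
        assert quantize([0.0, 0.26, 0.51, 0.76], self.spec) == (0, 1, 2, 3)
        assert quantize([-5.0, 7.0], self.spec) == (0, 3)  # clipping

    def test_nonfinite_identifies_index(self):
        with pytest.raises(ValueError, match="index 2"):
            quantize([0.1, 0.2, float("nan")], self.spec)

    def test_invalid_spec(self):
        with pytest.raises(ValueError):
            QuantizationSpec(levels=1, lower=0, upper=1)
        with pytest.raises(ValueError):
            QuantizationSpec(levels=4, lower=1, upper=1)


class TestLZ76:
    @pytest.mark.parametrize(
        "s,expected",
        [
            ("0000000000", 2),
            ("01", 2),
            ("0101010101010101", 3),
            ("0", 1),
            ("0001101001000101", 6),  # classic hand-traced example
        ],
    )
    def test_hand_trace_oracle(self, s, expected):
        assert lz76_complexity(s) == expected

    def test_zeros_and_alternations_families(self):
        assert all(lz76_complexity("0" * n) == 2 for n in range(2, 65))
        assert all(lz76_complexity("01" * n) == 3 for n in range(2, 33))

    @settings(max_examples=200, derandomize=True)
    @given(st.lists(st.integers(0, 2), min_size=1, max_size=60))
    def test_matches_independent_reference(self, seq):
        assert lz76_complexity(seq) == lz76_reference(seq)

    @settings(max_examples=150, derandomize=True)
    @given(
        st.lists(st.integers(0, 1), min_size=1, max_size=40),
        st.lists(st.integers(0, 1), min_size=0, max_size=40),
    )
    def test_nondecreasing_under_extension(self, s, t):
        assert lz76_complexity(s) <= lz76_complexity(s + t)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            lz76_complexity(())

    def test_relabeling_invariance(self):
        rng = np.random.default_rng(5)
        s = tuple(int(v) for v in rng.integers(0, 3, 500))
        relabeled = tuple({0: 2, 1: 0, 2: 1}[v] for v in s)
        assert lz76_complexity(s) == lz76_complexity(relabeled)
        assert lz76_codelength(s).bits == lz76_codelength(relabeled).bits


class TestLZ76Codelength:
    def test_all_zero_rate_tiny(self):
        est = lz76_codelength("0" * 10_000)
        assert est.bits / 10_000 <= 0.02

    def test_bernoulli_entropy_rate_convergence(self):
        for p, seed in [(0.5, 1), (0.1, 2)]:
            s = workbench.make_string("bernoulli", {"p": p, "n": 100_000}, seed)
            rate = lz76_codelength(s, alphabet_size=2).bits / 100_000
            assert abs(rate - bernoulli_entropy(p)) < 0.15

    def test_strictly_positive(self):
        assert lz76_codelength("0").bits > 0
        assert lz76_codelength((1,)).bits > 0

    def test_determinism(self):
        s = workbench.make_string("bernoulli", {"p": 0.4, "n": 2000}, 9)
        assert lz76_codelength(s).bits == lz76_codelength(s).bits


class TestEntropyOracles:
    def test_bernoulli(self):
        assert bernoulli_entropy(0.5) == 1.0
        assert bernoulli_entropy(0.0) == 0.0
        assert bernoulli_entropy(1.0) == 0.0
        assert abs(bernoulli_entropy(0.1) - 0.4690) < 1e-4
        with pytest.raises(ValueError):
            bernoulli_entropy(1.5)

    def test_gaussian(self):
        assert abs(gaussian_entropy_rate(1.0) - 2.0471) < 1e-3
        # doubling sigma adds exactly one bit
        assert abs(gaussian_entropy_rate(2.0) - gaussian_entropy_rate(1.0) - 1.0) < 1e-12
        sigmas = [0.1, 0.5, 1.0, 3.0]
        values = [gaussian_entropy_rate(s) for s in sigmas]
        assert values == sorted(values)
        with pytest.raises(ValueError):
            gaussian_entropy_rate(0.0)


@pytest.fixture(scope="module")
def ctm4(default_table):
    return universe.ctm_table(default_table, 4)


class TestBDM:
    def test_single_block_repeated(self, ctm4):
        est = BDMEstimator(ctm4, block_size=4)
        block = "0110"
        k = ctm4[block]
        # one distinct block with multiplicity m: K_CTM + log2 m (+ flag bit)
        assert est.codelength(block * 8).bits == pytest.approx(k + 3 + 1)
        assert est.codelength(block).bits == pytest.approx(k + 0 + 1)

    def test_exact_at_native_sizes(self, default_table):
        """BDM with block_size = |s| reproduces the universe K for all strings."""
        for size in (1, 2, 3, 4):
            table = universe.ctm_table(default_table, size)
            est = BDMEstimator(table, block_size=size)
            for i in range(2**size):
                s = format(i, f"0{size}b")
                assert est.codelength(s).bits == pytest.approx(default_table.k_of(s) + 1)

    def test_trailing_partial_block_literal(self, ctm4):
        # the tail is coded at log2(A) = 1 bit per symbol behind the flag
        est = BDMEstimator(ctm4, block_size=4)
        full = est.codelength("01100110").bits
        assert est.codelength("011001101").bits == pytest.approx(full + 1.0)
        assert est.codelength("01100110101").bits == pytest.approx(full + 3.0)

    def test_absent_block_named(self):
        est = BDMEstimator({"00": 5.0}, block_size=2)
        with pytest.raises(KeyError, match="01"):
            est.codelength("0001")


class TestCodecs:
    def test_determinism(self):
        s = workbench.make_string("bernoulli", {"p": 0.5, "n": 3000}, 3)
        a = codec_codelength(s, "zlib")
        b = codec_codelength(s, "zlib")
        assert a.bits == b.bits

    def test_zeros_compress_hard(self):
        est = CodecEstimator("zlib")
        assert est.codelength((0,) * 10_000).bits < 0.1 * 8 * 10_000

    def test_random_bytes_incompressible(self):
        rng = np.random.default_rng(0)
        s = tuple(int(v) for v in rng.integers(0, 256, 10_000))
        assert CodecEstimator("zlib").codelength(s).bits >= 0.9 * 8 * 10_000

    def test_unknown_codec_lists_registered(self):
        with pytest.raises(KeyError, match="zlib"):
            CodecEstimator("nosuchcodec")

    def test_factory(self):
        assert get_estimator("lz76").estimator_id == "lz76"
        assert get_estimator("codec:lzma").estimator_id == "codec:lzma"
        with pytest.raises(KeyError):
            get_estimator("fancy-neural")
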