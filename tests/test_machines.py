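"""Transducer codes and coupled-episode semantics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from algoreg._bitcodes import InvalidCodeError, elias_gamma, elias_gamma_len
from algoreg.machines import (
    ConfigError,
    TransducerSpec,
    Transcript,
    decode_program,
    encode_program,
    encoded_length,
    null_regulator,
    off_readout,
    run_episode,
    sample_program,
    try_decode,
)


def specs(max_states=3, max_in=3, max_out=3):
    """Hypothesis strategy over valid transducer specs."""

    @st.composite
    def build(draw):
        s = draw(st.integers(1, max_states))
        a_in = draw(st.integers(1, max_in))
        a_out = draw(st.integers(1, max_out))
        n = s * a_in
        return TransducerSpec(
            n_states=s,
            n_inputs=a_in,
            n_outputs=a_out,
            transition=tuple(draw(st.lists(st.integers(0, s - 1), min_size=n, max_size=n))),
            emission=tuple(draw(st.lists(st.integers(0, a_out - 1), min_size=n, max_size=n))),
            initial_state=draw(st.integers(0, s - 1)),
            initial_emission=draw(st.integers(0, a_out - 1)),
        )

    return build()


class TestCanonicalCode:
    @settings(max_examples=150, derandomize=True)
    @given(specs())
    def test_roundtrip_identity(self, spec):
        bits = encode_program(spec)
        decoded, consumed = decode_program(bits + "10110")
        assert decoded == spec
        assert consumed == len(bits)
        # re-encoding reproduces the bits exactly
        assert encode_program(decoded) == bits

    def test_identical_specs_identical_codes(self):
        a = null_regulator(2)
        b = null_regulator(2)
        assert encode_program(a) == encode_program(b)

    def test_hand_counted_layout_length(self):
        # 2-state binary machine: gamma(2)+gamma(2)+gamma(2) = 9 header bits,
        # initial state (1) + initial emission (1), 4 table entries of
        # (1 state bit + 1 emission bit) = 8; total 19.
        spec = TransducerSpec(2, 2, 2, (0, 1, 1, 0), (0, 1, 1, 0), 0, 0)
        assert len(encode_program(spec)) == 9 + 1 + 1 + 8 == 19
        assert encoded_length(2, 2, 2) == 19

    def test_decode_empty_is_invalid(self):
        assert try_decode("") is None
        with pytest.raises(InvalidCodeError):
            decode_program("")

    def test_one_bit_flips_never_crash(self):
        bits = encode_program(null_regulator(2))
        for i in range(len(bits)):
            flipped = bits[:i] + ("1" if bits[i] == "0" else "0") + bits[i + 1 :]
            out = try_decode(flipped)
            # invalid or a (different) valid spec; never an out-of-bounds read
            if out is not None:
                spec, consumed = out
                assert consumed <= len(flipped)
                assert isinstance(spec, TransducerSpec)

    def test_oversized_spec_rejected(self):
        with pytest.raises(ConfigError, match="4096"):
            encode_program(
                TransducerSpec(1, 1, 5000, (0,), (0,), 0, 0)
            )


class TestEpisodes:
    def test_constant_world_ignores_regulator(self):
        const0 = TransducerSpec(1, 2, 2, (0, 0), (0, 0), 0, 0)
        for reg in (null_regulator(2), TransducerSpec(1, 2, 2, (0, 0), (1, 1), 0, 1)):
            t = run_episode(const0, reg, 12)
            assert t.w_out == (0,) * 12

    def test_echo_world_with_null_regulator(self):
        # world that echoes its previous input: emission(s, i) = i
        echo = TransducerSpec(1, 2, 2, (0, 0), (0, 1), 0, 1)
        t = run_episode(echo, null_regulator(2), 6)
        assert t.w_out == (1, 0, 0, 0, 0, 0)  # initial emission then zeros

    def test_alphabet_mismatch_names_both(self):
        w = TransducerSpec(1, 3, 2, (0, 0, 0), (0, 0, 0), 0, 0)
        with pytest.raises(ConfigError, match="consumes 3.*emits 2"):
            run_episode(w, null_regulator(2), 4)

    def test_episode_determinism(self):
        w = TransducerSpec(2, 2, 2, (1, 0, 0, 1), (1, 0, 0, 1), 0, 1)
        r = TransducerSpec(2, 2, 2, (0, 1, 1, 0), (0, 1, 1, 0), 1, 0)
        a = run_episode(w, r, 40)
        b = run_episode(w, r, 40)
        assert a == b

    @settings(max_examples=40, derandomize=True)
    @given(st.data(), st.integers(2, 20))
    def test_causality_prefix_property(self, data, horizon):
        """Emissions up to step t are unchanged by what happens after t."""
        w = data.draw(specs(max_in=2, max_out=2))
        # the regulator's interface must mirror the world's
        s = data.draw(st.integers(1, 3))
        n = s * w.n_outputs
        r = TransducerSpec(
            n_states=s,
            n_inputs=w.n_outputs,
            n_outputs=w.n_inputs,
            transition=tuple(data.draw(st.lists(st.integers(0, s - 1), min_size=n, max_size=n))),
            emission=tuple(
                data.draw(st.lists(st.integers(0, w.n_inputs - 1), min_size=n, max_size=n))
            ),
            initial_state=data.draw(st.integers(0, s - 1)),
            initial_emission=data.draw(st.integers(0, w.n_inputs - 1)),
        )
        full = run_episode(w, r, horizon)
        for t in range(1, horizon):
            trunc = run_episode(w, r, t)
            assert trunc.w_out == full.w_out[:t]
            assert trunc.r_out == full.r_out[:t]

    def test_off_readout_matches_null_episode(self):
        w = TransducerSpec(2, 2, 2, (1, 0, 0, 1), (0, 1, 1, 0), 0, 1)
        assert off_readout(w, 10) == run_episode(w, null_regulator(2), 10).w_out


class TestNullRegulator:
    def test_emits_zero_forever(self):
        t = run_episode(TransducerSpec(1, 2, 2, (0, 0), (1, 1), 0, 1),
                        null_regulator(2), 9)
        assert t.r_out == (0,) * 9

    def test_minimal_among_one_state_specs(self):
        """Every 1-state spec with the same alphabets has the same code length."""
        from algoreg.machines import iter_specs

        null_len = len(encode_program(null_regulator(2)))
        lengths = {len(encode_program(s)) for s in iter_specs(1, 2, 2)}
        assert lengths == {null_len}


class TestSampling:
    def test_prefix_prior_frequencies(self):
        rng = np.random.default_rng(0)
        n = 100_000
        counts = {}
        for _ in range(n):
            s = sample_program(10, rng)
            counts[encode_program(s)] = counts.get(encode_program(s), 0) + 1
        by_len = {}
        for code, c in counts.items():
            by_len.setdefault(len(code), []).append(c)
        # equal-length specs: equal frequency within 3 standard errors
        for length, cs in by_len.items():
            if len(cs) >= 2:
                p = np.mean(cs) / n
                se = np.sqrt(p * (1 - p) / n)
                assert max(cs) / n - min(cs) / n < 6 * se + 1e-12
        # a 7-bit and a 10-bit code: frequency ratio ~ 8
        if 7 in by_len and 10 in by_len:
            ratio = np.mean(by_len[7]) / np.mean(by_len[10])
            assert 5.5 < ratio < 11.5

    def test_seeded_reproducibility(self):
        a = [encode_program(sample_program(12, np.random.default_rng(42))) for _ in range(5)]
        b = [encode_program(sample_program(12, np.random.default_rng(42))) for _ in range(5)]
        assert a == b

    def test_bound_too_small(self):
        with pytest.raises(ConfigError):
            sample_program(2, np.random.default_rng(0))


def test_transcript_csv_roundtrip(tmp_path):
    t = run_episode(TransducerSpec(1, 2, 2, (0, 0), (0, 1), 0, 1),
                    null_regulator(2), 8)
    path = tmp_path / "t.csv"
    t.to_csv(path, metadata={"seed": 3})
    back = Transcript.from_csv(path)
    assert back.w_out == t.w_out and back.r_out == t.r_out


def test_gamma_code_is_prefix_free():
    codes = [elias_gamma(n) for n in range(1, 40)]
    assert all(len(elias_gamma(n)) == elias_gamma_len(n) for n in range(1, 40))
    for i, a in enumerate(codes):
        for j, b in enumerate(codes):
            if i != j:
                assert not b.startswith(a) or len(b) == len(a)
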