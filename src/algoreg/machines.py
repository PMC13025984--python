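"""Deterministic causal finite transducers: worlds and regulators.

A world W and a regulator R are finite-state transducers coupled over their
interface alphabets.  Each machine carries a canonical self-delimiting binary
code (Elias-gamma headers for the sizes, fixed-width table entries), whose
length serves as the computable upper-bound stand-in for the machine's
program length |p|.  The coupled episode uses staggered synchronous
semantics: at t=1 both machines emit their initial emission; at every later
step each machine emits and transitions from the symbol the *other* machine
emitted at the previous step.  Output at step t therefore depends only on
inputs received at steps < t (causality), and the episode is unique and
deterministic for every machine pair.
"""

from __future__ import annotations

import csv
import hashlib
import json
from dataclasses import dataclass, field
from typing import Iterator, Optional, Sequence

import numpy as np

from ._bitcodes import (
    BitReader,
    InvalidCodeError,
    elias_gamma,
    elias_gamma_len,
    fixed_width,
    fixed_width_len,
)

#: Hard bound on state and alphabet counts accepted by the canonical code.
MAX_SIZE = 4096

#: Version tag recorded in serialized artifacts.
CODEBOOK_VERSION = "transducer-gamma-v1"


class ConfigError(ValueError):
    """Invalid machine configuration (e.g. mismatched interface alphabets)."""


@dataclass(frozen=True)
class TransducerSpec:
    """A deterministic causal finite transducer.

    ``transition`` and ``emission`` are flattened total maps indexed by
    ``state * n_inputs + input_symbol``.  ``initial_emission`` is the symbol
    emitted at t=1 before any input has been seen; it resolves the episode
    bootstrap.  Alphabets are 0-indexed integers and symbol 0 is the
    designated null/zero symbol.
    """

    n_states: int
    n_inputs: int
    n_outputs: int
    transition: tuple
    emission: tuple
    initial_state: int = 0
    initial_emission: int = 0

    def __post_init__(self):
        if self.n_states < 1 or self.n_inputs < 1 or self.n_outputs < 1:
            raise ConfigError("state and alphabet counts must be positive")
        n_entries = self.n_states * self.n_inputs
        if len(self.transition) != n_entries or len(self.emission) != n_entries:
            raise ConfigError(
                f"transition/emission must be total over {self.n_states} states x "
                f"{self.n_inputs} inputs ({n_entries} entries)"
            )
        if not all(0 <= s < self.n_states for s in self.transition):
            raise ConfigError("transition target out of state range")
        if not all(0 <= o < self.n_outputs for o in self.emission):
            raise ConfigError("emission symbol out of output alphabet")
        if not 0 <= self.initial_state < self.n_states:
            raise ConfigError("initial_state out of range")
        if not 0 <= self.initial_emission < self.n_outputs:
            raise ConfigError("initial_emission out of range")

    def step(self, state: int, symbol: int) -> tuple:
        """(next_state, emitted_symbol) after consuming ``symbol`` in ``state``."""
        k = state * self.n_inputs + symbol
        return self.transition[k], self.emission[k]

    def digest(self) -> str:
        """Short stable hash of the canonical encoding."""
        return hashlib.sha256(encode_program(self).encode()).hexdigest()[:12]

    # -- JSON round trip -----------------------------------------------------
    def to_json_dict(self) -> dict:
        return {
            "codebook": CODEBOOK_VERSION,
            "n_states": self.n_states,
            "n_inputs": self.n_inputs,
            "n_outputs": self.n_outputs,
            "transition": list(self.transition),
            "emission": list(self.emission),
            "initial_state": self.initial_state,
            "initial_emission": self.initial_emission,
        }

    @classmethod
    def from_json_dict(cls, d: dict) -> "TransducerSpec":
        return cls(
            n_states=d["n_states"],
            n_inputs=d["n_inputs"],
            n_outputs=d["n_outputs"],
            transition=tuple(d["transition"]),
            emission=tuple(d["emission"]),
            initial_state=d["initial_state"],
            initial_emission=d["initial_emission"],
        )

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_json_dict(), fh, indent=1)

    @classmethod
    def load(cls, path) -> "TransducerSpec":
        with open(path) as fh:
            return cls.from_json_dict(json.load(fh))


@dataclass(frozen=True)
class Transcript:
    """Paired interface streams of one coupled episode.

    ``readout`` is a declared projection of ``w_out`` (identity by default);
    it is the string x fed to codelength estimators.
    """

    horizon: int
    w_out: tuple
    r_out: tuple
    readout: tuple = field(default=None)

    def __post_init__(self):
        if len(self.w_out) != self.horizon or len(self.r_out) != self.horizon:
            raise ConfigError("stream lengths must equal the horizon")
        if self.readout is None:
            object.__setattr__(self, "readout", tuple(self.w_out))

    def to_csv(self, path, metadata: Optional[dict] = None) -> None:
        with open(path, "w", newline="") as fh:
            meta = {"horizon": self.horizon}
            if metadata:
                meta.update(metadata)
            fh.write("# " + json.dumps(meta, sort_keys=True) + "\n")
            writer = csv.writer(fh, lineterminator="\n")
            writer.writerow(["t", "w_out", "r_out"])
            for t, (w, r) in enumerate(zip(self.w_out, self.r_out), start=1):
                writer.writerow([t, w, r])

    @classmethod
    def from_csv(cls, path) -> "Transcript":
        w_out, r_out = [], []
        with open(path) as fh:
            for row in csv.reader(line for line in fh if not line.startswith("#")):
                if not row or row[0] == "t":
                    continue
                w_out.append(int(row[1]))
                r_out.append(int(row[2]))
        return cls(horizon=len(w_out), w_out=tuple(w_out), r_out=tuple(r_out))


# ---------------------------------------------------------------------------
# Canonical self-delimiting code
# ---------------------------------------------------------------------------

def encode_program(spec: TransducerSpec) -> str:
    """Canonical self-delimiting bitstring for a transducer.

    Layout: gamma(n_states) gamma(n_inputs) gamma(n_outputs),
    then fixed-width initial_state and initial_emission, then for each
    (state, input) pair in row-major order a fixed-width next-state field and
    a fixed-width emission field.  The codebook is prefix-free because the
    gamma header determines every following field width.
    """
    if spec.n_states > MAX_SIZE or max(spec.n_inputs, spec.n_outputs) > MAX_SIZE:
        raise ConfigError(f"encoding bound exceeded (limit {MAX_SIZE})")
    parts = [
        elias_gamma(spec.n_states),
        elias_gamma(spec.n_inputs),
        elias_gamma(spec.n_outputs),
        fixed_width(spec.initial_state, spec.n_states),
        fixed_width(spec.initial_emission, spec.n_outputs),
    ]
    for k in range(spec.n_states * spec.n_inputs):
        parts.append(fixed_width(spec.transition[k], spec.n_states))
        parts.append(fixed_width(spec.emission[k], spec.n_outputs))
    return "".join(parts)


def encoded_length(n_states: int, n_inputs: int, n_outputs: int) -> int:
    """Code length in bits of any spec with the given shape (layout hand-count)."""
    b_s = fixed_width_len(n_states)
    b_o = fixed_width_len(n_outputs)
    return (
        elias_gamma_len(n_states)
        + elias_gamma_len(n_inputs)
        + elias_gamma_len(n_outputs)
        + b_s
        + b_o
        + n_states * n_inputs * (b_s + b_o)
    )


def decode_program(bits: str) -> tuple:
    """Decode the code word at the head of ``bits``.

    Returns ``(spec, consumed_length)``.  Reads exactly the code word and no
    further (self-delimiting contract).  Raises :class:`InvalidCodeError` for
    truncated or malformed prefixes.
    """
    reader = BitReader(bits)
    n_states = reader.read_gamma()
    n_inputs = reader.read_gamma()
    n_outputs = reader.read_gamma()
    if n_states > MAX_SIZE or max(n_inputs, n_outputs) > MAX_SIZE:
        raise InvalidCodeError(f"decoded size exceeds bound {MAX_SIZE}")
    initial_state = reader.read_fixed(n_states)
    initial_emission = reader.read_fixed(n_outputs)
    transition, emission = [], []
    for _ in range(n_states * n_inputs):
        transition.append(reader.read_fixed(n_states))
        emission.append(reader.read_fixed(n_outputs))
    spec = TransducerSpec(
        n_states=n_states,
        n_inputs=n_inputs,
        n_outputs=n_outputs,
        transition=tuple(transition),
        emission=tuple(emission),
        initial_state=initial_state,
        initial_emission=initial_emission,
    )
    return spec, reader.pos


def try_decode(bits: str) -> Optional[tuple]:
    """Like :func:`decode_program` but returns None on invalid input.

    This is the non-raising signal used by the universe enumerator, where an
    invalid prefix is simply a non-program, not an error state.
    """
    try:
        return decode_program(bits)
    except InvalidCodeError:
        return None


# ---------------------------------------------------------------------------
# Episode semantics
# ---------------------------------------------------------------------------

def run_episode(world: TransducerSpec, regulator: TransducerSpec, horizon: int) -> Transcript:
    """Simulate the coupled world-regulator episode for ``horizon`` steps.

    Staggered synchronous semantics: both machines emit their initial
    emission at t=1; at step t > 1 each machine consumes the other's emission
    from step t-1, emits, and transitions.
    """
    if horizon < 1:
        raise ConfigError("horizon must be >= 1")
    if world.n_inputs != regulator.n_outputs or world.n_outputs != regulator.n_inputs:
        raise ConfigError(
            "interface alphabet mismatch: world consumes "
            f"{world.n_inputs}/emits {world.n_outputs}, regulator consumes "
            f"{regulator.n_inputs}/emits {regulator.n_outputs}"
        )
    w_out = [world.initial_emission]
    r_out = [regulator.initial_emission]
    sw, sr = world.initial_state, regulator.initial_state
    for _ in range(1, horizon):
        w_in, r_in = r_out[-1], w_out[-1]
        sw, w_sym = world.step(sw, w_in)
        sr, r_sym = regulator.step(sr, r_in)
        w_out.append(w_sym)
        r_out.append(r_sym)
    return Transcript(horizon=horizon, w_out=tuple(w_out), r_out=tuple(r_out))


def null_regulator(output_alphabet_size: int, input_alphabet_size: int = 2) -> TransducerSpec:
    """The OFF baseline: a 1-state machine emitting symbol 0 forever."""
    if output_alphabet_size < 1:
        raise ConfigError("alphabet size must be >= 1")
    return TransducerSpec(
        n_states=1,
        n_inputs=input_alphabet_size,
        n_outputs=output_alphabet_size,
        transition=(0,) * input_alphabet_size,
        emission=(0,) * input_alphabet_size,
    )


def off_readout(world: TransducerSpec, horizon: int) -> tuple:
    """The unregulated readout y = O_{W,null}(N)."""
    null = null_regulator(world.n_inputs, world.n_outputs)
    return run_episode(world, null, horizon).w_out


# ---------------------------------------------------------------------------
# Prefix-prior sampling
# ---------------------------------------------------------------------------

def sample_program(
    max_code_length: int,
    rng: np.random.Generator | int,
    max_attempts: int = 1_000_000,
) -> TransducerSpec:
    """Sample a spec with probability proportional to 2^(-|encode(spec)|).

    Draws fair bits and attempts to decode a code word within the first
    ``max_code_length`` bits; a success is accepted.  Conditioned on
    acceptance this is exactly the prefix prior restricted to codes of length
    at most the bound.
    """
    if max_code_length < encoded_length(1, 1, 1):
        raise ConfigError(
            f"max_code_length {max_code_length} smaller than the shortest valid "
            f"code ({encoded_length(1, 1, 1)} bits)"
        )
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    for _ in range(max_attempts):
        bits = "".join("1" if b else "0" for b in rng.integers(0, 2, max_code_length))
        decoded = try_decode(bits)
        if decoded is not None:
            return decoded[0]
    raise RuntimeError("sampling failed: no valid code found within attempt budget")


def iter_specs(n_states: int, n_inputs: int, n_outputs: int) -> Iterator[TransducerSpec]:
    """Exhaustively enumerate every spec with the given shape."""
    import itertools

    n_entries = n_states * n_inputs
    entry_choices = list(itertools.product(range(n_states), range(n_outputs)))
    for initial_state in range(n_states):
        for initial_emission in range(n_outputs):
            for table in itertools.product(entry_choices, repeat=n_entries):
                trans = tuple(t for t, _ in table)
                emis = tuple(e for _, e in table)
                yield TransducerSpec(
                    n_states=n_states,
                    n_inputs=n_inputs,
                    n_outputs=n_outputs,
                    transition=trans,
                    emission=emis,
                    initial_state=initial_state,
                    initial_emission=initial_emission,
                )
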