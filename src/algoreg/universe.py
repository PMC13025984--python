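"""Exact enumeration of a micro program universe.

The interpreter runs self-delimiting binary programs of two kinds, selected
by a leading mode bit:

* mode ``1`` -- literal: an Elias-gamma output length n followed by n raw
  bits, which are printed verbatim (every string therefore has at least one
  program, as on any real universal machine);
* mode ``0`` -- generator: an Elias-gamma output length n followed by the
  canonical transducer code of the machines module; the transducer free-runs
  for n steps against the null input and prints its emission stream.

The halting domain is prefix-free (gamma codes and header-determined field
widths), so the Kraft sum over halting programs is at most 1 and the
universal semimeasure m(x) = sum of 2^-|p| over programs printing x is well
defined.  Resource exhaustion (output length beyond the step cap or the
configured output bound) is the documented non-halting bucket.  All masses
are accumulated as exact integers at scale 2^L, so Kraft sums, m(x) and the
posterior identities downstream are exact rationals.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Dict, Optional

from ._bitcodes import BitReader, InvalidCodeError, elias_gamma, elias_gamma_len
from .machines import (
    CODEBOOK_VERSION,
    TransducerSpec,
    decode_program,
    encode_program,
    encoded_length,
)

UNIVERSE_CODEBOOK_VERSION = CODEBOOK_VERSION + "+mode-output-len-v1"


@dataclass(frozen=True)
class MicroInterpreter:
    """Resource-bounded prefix interpreter over the extended codebook."""

    output_alphabet_size: int = 2
    step_cap: int = 256

    def __post_init__(self):
        if self.output_alphabet_size != 2:
            raise ValueError("the micro interpreter prints binary strings")
        if self.step_cap < 1:
            raise ValueError("step_cap must be >= 1")

    def run(self, bits: str, max_output_len: Optional[int] = None) -> tuple:
        """Execute the program at the head of ``bits``.

        Returns ``(status, output, consumed)`` with status one of
        ``'halt'`` (output is the printed string), ``'capped'`` (valid code
        whose output length exceeds the step cap or output bound -- the
        non-halting bucket) or ``'invalid'`` (no valid code word at the head).
        """
        try:
            reader = BitReader(bits)
            mode = reader.take(1)
            n = reader.read_gamma()
            capped = n > self.step_cap or (
                max_output_len is not None and n > max_output_len
            )
            if mode == "1":
                reader.take(n)
                consumed = reader.pos
                if capped:
                    return ("capped", None, consumed)
                output = bits[consumed - n : consumed]
            else:
                spec, spec_len = decode_program(bits[reader.pos :])
                consumed = reader.pos + spec_len
                if spec.n_outputs != self.output_alphabet_size:
                    return ("invalid", None, None)
                if capped:
                    return ("capped", None, consumed)
                output = "".join(str(v) for v in _free_run(spec, n))
        except InvalidCodeError:
            return ("invalid", None, None)
        return ("halt", output, consumed)


def _free_run(spec: TransducerSpec, n: int) -> list:
    """Emission stream of ``spec`` coupled to the null input (symbol 0)."""
    out = [spec.initial_emission]
    s = spec.initial_state
    for _ in range(n - 1):
        s, sym = spec.step(s, 0)
        out.append(sym)
    return out[:n]


@dataclass
class UniverseEntry:
    m: Fraction
    k: int
    n_programs: int
    witness: str  # one shortest program for this output


@dataclass
class UniverseTable:
    """Exact enumeration results: m(x), K(x) and program counts per output."""

    max_code_length: int
    step_cap: int
    max_output_len: int
    output_alphabet_size: int
    codebook_version: str
    entries: Dict[str, UniverseEntry]
    total_mass: Fraction
    n_halting: int
    n_capped: int

    # -- membership with literal completion ---------------------------------
    def _literal_len(self, x: str) -> Optional[int]:
        n = len(x)
        if n < 1 or n > self.max_output_len or n > self.step_cap:
            return None
        plen = 1 + elias_gamma_len(n) + n
        return plen if plen <= self.max_code_length else None

    def k_of(self, x: str) -> Optional[int]:
        x = _as_bits(x)
        if x in self.entries:
            return self.entries[x].k
        return self._literal_len(x)

    def m_of(self, x: str) -> Optional[Fraction]:
        x = _as_bits(x)
        if x in self.entries:
            return self.entries[x].m
        lit = self._literal_len(x)
        return Fraction(1, 2**lit) if lit is not None else None

    def log2_m(self, x: str) -> Optional[float]:
        m = self.m_of(x)
        if m is None:
            return None
        return math.log2(m.numerator) - math.log2(m.denominator)

    def gap_of(self, x: str) -> Optional[float]:
        """Coding-theorem gap g(x) = K(x) + log2 m(x) >= 0."""
        k = self.k_of(x)
        if k is None:
            return None
        return k + self.log2_m(x)

    # -- serialization: JSON metadata header + CSV entry lines ---------------
    def save(self, path) -> None:
        meta = {
            "max_code_length": self.max_code_length,
            "step_cap": self.step_cap,
            "max_output_len": self.max_output_len,
            "output_alphabet_size": self.output_alphabet_size,
            "codebook_version": self.codebook_version,
            "total_mass": [str(self.total_mass.numerator), str(self.total_mass.denominator)],
            "n_halting": self.n_halting,
            "n_capped": self.n_capped,
        }
        with open(path, "w") as fh:
            fh.write("# " + json.dumps(meta, sort_keys=True) + "\n")
            fh.write("output,m_numerator,m_denominator,k_bits,n_programs,witness\n")
            for out in sorted(self.entries):
                e = self.entries[out]
                fh.write(
                    f"{out},{e.m.numerator},{e.m.denominator},{e.k},{e.n_programs},{e.witness}\n"
                )

    @classmethod
    def load(cls, path) -> "UniverseTable":
        with open(path) as fh:
            header = fh.readline()
            meta = json.loads(header.lstrip("# "))
            fh.readline()  # column header
            entries = {}
            for line in fh:
                out, num, den, k, n_prog, witness = line.rstrip("\n").split(",")
                entries[out] = UniverseEntry(
                    m=Fraction(int(num), int(den)),
                    k=int(k),
                    n_programs=int(n_prog),
                    witness=witness,
                )
        return cls(
            max_code_length=meta["max_code_length"],
            step_cap=meta["step_cap"],
            max_output_len=meta["max_output_len"],
            output_alphabet_size=meta["output_alphabet_size"],
            codebook_version=meta["codebook_version"],
            entries=entries,
            total_mass=Fraction(int(meta["total_mass"][0]), int(meta["total_mass"][1])),
            n_halting=meta["n_halting"],
            n_capped=meta["n_capped"],
        )


def _as_bits(x) -> str:
    if isinstance(x, str):
        return x
    return "".join(str(int(v)) for v in x)


def _max_n_for_budget(budget: int) -> int:
    """Largest n >= 1 with elias_gamma_len(n) <= budget, or 0 if none."""
    if budget < 1:
        return 0
    return (1 << ((budget + 1) // 2)) - 1


def enumerate_universe(
    interpreter: MicroInterpreter, max_code_length: int, max_output_len: int
) -> UniverseTable:
    """Classify every program of length <= max_code_length and build the table.

    Generator programs are enumerated structurally by machine shape.  In a
    free run only the input-0 column of the tables is consulted, so specs are
    grouped by their behaviourally relevant fields (initial state/emission
    plus the input-0 column); each group contributes its exact program count
    and mass without simulating duplicates.  Literal-program mass is summed
    in closed form per output length; literal contributions to individual
    strings are attached to materialized entries here and supplied lazily for
    all other strings by the table lookup.
    """
    L = max_code_length
    step_cap = interpreter.step_cap
    a_out = interpreter.output_alphabet_size
    scale = 1 << L  # masses held as integers: m_int = m * 2^L

    entries: Dict[str, list] = {}  # out -> [m_int, k, n_programs, witness]
    total_int = 0
    n_halting = 0
    n_capped = 0

    def add(out: str, plen: int, count: int, witness_fn) -> None:
        nonlocal total_int, n_halting
        mass = count * (1 << (L - plen))
        total_int += mass
        n_halting += count
        e = entries.get(out)
        if e is None:
            entries[out] = [mass, plen, count, witness_fn()]
        else:
            e[0] += mass
            e[2] += count
            if plen < e[1]:
                e[1] = plen
                e[3] = witness_fn()

    # ---- generator programs (mode 0) --------------------------------------
    s_count = 1
    while True:
        if 1 + 1 + encoded_length(s_count, 1, a_out) > L:
            break
        a_in = 1
        while True:
            spec_len = encoded_length(s_count, a_in, a_out)
            budget = L - 1 - spec_len
            n_by_code = _max_n_for_budget(budget)
            if n_by_code < 1:
                break  # spec_len grows with a_in, so no larger a_in fits either
            n_hi = min(n_by_code, max_output_len, step_cap)
            # count of full specs sharing one behaviour (free table entries)
            free_mult = (s_count * a_out) ** (s_count * (a_in - 1))
            shape_specs = s_count * a_out * (s_count * a_out) ** (s_count * a_in)
            # valid codes with n beyond the resource caps: non-halting bucket
            n_capped += max(n_by_code - n_hi, 0) * shape_specs

            if n_hi >= 1:
                col_choices = list(itertools.product(range(s_count), range(a_out)))
                for init_state in range(s_count):
                    for init_em in range(a_out):
                        for col0 in itertools.product(col_choices, repeat=s_count):
                            nxt = [c[0] for c in col0]
                            emi = [c[1] for c in col0]
                            stream = [init_em]
                            s = init_state
                            for _ in range(n_hi - 1):
                                stream.append(emi[s])
                                s = nxt[s]
                            text = "".join(map(str, stream))

                            def witness_for(n, init_state=init_state, init_em=init_em,
                                            nxt=tuple(nxt), emi=tuple(emi)):
                                def build():
                                    trans, emis = [], []
                                    for st in range(s_count):
                                        trans.append(nxt[st])
                                        emis.append(emi[st])
                                        trans.extend([0] * (a_in - 1))
                                        emis.extend([0] * (a_in - 1))
                                    spec = TransducerSpec(
                                        n_states=s_count, n_inputs=a_in, n_outputs=a_out,
                                        transition=tuple(trans), emission=tuple(emis),
                                        initial_state=init_state, initial_emission=init_em,
                                    )
                                    return "0" + elias_gamma(n) + encode_program(spec)
                                return build

                            for n in range(1, n_hi + 1):
                                plen = 1 + elias_gamma_len(n) + spec_len
                                add(text[:n], plen, free_mult, witness_for(n))
            a_in += 1

        s_count += 1

    # ---- literal programs (mode 1) -----------------------------------------
    lit_n_max = 0
    n = 1
    while 1 + elias_gamma_len(n) + n <= L:
        lit_n_max = n
        n += 1
    for n in range(1, lit_n_max + 1):
        if n > max_output_len or n > step_cap:
            n_capped += 1 << n
            continue
        plen = 1 + elias_gamma_len(n) + n
        total_int += (1 << n) * (1 << (L - plen))
        n_halting += 1 << n
        # attach the literal contribution to already-materialized strings;
        # the rest is served analytically by the table lookup
        for out, e in entries.items():
            if len(out) == n:
                e[0] += 1 << (L - plen)
                e[2] += 1
                if plen < e[1]:
                    e[1] = plen
                    e[3] = "1" + elias_gamma(n) + out

    table_entries = {
        out: UniverseEntry(
            m=Fraction(m_int, scale), k=k, n_programs=cnt, witness=wit
        )
        for out, (m_int, k, cnt, wit) in entries.items()
    }
    return UniverseTable(
        max_code_length=L,
        step_cap=step_cap,
        max_output_len=max_output_len,
        output_alphabet_size=a_out,
        codebook_version=UNIVERSE_CODEBOOK_VERSION,
        entries=table_entries,
        total_mass=Fraction(total_int, scale),
        n_halting=n_halting,
        n_capped=n_capped,
    )


def brute_force_universe(
    interpreter: MicroInterpreter, max_code_length: int, max_output_len: int
) -> UniverseTable:
    """Independent oracle: classify every bitstring by actually running it.

    Exponential in the length bound -- usable only for small universes in
    tests, where it cross-checks the structural enumeration above.
    """
    L = max_code_length
    scale = 1 << L
    entries: Dict[str, list] = {}
    total_int = 0
    n_halting = 0
    n_capped = 0
    for length in range(1, L + 1):
        for value in range(1 << length):
            bits = format(value, f"0{length}b")
            status, output, consumed = interpreter.run(bits, max_output_len=max_output_len)
            if status == "invalid" or consumed != length:
                continue  # not a code word of exactly this length
            if status == "capped":
                n_capped += 1
                continue
            total_int += 1 << (L - length)
            n_halting += 1
            e = entries.get(output)
            if e is None:
                entries[output] = [1 << (L - length), length, 1, bits]
            else:
                e[0] += 1 << (L - length)
                e[2] += 1
                if length < e[1]:
                    e[1] = length
                    e[3] = bits
    table_entries = {
        out: UniverseEntry(m=Fraction(m_int, scale), k=k, n_programs=cnt, witness=wit)
        for out, (m_int, k, cnt, wit) in entries.items()
    }
    return UniverseTable(
        max_code_length=L,
        step_cap=interpreter.step_cap,
        max_output_len=max_output_len,
        output_alphabet_size=interpreter.output_alphabet_size,
        codebook_version=UNIVERSE_CODEBOOK_VERSION,
        entries=table_entries,
        total_mass=Fraction(total_int, scale),
        n_halting=n_halting,
        n_capped=n_capped,
    )


def k_exact(table: UniverseTable, x) -> Optional[int]:
    """Exact in-universe prefix complexity of ``x``; None if not produced."""
    return table.k_of(_as_bits(x))


@dataclass(frozen=True)
class CodingGapReport:
    """Per-string coding-theorem gaps g(x) = K(x) + log2 m(x) within the universe."""

    gaps: dict
    min_gap: float
    max_gap: float

    @property
    def c1(self) -> float:
        return 2.0**self.min_gap

    @property
    def c2(self) -> float:
        return 2.0**self.max_gap


def coding_gap_report(table: UniverseTable) -> CodingGapReport:
    if not table.entries:
        raise ValueError("empty universe table")
    gaps = {out: table.gap_of(out) for out in table.entries}
    values = list(gaps.values())
    return CodingGapReport(gaps=gaps, min_gap=min(values), max_gap=max(values))


def ctm_table(table: UniverseTable, block_size: int) -> Dict[str, int]:
    """Total CTM lookup K(block) for every binary block of ``block_size``."""
    out = {}
    for bits in itertools.product("01", repeat=block_size):
        block = "".join(bits)
        k = table.k_of(block)
        if k is None:
            raise KeyError(
                f"block {block} not covered by this universe "
                f"(raise max_code_length or lower block_size)"
            )
        out[block] = k
    return out


def default_universe(
    max_code_length: int = 22, step_cap: int = 256, max_output_len: int = 16
) -> UniverseTable:
    """The package's default desk-scale universe (L=22, step cap 256)."""
    return enumerate_universe(
        MicroInterpreter(step_cap=step_cap), max_code_length, max_output_len
    )
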