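"""Exact verification of the posterior-tilt results inside enumerated universes.

Inside a finite, fully enumerated pair universe every quantity of the
probabilistic regulator theorems is exact: the prefix prior over (W, R)
pairs is 2^-(joint code length), the posterior given a readout x is the
Bayes normalization over the pairs that actually produce x, and the
contrastive gap Delta and mutual-information surrogate M-hat are computed
from exact in-universe complexities.  The machine-dependent O(1) constants
of the theorems become measured numbers here: the smallest constant C* that
makes the posterior bound hold, and the universe's coding-gap extremes for
the Bayes-factor identity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction
from typing import Dict, List, Optional, Sequence

import numpy as np

from .machines import (
    TransducerSpec,
    encode_program,
    encoded_length,
    iter_specs,
    null_regulator,
    run_episode,
)
from .universe import (
    MicroInterpreter,
    UniverseTable,
    coding_gap_report,
    enumerate_universe,
)


@dataclass(frozen=True)
class PairRecord:
    """One enumerated (world, regulator) pair with its episode readouts."""

    pair_id: str
    world: TransducerSpec
    regulator: TransducerSpec
    code_w: str
    code_r: str
    on_readout: str
    off_readout: str

    @property
    def joint_code(self) -> str:
        return self.code_w + self.code_r

    @property
    def joint_bits(self) -> int:
        return len(self.code_w) + len(self.code_r)


@dataclass
class PairUniverse:
    """All (W, R) pairs with joint canonical code length <= max_joint_bits.

    The prior over pairs is proportional to 2^-(joint code length); the
    normalization constant is recorded exactly.
    """

    max_joint_bits: int
    horizon: int
    records: List[PairRecord]
    normalization: Fraction  # sum of 2^-joint over all pairs
    by_readout: Dict[str, List[int]]  # ON readout -> record indices

    def consistent(self, x: str) -> List[PairRecord]:
        return [self.records[i] for i in self.by_readout.get(x, [])]


def build_pair_universe(max_joint_bits: int = 24, horizon: int = 8) -> PairUniverse:
    """Enumerate every compatible (W, R) pair and run both episodes.

    Worlds emit binary readouts (output alphabet 2); regulators read that
    binary stream and emit symbols in the world's input alphabet.  For each
    pair the ON episode couples W to R and the OFF episode couples W to the
    null regulator; the readout is the world output stream.
    """
    if horizon < 1:
        raise ValueError("horizon must be >= 1")
    records: List[PairRecord] = []
    by_readout: Dict[str, List[int]] = {}
    norm_int = 0
    scale = 1 << max_joint_bits

    w_shapes = _shapes_for_worlds(max_joint_bits)
    for s_w, a_in_w, len_w in w_shapes:
        r_shapes = _shapes_for_regulators(a_in_w, max_joint_bits - len_w)
        if not r_shapes:
            continue
        for world in iter_specs(s_w, a_in_w, 2):
            code_w = encode_program(world)
            null = null_regulator(a_in_w, 2)
            off = run_episode(world, null, horizon).w_out
            off_str = "".join(map(str, off))
            for s_r, len_r in r_shapes:
                for reg in iter_specs(s_r, 2, a_in_w):
                    code_r = encode_program(reg)
                    on = run_episode(world, reg, horizon).w_out
                    on_str = "".join(map(str, on))
                    idx = len(records)
                    records.append(
                        PairRecord(
                            pair_id=f"p{idx:05d}",
                            world=world,
                            regulator=reg,
                            code_w=code_w,
                            code_r=code_r,
                            on_readout=on_str,
                            off_readout=off_str,
                        )
                    )
                    by_readout.setdefault(on_str, []).append(idx)
                    norm_int += 1 << (max_joint_bits - (len_w + len_r))
    return PairUniverse(
        max_joint_bits=max_joint_bits,
        horizon=horizon,
        records=records,
        normalization=Fraction(norm_int, scale),
        by_readout=by_readout,
    )


def _shapes_for_worlds(max_joint_bits: int) -> List[tuple]:
    """(n_states, input_alphabet, code length) for worlds that fit some pair."""
    shapes = []
    s = 1
    while encoded_length(s, 1, 2) + encoded_length(1, 2, 1) <= max_joint_bits:
        a_in = 1
        while True:
            len_w = encoded_length(s, a_in, 2)
            if len_w + encoded_length(1, 2, a_in) > max_joint_bits:
                break
            shapes.append((s, a_in, len_w))
            a_in += 1
        s += 1
    return shapes


def _shapes_for_regulators(world_a_in: int, budget: int) -> List[tuple]:
    """(n_states, code length) for regulators reading binary, emitting world inputs."""
    shapes = []
    s = 1
    while True:
        len_r = encoded_length(s, 2, world_a_in)
        if len_r > budget:
            break
        shapes.append((s, len_r))
        s += 1
    return shapes


def pair_count_closed_form(max_joint_bits: int) -> int:
    """Combinatorial oracle for the number of pairs (product over shapes)."""
    total = 0
    for s_w, a_in_w, len_w in _shapes_for_worlds(max_joint_bits):
        n_w = s_w * 2 * (s_w * 2) ** (s_w * a_in_w)
        for s_r, len_r in _shapes_for_regulators(a_in_w, max_joint_bits - len_w):
            n_r = s_r * a_in_w * (s_r * a_in_w) ** (s_r * 2)
            total += n_w * n_r
    return total


# ---------------------------------------------------------------------------
# Posterior records (Bayes over the pair universe)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PosteriorRecord:
    """One (W, R) explanation of an observed readout.

    ``posterior_mass`` is exact: 2^-joint_bits normalized over the pairs that
    produce the readout.  ``m_hat_bits`` is the in-universe mutual-information
    surrogate K(enc W) + K(enc R) - K(enc W || enc R) with K taken from the
    string universe; ``delta_bits`` is the pair's own contrast
    K(off readout) - K(on readout); ``bound_rhs`` is 2^(M-hat - Delta), the
    posterior bound at constant C = 1.
    """

    pair_id: str
    code_w_bits: int
    code_r_bits: int
    joint_bits: int
    posterior_mass: Fraction
    m_hat_bits: Optional[int] = None
    delta_bits: Optional[int] = None
    bound_rhs: Optional[float] = None


def posterior_given_x(
    pair_universe: PairUniverse,
    x: str,
    string_universe: Optional[UniverseTable] = None,
) -> List[PosteriorRecord]:
    """Exact posterior over pairs given the ON readout ``x``.

    The closed form 2^-|p| / m(x) and the Bayes normalization agree exactly
    because both are computed in rational arithmetic.  Returns the empty
    list when no pair produces ``x`` (the distinguished no-explanation
    result).  With a string universe supplied, each record is annotated
    with its M-hat, Delta and the C=1 bound.
    """
    consistent = pair_universe.consistent(x)
    if not consistent:
        return []
    scale = 1 << pair_universe.max_joint_bits
    weights = [Fraction(1 << (pair_universe.max_joint_bits - r.joint_bits), scale)
               for r in consistent]
    m_x = sum(weights)
    out = []
    for rec, w in zip(consistent, weights):
        m_hat = delta = None
        bound = None
        if string_universe is not None:
            m_hat = _m_hat(string_universe, rec)
            delta = _pair_delta(string_universe, rec)
            if m_hat is not None and delta is not None:
                bound = 2.0 ** (m_hat - delta)
        out.append(
            PosteriorRecord(
                pair_id=rec.pair_id,
                code_w_bits=len(rec.code_w),
                code_r_bits=len(rec.code_r),
                joint_bits=rec.joint_bits,
                posterior_mass=w / m_x,
                m_hat_bits=m_hat,
                delta_bits=delta,
                bound_rhs=bound,
            )
        )
    return out


def posterior_given_contrast(
    pair_universe: PairUniverse,
    x: str,
    b: int,
    string_universe: UniverseTable,
    mode: str = "equal",
) -> List[PosteriorRecord]:
    """Posterior restricted to the OFF-complexity stratum E_b.

    ``mode='equal'`` keeps pairs whose OFF readout has in-universe complexity
    exactly b (the default equality stratum); ``mode='at_least'`` keeps those
    with complexity >= b.  Masses are renormalized within the stratum.
    """
    if mode not in ("equal", "at_least"):
        raise ValueError("mode must be 'equal' or 'at_least'")
    records = posterior_given_x(pair_universe, x, string_universe)
    consistent = pair_universe.consistent(x)
    kept = []
    for rec, post in zip(consistent, records):
        k_off = string_universe.k_of(rec.off_readout)
        if k_off is None:
            continue
        if (mode == "equal" and k_off == b) or (mode == "at_least" and k_off >= b):
            kept.append(post)
    total = sum(p.posterior_mass for p in kept)
    if not kept or total == 0:
        return []
    return [
        PosteriorRecord(
            pair_id=p.pair_id,
            code_w_bits=p.code_w_bits,
            code_r_bits=p.code_r_bits,
            joint_bits=p.joint_bits,
            posterior_mass=p.posterior_mass / total,
            m_hat_bits=p.m_hat_bits,
            delta_bits=p.delta_bits,
            bound_rhs=p.bound_rhs,
        )
        for p in kept
    ]


def _m_hat(su: UniverseTable, rec: PairRecord) -> Optional[int]:
    kw = su.k_of(rec.code_w)
    kr = su.k_of(rec.code_r)
    kwr = su.k_of(rec.joint_code)
    if kw is None or kr is None or kwr is None:
        return None
    return kw + kr - kwr


def _pair_delta(su: UniverseTable, rec: PairRecord) -> Optional[int]:
    k_on = su.k_of(rec.on_readout)
    k_off = su.k_of(rec.off_readout)
    if k_on is None or k_off is None:
        return None
    return k_off - k_on


# ---------------------------------------------------------------------------
# Theorem 2: posterior <= C * 2^M-hat * 2^-Delta
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Theorem2Report:
    readout: str
    records: tuple
    c_star: float  # smallest constant making the bound hold for every pair

    def bound_holds(self, c: float) -> bool:
        return all(
            float(r.posterior_mass) <= c * r.bound_rhs * (1 + 1e-12)
            for r in self.records
        )


def verify_theorem2(
    pair_universe: PairUniverse, string_universe: UniverseTable, x_on: str
) -> Theorem2Report:
    """Measure the smallest C* with posterior <= C* 2^M-hat 2^-Delta for all pairs."""
    records = posterior_given_x(pair_universe, x_on, string_universe)
    if not records:
        raise ValueError(f"no pair produces readout {x_on!r}")
    c_star = 0.0
    for r in records:
        if r.bound_rhs is None:
            raise ValueError("string universe does not cover this pair universe")
        c_star = max(c_star, float(r.posterior_mass) / r.bound_rhs)
    return Theorem2Report(readout=x_on, records=tuple(records), c_star=c_star)


def posterior_envelope(
    reports: Sequence[Theorem2Report],
) -> tuple:
    """Upper envelope of posterior mass against the exponent t = Delta - M-hat.

    Pools every (t, posterior) point of the reports, keeps the maximum
    posterior per integer t, and returns (t values, log2 envelope, fitted
    slope).  The theorem predicts the envelope halves per bit of t, i.e. a
    slope near -1.
    """
    best: Dict[int, float] = {}
    for rep in reports:
        for r in rep.records:
            t = r.delta_bits - r.m_hat_bits
            p = float(r.posterior_mass)
            if p > best.get(t, 0.0):
                best[t] = p
    ts = np.array(sorted(best), dtype=float)
    logs = np.array([math.log2(best[int(t)]) for t in ts])
    slope = float(np.polyfit(ts, logs, 1)[0]) if len(ts) >= 2 else float("nan")
    return ts, logs, slope


# ---------------------------------------------------------------------------
# Tail curves
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TailCurves:
    """Posterior tails against k: excess joint length and mutual-info shortfall."""

    readout: str
    k_values: tuple
    excess_tail: tuple  # Pr{ joint >= K(x) + k | x }
    mutual_tail: tuple  # Pr{ M-hat <= Delta - k | x }
    excess_slope: float
    mutual_slope: float


def fitted_tail_slope(tail: Sequence[float]) -> float:
    """Least-squares slope of log2(tail) over the leading strictly-positive run.

    A tail that hits zero decays faster than any geometric rate, so only the
    positive prefix informs the fit; a single positive point yields -inf
    (immediate extinction).
    """
    vals = []
    for v in tail:
        if v <= 0:
            break
        vals.append(math.log2(v))
    if len(vals) <= 1:
        return float("-inf") if len(tail) > len(vals) else float("nan")
    k = np.arange(len(vals), dtype=float)
    return float(np.polyfit(k, np.array(vals), 1)[0])


def tail_curves(
    pair_universe: PairUniverse,
    string_universe: UniverseTable,
    x_on: str,
    k_max: int = 5,
) -> TailCurves:
    """Exact posterior tails for the geometric-decay statements."""
    records = posterior_given_x(pair_universe, x_on, string_universe)
    if not records:
        raise ValueError(f"no pair produces readout {x_on!r}")
    k_x = string_universe.k_of(x_on)
    excess, mutual = [], []
    for k in range(k_max + 1):
        e = sum(
            (r.posterior_mass for r in records if r.joint_bits >= k_x + k),
            Fraction(0),
        )
        m = sum(
            (r.posterior_mass for r in records if r.m_hat_bits <= r.delta_bits - k),
            Fraction(0),
        )
        excess.append(float(e))
        mutual.append(float(m))
    return TailCurves(
        readout=x_on,
        k_values=tuple(range(k_max + 1)),
        excess_tail=tuple(excess),
        mutual_tail=tuple(mutual),
        excess_slope=fitted_tail_slope(excess),
        mutual_slope=fitted_tail_slope(mutual),
    )


# ---------------------------------------------------------------------------
# Theorem 3: Bayes factor identity
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BayesFactorResult:
    bits: float  # log2 m(x_on) - log2 m(x_off)
    k_on: int
    k_off: int
    residual: float  # |bits - (k_off - k_on)|


def bayes_factor(
    string_universe: UniverseTable,
    x_on: str,
    x_off: str,
    max_gap: Optional[float] = None,
) -> Optional[BayesFactorResult]:
    """Universal log Bayes factor for ON vs OFF and its identity residual.

    Returns None when either readout is not produced within the universe
    (the distinguished absent result).  The residual against the complexity
    gap K(off) - K(on) is asserted to stay within the universe's measured
    maximum coding gap, which is the exact in-universe form of the
    plus-or-minus O(1) identity.
    """
    log_m_on = string_universe.log2_m(x_on)
    log_m_off = string_universe.log2_m(x_off)
    if log_m_on is None or log_m_off is None:
        return None
    k_on = string_universe.k_of(x_on)
    k_off = string_universe.k_of(x_off)
    bits = log_m_on - log_m_off
    residual = abs(bits - (k_off - k_on))
    if max_gap is None:
        max_gap = coding_gap_report(string_universe).max_gap
    if residual > max_gap + 1e-9:
        raise AssertionError(
            f"Bayes-factor identity violated: residual {residual:.6f} exceeds "
            f"measured coding gap {max_gap:.6f}"
        )
    return BayesFactorResult(bits=bits, k_on=k_on, k_off=k_off, residual=residual)


# ---------------------------------------------------------------------------
# Defaults
# ---------------------------------------------------------------------------

def default_string_universe() -> UniverseTable:
    """String universe whose literal programs cover all pair encodings.

    Max code length 34 makes literal programs reach 24-bit strings, so every
    default pair-universe encoding (joint codes up to 24 bits) has exact
    in-universe complexity and mass.
    """
    return enumerate_universe(
        MicroInterpreter(step_cap=256), max_code_length=34, max_output_len=24
    )


def default_readout_suite(pair_universe: PairUniverse, n: int = 10) -> List[str]:
    """The n distinct ON readouts with the largest prior mass (stable order)."""
    mass: Dict[str, Fraction] = {}
    for rec in pair_universe.records:
        mass[rec.on_readout] = mass.get(rec.on_readout, Fraction(0)) + Fraction(
            1, 1 << rec.joint_bits
        )
    ranked = sorted(mass.items(), key=lambda kv: (-kv[1], kv[0]))
    return [k for k, _ in ranked[:n]]
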