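"""The Good Algorithmic Regulator diagnostic.

A regulator is a good algorithmic regulator when the readout it produces is
strictly more compressible than the null-baseline (regulator OFF) readout:
Delta = L(off) - L(on) > 0 under one fixed codelength estimator used for
both conditions.  This module computes the contrastive gap, paired sign-flip
permutation inference across episodes, the normalized compression distance
sanity check, and compression-based mutual-information estimates between
program descriptions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .estimators import Estimator, as_symbols

#: Symbol appended between x and y when forming the joint description x||y.
#: It is reserved: inputs are checked not to contain it.
JOINT_SEPARATOR_OFFSET = 1


@dataclass(frozen=True)
class GapResult:
    """Contrastive quantities a (ON), b (OFF) and Delta = b - a, in bits."""

    a_bits: float
    b_bits: float
    delta_bits: float
    estimator_id: str
    params: tuple
    n_episodes: int = 1
    p_value: Optional[float] = None
    n_permutations: Optional[int] = None
    seed: Optional[int] = None

    def __post_init__(self):
        if abs(self.delta_bits - (self.b_bits - self.a_bits)) > 1e-9:
            raise ValueError("delta_bits must equal b_bits - a_bits")


@dataclass(frozen=True)
class MutualInfoEstimate:
    """Compression-based M-hat = C(pW) + C(pR) - C(pW || pR)."""

    kw_bits: float
    kr_bits: float
    kwr_bits: float
    m_bits: float
    estimator_id: str
    codec_imperfection: bool  # set when m_bits < 0 (diagnostic, not clamped)


def delta_gap(x_on, x_off, estimator: Estimator) -> GapResult:
    """Contrastive compressibility gap between ON and OFF readouts.

    Both codelengths come from the same estimator configuration, so a
    positive ``delta_bits`` is evidence in the good-regulator direction.
    """
    on = as_symbols(x_on)
    off = as_symbols(x_off)
    if not on or not off:
        raise ValueError("readouts must be non-empty")
    a = estimator.codelength(on)
    b = estimator.codelength(off)
    return GapResult(
        a_bits=a.bits,
        b_bits=b.bits,
        delta_bits=b.bits - a.bits,
        estimator_id=a.estimator_id,
        params=a.params,
    )


def episode_gaps(episodes: Sequence[tuple], estimator: Estimator) -> list:
    """Per-episode Delta-hat for paired (x_on, x_off) readouts."""
    return [delta_gap(on, off, estimator) for on, off in episodes]


def paired_permutation_test(
    deltas: Sequence[float], n_permutations: int = 999, seed: int | None = None
) -> float:
    """Sign-flip permutation p-value for mean(Delta) > 0.

    Under the paired null the sign of each episode's Delta-hat is
    exchangeable; p = (1 + #{permuted mean >= observed}) / (n_permutations+1),
    the +1 smoothing keeping the test valid at any permutation count.
    """
    d = np.asarray(list(deltas), dtype=float)
    if d.size < 2:
        raise ValueError("need at least 2 episodes")
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    rng = np.random.default_rng(seed)
    observed = d.mean()
    signs = rng.choice([-1.0, 1.0], size=(n_permutations, d.size))
    permuted = (signs * d).mean(axis=1)
    exceed = int(np.sum(permuted >= observed - 1e-12))
    return (1 + exceed) / (n_permutations + 1)


def gap_with_inference(
    episodes: Sequence[tuple],
    estimator: Estimator,
    n_permutations: int = 999,
    seed: int | None = None,
) -> GapResult:
    """Aggregate GapResult over paired episodes with permutation p-value."""
    gaps = episode_gaps(episodes, estimator)
    a = sum(g.a_bits for g in gaps)
    b = sum(g.b_bits for g in gaps)
    p = paired_permutation_test(
        [g.delta_bits for g in gaps], n_permutations=n_permutations, seed=seed
    )
    return GapResult(
        a_bits=a,
        b_bits=b,
        delta_bits=b - a,
        estimator_id=gaps[0].estimator_id,
        params=gaps[0].params,
        n_episodes=len(gaps),
        p_value=p,
        n_permutations=n_permutations,
        seed=seed,
    )


def ncd(x, y, estimator: Estimator, symmetric: bool = False) -> float:
    """Normalized compression distance (C(xy) - min(Cx,Cy)) / max(Cx,Cy).

    The joint is the plain concatenation in the order x then y; with
    ``symmetric=True`` the smaller of both concatenation orders is used.
    """
    xs, ys = as_symbols(x), as_symbols(y)
    if not xs or not ys:
        raise ValueError("inputs must be non-empty")
    cx = estimator.bits(xs)
    cy = estimator.bits(ys)
    cxy = estimator.bits(xs + ys)
    if symmetric:
        cxy = min(cxy, estimator.bits(ys + xs))
    return (cxy - min(cx, cy)) / max(cx, cy)


def mutual_info_estimate(p_w, p_r, estimator: Estimator) -> MutualInfoEstimate:
    """M-hat(W:R) between two program descriptions via joint compression.

    The joint description is pW, a reserved out-of-alphabet separator
    symbol, then pR; the identity m = C(pW) + C(pR) - C(pW||pR) may be
    negative for imperfect codecs, which is reported (flagged), never
    clamped.
    """
    w = as_symbols(p_w)
    r = as_symbols(p_r)
    if not w or not r:
        raise ValueError("program descriptions must be non-empty")
    sep = max(max(w), max(r)) + JOINT_SEPARATOR_OFFSET
    if sep > 255:
        raise ValueError("no reserved separator symbol available (alphabet full)")
    kw = estimator.bits(w)
    kr = estimator.bits(r)
    kwr = estimator.bits(w + (sep,) + r)
    m = kw + kr - kwr
    return MutualInfoEstimate(
        kw_bits=kw,
        kr_bits=kr,
        kwr_bits=kwr,
        m_bits=m,
        estimator_id=estimator.estimator_id,
        codec_imperfection=m < 0,
    )
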