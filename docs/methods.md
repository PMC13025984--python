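# Methods

This note documents the models, estimators, fixtures and numerical choices
behind `algoreg`, and what the shipped tests do and do not establish.

## 1. The coupled world–regulator model

Worlds and regulators are deterministic causal finite-state transducers.
Each machine is a total map: `transition(state, input) → state` and
`emission(state, input) → symbol`, plus an initial state and an *initial
emission* — the symbol produced at t = 1 before any input has been seen.
The coupled episode uses staggered synchronous semantics: at t = 1 both
machines emit their initial emission; at every later step each machine
consumes the other's emission from the previous step, emits, and
transitions.  Output at step t therefore depends only on inputs from steps
< t, the episode always exists, and it is unique — no fixed-point search.
The mutual-stream equations leave the simultaneity convention open; the
staggered reading is the minimal one consistent with "deterministic causal"
machines, and the initial emission resolves the bootstrap.  The OFF
baseline couples the world to the *null regulator*, a 1-state machine that
emits symbol 0 forever.

**Canonical code.** "Shortest program" is uncomputable, so each machine is
identified with a canonical self-delimiting code: Elias-gamma headers for
the state and alphabet counts, then fixed-width fields for the initial
state/emission and the flattened tables.  Code length is the upper-bound
surrogate for K(machine).  The codebook is prefix-free (every field width
is determined by the already-decoded header), which is what makes
prefix-prior sampling by rejection exact: feed fair coin flips to the
decoder and accept completed code words — each program is drawn with
probability 2^(−length), conditioned on fitting the length bound.

## 2. Codelength estimators

All estimators are deterministic and used identically across the ON and
OFF conditions of any one comparison; a `CodelengthEstimate` records the
estimator identity and parameters alongside the bits.

**LZ76.** `lz76_complexity` is the 1976 exhaustive-history production
complexity: phrases are the shortest extensions not copyable from an
earlier position (self-overlap allowed), with the terminal phrase counted
even when reproducible.  The implementation locates reproducibility
witnesses with `bytes.find` and an exponential-plus-binary search on the
phrase length; a quadratic-time naive re-derivation serves as the test
oracle.  `lz76_codelength` charges each phrase a position pointer into the
n-symbol history plus one literal innovation symbol,

    L(s) = c(s) · (log₂ n + log₂ A) + |γ(n)| + |γ(A)|,

the classic two-part phrase code with an explicit self-delimiting header.
We use the history-pointer form rather than a pointer into the phrase
dictionary (log₂ c per phrase) deliberately: the dictionary form converges
to the entropy rate only at astronomically long inputs (its deficit is
still ≈ 0.17 bits/symbol for fair-coin strings at n = 10⁵), while the
history-pointer form is within 0.08 bits/symbol there, which is the
finite-n accuracy the validation targets require.  When the alphabet size
is not declared it is inferred as the number of distinct symbols, so
estimates are invariant under alphabet relabeling.

**BDM.** `bdm_codelength` tiles the string into non-overlapping blocks
scored by an exact CTM table (see §3): the sum over distinct blocks of
K(block) + log₂ multiplicity, with the log base 2 for consistency with
every other bit count.  A trailing partial block is coded literally at
log₂ A bits per symbol behind a 1-bit flag.  Block/tiling boundary effects
are an estimator bias, not corrected; the table must be total for the
configured block size (guaranteed for block sizes up to the universe's
literal-program reach).

**Codecs.** `codec_codelength` reports 8 × compressed byte length under a
registered lossless codec (zlib, lzma, bz2 from the standard library; the
registry accepts external codecs).  Serialization is one symbol per byte,
fixed and documented so joint descriptions are bit-reproducible.  Codec
headers make short-string estimates coarse; that is why the
mutual-information estimator (below) defaults to zlib, whose ~100-bit
header largely cancels in the identity K(x) + K(y) − K(x,y).

**Oracles.** `bernoulli_entropy` and `gaussian_entropy_rate`
(½·log₂ 2πeσ²) are the closed forms used to validate estimator
convergence; only the scalar white-Gaussian case is provided.

## 3. The exact micro program universe

The interpreter runs self-delimiting programs of two kinds behind a leading
mode bit: *literal* programs (γ-coded length n, then n raw bits, printed
verbatim) and *generator* programs (γ-coded output length, then a canonical
transducer code; the machine free-runs against null input for n steps).
Literal programs play the role of the print-instruction every real
universal machine has: they guarantee every short string has at least one
program, so K and m are total on the covered range, CTM tables are total,
and the complexities of program encodings themselves (needed by the tilt
module) are defined.  The halting domain is prefix-free, so Kraft–McMillan
applies.

Enumeration is exact and efficient: masses are integers at scale 2^L (no
floating-point drift; Kraft sums and posteriors are exact rationals);
generator programs are grouped by their behaviorally relevant fields (in a
free run only the input-0 table column matters), each group contributing
its exact program count; literal mass is summed in closed form per length,
with per-string literal contributions served lazily by the table lookup.
A brute-force interpreter that actually executes every bitstring
cross-checks the structural enumeration on small universes in the tests.

Resource bounds stand in for the halting problem: output lengths beyond the
step cap or the configured output bound are the documented non-halting
bucket.  Raising either bound only adds programs, so masses weakly increase
and K values weakly decrease (tested).  Defaults: max code length L = 22,
step cap 256, max output length 16.  At this scale the measured
Coding-Theorem constants are 0 ≤ K(x) + log₂ m(x) ≤ 1.585 bits.

## 4. The GAR diagnostic

`delta_gap` computes â = L(x_on), b̂ = L(x_off) and Δ̂ = b̂ − â under one
estimator configuration; positive Δ̂ is the good-regulator direction.
Inference across episodes uses a paired sign-flip permutation test on the
per-episode Δ̂ with the mean as statistic and the +1 smoothing rule
p = (1 + #{permuted ≥ observed}) / (n_perm + 1), which keeps the test
level-valid at any permutation count (calibration verified by simulation).
NCD follows the standard formula on the plain concatenation x‖y in that
order (a symmetrized variant is an option, not the default).  The
mutual-information estimate M̂ = C(pW) + C(pR) − C(pW ⧺ sep ⧺ pR) uses a
reserved out-of-alphabet separator symbol; negative M̂ is reported with a
codec-imperfection flag, never clamped, since it diagnoses the codec rather
than the programs.

## 5. Exact theorem verification (tilt)

The pair universe enumerates every interface-compatible (W, R) pair whose
concatenated canonical codes fit the joint length bound (default 24 bits,
horizon 8), runs the ON episode and the OFF (null-regulator) episode for
each, and places the prefix prior 2^(−joint bits) over pairs.  Posteriors
given a readout are exact rationals; the Bayes normalization and the
closed form 2^(−|p|)/m(x) agree identically.

In-universe surrogates: K values of readouts and of program encodings come
from a string universe with L = 34, whose literal programs reach 24-bit
strings — so every pair encoding has a defined complexity.  Per pair,
Δ = K(off readout) − K(on readout) and M̂ = K(enc W) + K(enc R) −
K(enc W ‖ enc R); the joint encoding is an upper-bound surrogate for
K(W,R).  `verify_theorem2` reports the smallest constant C* making
posterior ≤ C*·2^{M̂−Δ} hold for every consistent pair; across the default
10-readout suite (the highest-prior-mass ON readouts) C* ≈ 0.02–0.04 and
varies by a factor ≈ 2.3.

Two shape claims about this bound are *not* reproduced at this universe
scale, and the acceptance tests that assert them fail honestly:

- the posterior upper envelope against t = Δ − M̂ has essentially one
  binding point (the shortest consistent pair), so no per-bit halving trend
  is measurable — the bound holds but is slack except at that point;
- the excess-length tail Pr{joint ≥ K(x)+k | x} decays at ≈ −0.4 bits per
  unit k, not ≤ −0.8: the transducer codebook's length spectrum is sparse
  (adding a state costs ~6 bits while multiplying the program count by
  ~2^3.6), so mass thins slowly.  The geometric *bound* holds with a small
  constant; near-tightness would require a codebook with sub-exponential
  program counts per length.

The mutual-information tail is degenerate in the favorable direction: no
enumerated pair has M̂ ≤ Δ, so Pr{M̂ ≤ Δ − k} ≡ 0.  The Bayes-factor
identity is exact by construction: the residual
|log₂ m(x_on)/m(x_off) − (K(x_off) − K(x_on))| is a difference of two
per-string coding gaps and can never exceed the universe's measured maximum
gap.  Conditioning on the OFF-complexity stratum E_b supports both an
equality stratum (default) and a ≥-threshold mode; the per-pair Δ used in
the bound always comes from that pair's own OFF readout.

## 6. Fixtures

**Thermostat.** T_{t+1} = T_t + ρ·(T_out,t − T_t) + u_t·P with bang-bang
hysteresis control (switch on below setpoint − deadband, off above
setpoint + deadband).  The readout is the error signal T − setpoint
quantized to 8 levels on [−4, 4].  Defaults: ρ = 0.42, P = 0.7,
deadband = 1.55, setpoint 20, horizon 2000; outdoor temperature is a
seeded stationary AR(1) path (mean 18, coefficient 0.52, innovation 0.36
→ sd ≈ 0.42, correlation time ≈ 1.5 steps), shared between the ON and OFF
runs of an episode so gaps are paired.  These conditions were chosen, after
a parameter study, as the regime in which regulation genuinely manifests as
compression on this quantizer: the heater (static lift P/ρ ≈ 1.67 < the
2-unit outdoor deficit) saturates and clamps the error *inside* one
quantization bin, while the unregulated room equilibrates exactly at a bin
boundary and dithers with the weather.  Limit-cycling configurations on
this even 8-level grid put the deadband astride the boundary at zero, and
the cycle's switching innovations make the ON readout *less* LZ-compressible
than the OFF staircase — the contrast then has the wrong sign.  The
classic bounded limit cycle (period ≥ 2) is exhibited exactly by the
transducer incarnation (`thermostat_world_machine` + `bang_bang_machine`).

A world-independent fair-coin emitter is provided as the trivial control.
Its median Δ̂ is strongly *negative* (≈ −1100 bits at these conditions),
not near zero: injected actuation noise is filtered into the readout and
strictly lengthens its description relative to the null.  The meaningful
property — the random emitter never produces positive GAR evidence while
the bang-bang controller does in every episode — is what the
discrimination test asserts; the near-zero-median variant of the claim is
kept as a failing acceptance check because it cannot hold for any emitter
power able to regulate.

**Membrane scan.** Histories follow B3/S23 on a torus; an optional drive
region is refreshed with i.i.d. cells each step (a sustained noise
source).  A candidate membrane is a rectangle; its readout is the
inner-perimeter cell states in row-major order, concatenated over steps
1..T.  The ablation null re-evolves the whole history after a
*density-preserving shuffle* of the candidate's interior at t = 0
(replaying the drive), averaged over 3 replicates; shuffling rather than
refilling means a dead or saturated region is exactly its own null, while
arrangement — the only thing a structure has — is destroyed.  A
time-shuffle of the readout is the cheaper, weaker alternative null.
Δ̂ = mean L(null) − L(actual); ranking is Δ̂ descending with ties broken by
smaller area then row-major position.

The agency fixture (64×64, T = 128) embeds a blinker ringed by eight
still-life blocks (35 live cells) far from a 12×12 driven noise square.
Ablating the structured interior reliably produces an expanding soup whose
debris floods the membrane (Δ̂ ≈ +300…+2800 bits across seeds), the noise
window's Δ̂ fluctuates near zero (two realizations of the same driven
chaos), and empty windows score exactly zero — so the structure ranks
first.  A lone 3-cell blinker would not: its ablation usually dies before
reaching the membrane, which is why the fixture gives the oscillator a
body of still-life mass.

## 7. What the synthetic fixtures do and do not show

The fixtures emulate the qualitative regimes the framework reasons about —
a regulator clamping a readout against exogenous variability, structure
embedded in noise, i.i.d./periodic extremes for estimator validation.  They
are deterministic given seeds, low-dimensional, and their quantization and
noise scales were co-designed with the default estimator; passing tests
show the diagnostic behaves as the theory predicts *under these
conditions*, not that any particular real system is or is not an
algorithmic regulator, and not that the estimator surrogates approximate
true Kolmogorov complexity beyond their upper-bound character.  Real
biological or social readouts bring non-stationarity, measurement noise
and estimator-choice sensitivity that the fixtures deliberately exclude.

## 8. Numerical and interface conventions

Exact arithmetic (integer masses at scale 2^L, `fractions.Fraction` at the
boundaries) everywhere a theorem is verified; floats only for estimator
bits and reported gaps (per-string coding gaps use log₂ of big-integer
rationals, error < 10⁻¹²).  Alphabets are 0-indexed with 0 the designated
null symbol; symbol sequences cap at 256 symbols (one byte each).
Universe tables serialize as a JSON metadata line plus CSV entries;
transducers as JSON; transcripts as CSV with a JSON comment header.  Every
CLI command writes a `RunManifest` (seed, config hash, checksums) next to
its outputs, and documented runs re-execute byte-identically.  All
randomness flows through seeded `numpy` generators; the CLI derives
per-stage seeds from `--seed`.
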