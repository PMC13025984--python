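"""Synthetic fixtures, file formats and run manifests.

Everything needed to exercise the diagnostic end to end without external
data: the thermostat world with a bang-bang (hysteresis) controller in both
a real-valued simulation and a finite-transducer incarnation, canonical
string generators for estimator validation, and reproducibility manifests
for CLI runs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .estimators import QuantizationSpec, quantize
from .machines import TransducerSpec

#: Default readout quantizer: 8 levels over [-4, +4] temperature units of
#: error (T - setpoint); recorded in every gap result via estimator params.
DEFAULT_QUANTIZATION = QuantizationSpec(levels=8, lower=-4.0, upper=4.0)


@dataclass(frozen=True)
class ThermostatParams:
    """A single-room thermal plant with an on/off heater.

    T_{t+1} = T_t + retention * (T_out,t - T_t) + u_t * power, with
    u_t in {0, 1} chosen by a bang-bang controller with a symmetric
    deadband around the setpoint (ON mode) or forced to 0 (OFF mode).
    ``outdoor`` may be a constant or a per-step sequence; the readout is the
    quantized error signal T - setpoint.
    """

    retention: float = 0.42
    outdoor: float | Sequence[float] = 18.0
    power: float = 0.7
    setpoint: float = 20.0
    deadband: float = 1.55
    horizon: int = 2000
    initial_temperature: Optional[float] = None  # default: first outdoor value
    quantization: QuantizationSpec = field(default=DEFAULT_QUANTIZATION)

    def __post_init__(self):
        if not 0.0 < self.retention < 1.0:
            raise ValueError("retention must lie in (0, 1)")
        if self.deadband <= 0:
            raise ValueError("deadband must be positive")
        if self.horizon < 1:
            raise ValueError("horizon must be >= 1")
        if self.power < 0:
            raise ValueError("power must be non-negative")

    def outdoor_series(self) -> np.ndarray:
        if np.isscalar(self.outdoor):
            return np.full(self.horizon, float(self.outdoor))
        arr = np.asarray(self.outdoor, dtype=float)
        if arr.size < self.horizon:
            raise ValueError(
                f"outdoor sequence length {arr.size} shorter than horizon {self.horizon}"
            )
        return arr[: self.horizon]


def thermostat_episode(
    params: ThermostatParams, mode: str = "ON", controller: str = "bang-bang",
    seed: Optional[int] = None,
) -> tuple:
    """Simulate one episode; returns (temperature array, quantized readout).

    ``mode='OFF'`` forces u_t = 0 (the null regulator).  ``controller``
    selects the ON-mode policy: ``'bang-bang'`` (hysteresis around the
    setpoint) or ``'random'`` (a world-independent fair-coin emitter, the
    trivial control for sanity checks; requires ``seed``).
    """
    if mode not in ("ON", "OFF"):
        raise ValueError("mode must be 'ON' or 'OFF'")
    if controller not in ("bang-bang", "random"):
        raise ValueError("controller must be 'bang-bang' or 'random'")
    outdoor = params.outdoor_series()
    t_cur = (
        float(params.initial_temperature)
        if params.initial_temperature is not None
        else float(outdoor[0])
    )
    rng = np.random.default_rng(seed) if controller == "random" else None
    temps = np.empty(params.horizon)
    u = 0
    for t in range(params.horizon):
        temps[t] = t_cur
        if mode == "OFF":
            u = 0
        elif controller == "random":
            u = int(rng.integers(0, 2))
        else:  # bang-bang with hysteresis: switch only outside the deadband
            if t_cur < params.setpoint - params.deadband:
                u = 1
            elif t_cur > params.setpoint + params.deadband:
                u = 0
        t_cur = t_cur + params.retention * (outdoor[t] - t_cur) + u * params.power
    readout = quantize(temps - params.setpoint, params.quantization)
    return temps, readout


def outdoor_weather(
    horizon: int, seed: int, mean: float = 18.0, ar_coeff: float = 0.52,
    innovation_sd: float = 0.36,
) -> np.ndarray:
    """Fluctuating outdoor temperature: a seeded stationary AR(1) path.

    Defaults give a stationary standard deviation near 0.42 temperature
    units with a short correlation time (~1.5 steps) — brisk weather noise
    that the unregulated room transmits into its readout, so the OFF
    baseline is not trivially simple.
    """
    rng = np.random.default_rng(seed)
    stationary_sd = innovation_sd / np.sqrt(1 - ar_coeff**2)
    x = rng.normal(0.0, stationary_sd)
    out = np.empty(horizon)
    for t in range(horizon):
        out[t] = mean + x
        x = ar_coeff * x + rng.normal(0.0, innovation_sd)
    return out


def thermostat_fixture(
    seed: int, n_episodes: int = 20, params: Optional[ThermostatParams] = None,
    controller: str = "bang-bang",
) -> list:
    """Paired ON/OFF thermostat episodes over per-episode weather paths.

    Episode i uses the weather path seeded by (seed, i); ON and OFF share
    the path so the contrast is paired.  Returns a list of
    (readout_on, readout_off) tuples.
    """
    base = params or ThermostatParams()
    episodes = []
    for i in range(n_episodes):
        ep_seed = int(np.random.SeedSequence((seed, i)).generate_state(1)[0] % (2**31))
        weather = outdoor_weather(base.horizon, ep_seed)
        p = replace(base, outdoor=weather)
        _, on = thermostat_episode(p, "ON", controller=controller, seed=ep_seed)
        _, off = thermostat_episode(p, "OFF")
        episodes.append((on, off))
    return episodes


# ---------------------------------------------------------------------------
# Transducer incarnation of the thermostat (for the machines module)
# ---------------------------------------------------------------------------

def thermostat_world_machine(n_levels: int = 9) -> TransducerSpec:
    """The thermostat plant as a finite transducer over quantized temperature.

    States and output symbols are temperature levels 0..n_levels-1; input 0
    (heater off) moves one level down, input 1 (heater on) one level up,
    both saturating.  The emitted symbol is the current level.
    """
    transition, emission = [], []
    for level in range(n_levels):
        for u in (0, 1):
            nxt = max(level - 1, 0) if u == 0 else min(level + 1, n_levels - 1)
            transition.append(nxt)
            emission.append(level)
    mid = n_levels // 2
    return TransducerSpec(
        n_states=n_levels,
        n_inputs=2,
        n_outputs=n_levels,
        transition=tuple(transition),
        emission=tuple(emission),
        initial_state=mid,
        initial_emission=mid,
    )


def bang_bang_machine(n_levels: int = 9, low: int = 3, high: int = 5) -> TransducerSpec:
    """Bang-bang controller with hysteresis as a 2-state transducer.

    State 0 = heating, state 1 = idle.  Reading a level below ``low``
    switches to heating, above ``high`` to idle; in between the state (and
    hence the emitted command) is held — the hysteresis memory.
    """
    if not 0 <= low < high <= n_levels - 1:
        raise ValueError("need 0 <= low < high <= n_levels-1")
    transition, emission = [], []
    for state in (0, 1):
        for level in range(n_levels):
            if level < low:
                nxt = 0
            elif level > high:
                nxt = 1
            else:
                nxt = state
            transition.append(nxt)
            emission.append(1 if nxt == 0 else 0)  # heating state emits u=1
    return TransducerSpec(
        n_states=2,
        n_inputs=n_levels,
        n_outputs=2,
        transition=tuple(transition),
        emission=tuple(emission),
        initial_state=1,
        initial_emission=0,
    )


def tail_cycle_length(seq: Sequence[int], max_period: int = 64) -> Optional[int]:
    """Smallest period of the eventually-periodic tail of ``seq``, or None.

    Checks whether the last half of the sequence is periodic with some
    period <= max_period (cycle detection on the tail).
    """
    s = tuple(seq)
    tail = s[len(s) // 2 :]
    for period in range(1, min(max_period, len(tail) // 2) + 1):
        if all(tail[i] == tail[i + period] for i in range(len(tail) - period)):
            return period
    return None


# ---------------------------------------------------------------------------
# Canonical strings
# ---------------------------------------------------------------------------

def make_string(kind: str, params: dict, seed: Optional[int] = None) -> tuple:
    """Reproducible fixture sequences: bernoulli, periodic or constant.

    ``params`` by kind — bernoulli: {p, n}; periodic: {motif, n};
    constant: {symbol, n}.
    """
    if kind == "bernoulli":
        rng = np.random.default_rng(seed)
        return tuple(int(v) for v in (rng.random(params["n"]) < params["p"]))
    if kind == "periodic":
        motif = [int(c) for c in str(params["motif"])]
        n = params["n"]
        reps = -(-n // len(motif))
        return tuple(motif * reps)[:n]
    if kind == "constant":
        return (int(params["symbol"]),) * params["n"]
    raise ValueError(f"unknown string kind {kind!r}")


# ---------------------------------------------------------------------------
# Run manifests
# ---------------------------------------------------------------------------

TOOL_VERSION = "0.1.0"


@dataclass(frozen=True)
class RunManifest:
    """Reproducibility record emitted next to every CLI output."""

    seed: Optional[int]
    config_hash: str
    tool_version: str
    checksums: dict

    @classmethod
    def create(cls, seed: Optional[int], config: dict, files: Sequence[str]) -> "RunManifest":
        blob = json.dumps(config, sort_keys=True, default=str).encode()
        checksums = {}
        for path in files:
            h = hashlib.sha256()
            with open(path, "rb") as fh:
                h.update(fh.read())
            checksums[str(path)] = h.hexdigest()
        return cls(
            seed=seed,
            config_hash=hashlib.sha256(blob).hexdigest()[:16],
            tool_version=TOOL_VERSION,
            checksums=checksums,
        )

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "seed": self.seed,
                    "config_hash": self.config_hash,
                    "tool_version": self.tool_version,
                    "checksums": self.checksums,
                },
                fh,
                indent=1,
                sort_keys=True,
            )


def read_symbols(path) -> tuple:
    """Read a symbol sequence from a single-column CSV or a compact string file."""
    with open(path) as fh:
        text = fh.read().strip()
    if "\n" in text or "," in text:
        lines = [ln.strip() for ln in text.replace(",", "\n").splitlines()]
        values = [ln for ln in lines if ln and not ln.startswith("#")]
        if values and values[0].lower() in ("symbol", "value", "x"):
            values = values[1:]
        return tuple(int(v) for v in values)
    return tuple(int(c) for c in text)


def write_symbols(path, seq) -> None:
    with open(path, "w") as fh:
        fh.write("symbol\n")
        for v in seq:
            fh.write(f"{int(v)}\n")
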