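"""Forward model of a thermally modulated metal-oxide-semiconductor gas sensor.

A MOS chemiresistor sits in a voltage divider: the supply ``V_C`` drives the
series pair (sensing film ``R_S``, load resistor ``R_L``) and the measured
output is the load-resistor drop ``V_OUT = V_C * R_L / (R_S + R_L)``.  The
integrated heater is ramped from 0 to 5 V, so one recording ("sweep") is the
curve ``V_OUT(V_H)`` sampled on a regular heater-voltage grid — by default 501
points at 0.01 V resolution.

Reducing gases (here ethanol and acetone) lower the film resistance once the
film is hot enough for the surface redox reaction to run.  The model captures
this with, per gas, a logistic onset gate in heater voltage and a power law in
concentration:

    R_S(v) = R_air(v) / (1 + sum_g A_g * sigma((v - v_on_g)/w_g) * (c_g/c_ref)^beta_g)

where ``R_air`` is the clean-air baseline resistance, interpolated
log-linearly between its cold-heater and hot-heater values, and ``sigma`` is
the standard logistic function.  Gas amplitudes ``A_g`` are not free-hand
constants: :func:`calibrate_amplitudes` inverts the divider in closed form so
that the noise-free single-gas sweep at the reference concentration (0.5 %)
attains a prescribed peak output voltage.

The dataset generator emulates a two-analyte factorial design: 13 serial
half-log2 dilutions per analyte (2^-7 % ... 2^-1 %, ratio sqrt(2)), all 13 x 13
combinations, optionally in replicate, with additive Gaussian voltage noise.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.special import expit

__all__ = [
    "GAS_NAMES",
    "HeaterRamp",
    "AnalyteMix",
    "CircuitParams",
    "GasParams",
    "GasResponseParams",
    "SensorSweep",
    "CalibrationError",
    "air_resistance",
    "sensor_resistance",
    "divider_voltage",
    "calibrate_amplitudes",
    "simulate_sweep",
    "concentration_levels",
    "generate_dataset",
]

GAS_NAMES = ("ethanol", "acetone")

#: Mass-percent to parts-per-million conversion (1 % = 10,000 ppm by mass).
PCT_TO_PPM = 1.0e4


class CalibrationError(ValueError):
    """Raised when a requested peak voltage cannot be reached by any amplitude."""


@dataclass(frozen=True)
class HeaterRamp:
    """Linear heater-voltage ramp, represented by its voltage grid only.

    The physical ramp rate (0.5 V/min in the reference setup) is metadata:
    the analysis consumes ``V_OUT(V_H)`` pairs, not a time series.
    """

    v_start: float = 0.0
    v_end: float = 5.0
    step: float = 0.01

    def __post_init__(self) -> None:
        if not self.v_start < self.v_end:
            raise ValueError(f"require v_start < v_end, got [{self.v_start}, {self.v_end}]")
        if self.step <= 0:
            raise ValueError(f"require step > 0, got {self.step}")

    @property
    def n_points(self) -> int:
        return int(round((self.v_end - self.v_start) / self.step)) + 1

    def grid(self) -> np.ndarray:
        """Heater voltage samples, evenly spaced, endpoints included."""
        return np.linspace(self.v_start, self.v_end, self.n_points)


@dataclass(frozen=True)
class AnalyteMix:
    """Mass fractions (in %) of the two analytes in the liquid sample."""

    c_ethanol: float
    c_acetone: float

    def __post_init__(self) -> None:
        if self.c_ethanol < 0 or self.c_acetone < 0:
            raise ValueError(
                f"concentrations must be >= 0, got ({self.c_ethanol}, {self.c_acetone})"
            )

    def as_dict(self) -> dict[str, float]:
        return {"ethanol": self.c_ethanol, "acetone": self.c_acetone}


@dataclass(frozen=True)
class CircuitParams:
    """Voltage-divider readout circuit: supply voltage and load resistance.

    Resistances are expressed in units of the load resistor, so ``r_load=1``
    by convention; only the ratio ``R_S / R_L`` enters the divider.
    """

    v_c: float = 5.0
    r_load: float = 1.0

    def __post_init__(self) -> None:
        if self.v_c <= 0:
            raise ValueError(f"supply voltage must be > 0, got {self.v_c}")
        if self.r_load <= 0:
            raise ValueError(f"load resistance must be > 0, got {self.r_load}")


@dataclass(frozen=True)
class GasParams:
    """Response-curve shape for one gas.

    amplitude   dimensionless conductance gain at the reference concentration
    v_onset     heater voltage (V) at the half-rise of the onset gate
    width       logistic width (V) of the onset
    beta        concentration exponent of the power law (0 < beta <= 1)
    """

    amplitude: float = 1.0
    v_onset: float = 2.0
    width: float = 0.5
    beta: float = 0.6

    def __post_init__(self) -> None:
        if self.amplitude <= 0:
            raise ValueError(f"amplitude must be > 0, got {self.amplitude}")
        if not 0 < self.v_onset < 5:
            raise ValueError(f"onset voltage must lie in (0, 5) V, got {self.v_onset}")
        if self.width <= 0:
            raise ValueError(f"onset width must be > 0, got {self.width}")
        if not 0 < self.beta <= 1:
            raise ValueError(f"beta must lie in (0, 1], got {self.beta}")


@dataclass(frozen=True)
class GasResponseParams:
    """Shape constants of the sensor response for both gases plus the air baseline.

    Defaults encode the qualitative phenomenology of the TGS2610-class
    sensor: ethanol's response rises earlier in the ramp; acetone rises later
    but more steeply and, after amplitude calibration, to a higher peak.
    ``r_air_high``/``r_air_low`` are the clean-air film resistances at cold
    and fully powered heater (in load-resistor units).
    """

    ethanol: GasParams = field(default_factory=lambda: GasParams(1.0, 1.6, 0.5, 0.6))
    acetone: GasParams = field(default_factory=lambda: GasParams(1.0, 2.4, 0.35, 0.6))
    c_ref: float = 0.5
    r_air_high: float = 50.0
    r_air_low: float = 8.0

    def __post_init__(self) -> None:
        if self.c_ref <= 0:
            raise ValueError(f"reference concentration must be > 0, got {self.c_ref}")
        if not self.r_air_high >= self.r_air_low > 0:
            raise ValueError(
                f"require r_air_high >= r_air_low > 0, got ({self.r_air_high}, {self.r_air_low})"
            )
        if not self.ethanol.v_onset < self.acetone.v_onset:
            raise ValueError(
                "ethanol onset must precede acetone onset "
                f"({self.ethanol.v_onset} !< {self.acetone.v_onset})"
            )

    def gas(self, name: str) -> GasParams:
        if name not in GAS_NAMES:
            raise KeyError(f"unknown gas {name!r}; expected one of {GAS_NAMES}")
        return getattr(self, name)


@dataclass(frozen=True)
class SensorSweep:
    """One heater-ramp recording with its provenance."""

    heater_v: np.ndarray
    out_v: np.ndarray
    mix: AnalyteMix
    replicate: int = 0
    seed: int | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "heater_v", np.asarray(self.heater_v, dtype=float))
        object.__setattr__(self, "out_v", np.asarray(self.out_v, dtype=float))
        if self.heater_v.shape != self.out_v.shape:
            raise ValueError(
                f"heater_v and out_v must match, got {self.heater_v.shape} vs {self.out_v.shape}"
            )

    def __len__(self) -> int:
        return self.heater_v.size


def air_resistance(
    v_h: float | np.ndarray,
    params: GasResponseParams,
    ramp: HeaterRamp = HeaterRamp(),
) -> np.ndarray:
    """Clean-air film resistance, log-linear in heater voltage across the ramp."""
    frac = (np.asarray(v_h, dtype=float) - ramp.v_start) / (ramp.v_end - ramp.v_start)
    return params.r_air_high * (params.r_air_low / params.r_air_high) ** frac


def sensor_resistance(
    v_h: float | np.ndarray,
    mix: AnalyteMix,
    params: GasResponseParams = GasResponseParams(),
    ramp: HeaterRamp = HeaterRamp(),
) -> np.ndarray:
    """Film resistance under a gas mixture at heater voltage ``v_h``.

    Strictly positive, and strictly decreasing in each gas concentration at
    any heater voltage (more reducing gas -> more free carriers -> lower
    resistance).  With both concentrations zero it equals the air baseline
    exactly.
    """
    v = np.asarray(v_h, dtype=float)
    denom = np.ones_like(v)
    for name in GAS_NAMES:
        g = params.gas(name)
        c = mix.as_dict()[name]
        if c == 0.0:
            continue
        gate = expit((v - g.v_onset) / g.width)
        denom = denom + g.amplitude * gate * (c / params.c_ref) ** g.beta
    return air_resistance(v, params, ramp) / denom


def divider_voltage(
    r_s: float | np.ndarray, circuit: CircuitParams = CircuitParams()
) -> np.ndarray:
    """Output voltage of the divider for film resistance ``r_s``.

    ``V_OUT = V_C * R_L / (R_S + R_L)``; always in (0, V_C) for finite
    positive ``r_s``.
    """
    r = np.asarray(r_s, dtype=float)
    if np.any(r <= 0):
        raise ValueError("sensor resistance must be > 0")
    return circuit.v_c * circuit.r_load / (r + circuit.r_load)


def calibrate_amplitudes(
    targets: Mapping[str, float],
    params: GasResponseParams = GasResponseParams(),
    circuit: CircuitParams = CircuitParams(),
    ramp: HeaterRamp = HeaterRamp(),
) -> GasResponseParams:
    """Solve gas amplitudes so single-gas sweeps hit prescribed peak voltages.

    For each gas the target is the maximum ``V_OUT`` of the noise-free sweep
    at the reference concentration (0.5 %).  Because both the falling air
    baseline and the rising onset gate drive ``R_S`` down monotonically along
    the ramp, the peak sits at the ramp end, where the divider inverts in
    closed form:

        R_S,peak = R_L * (V_C - V_peak) / V_peak
        A_g      = (R_air(v_end) / R_S,peak - 1) / sigma((v_end - v_on_g)/w_g)

    Raises :class:`CalibrationError` if the target is outside what the
    divider (or a positive amplitude) can reach.
    """
    updates: dict[str, GasParams] = {}
    r_air_end = float(air_resistance(ramp.v_end, params, ramp))
    for name, v_peak in targets.items():
        g = params.gas(name)
        if not 0 < v_peak < circuit.v_c:
            raise CalibrationError(
                f"target peak {v_peak} V for {name} outside (0, {circuit.v_c}) V"
            )
        r_peak = circuit.r_load * (circuit.v_c - v_peak) / v_peak
        gate_end = float(expit((ramp.v_end - g.v_onset) / g.width))
        amplitude = (r_air_end / r_peak - 1.0) / gate_end
        if amplitude <= 0:
            raise CalibrationError(
                f"target peak {v_peak} V for {name} lies below the clean-air "
                f"baseline ({float(divider_voltage(r_air_end, circuit)):.3f} V)"
            )
        updates[name] = dataclasses.replace(g, amplitude=amplitude)
    return dataclasses.replace(params, **updates)


def simulate_sweep(
    mix: AnalyteMix,
    ramp: HeaterRamp = HeaterRamp(),
    params: GasResponseParams = GasResponseParams(),
    circuit: CircuitParams = CircuitParams(),
    noise_sd: float = 0.0,
    seed: int | None = None,
    replicate: int = 0,
) -> SensorSweep:
    """Simulate one sweep: deterministic forward model plus Gaussian voltage noise.

    Noise is additive on the output voltage and the result is clipped to the
    physical divider range [0, V_C].  Identical ``(mix, seed, noise_sd)``
    give bitwise-identical arrays.
    """
    if noise_sd < 0:
        raise ValueError(f"noise_sd must be >= 0, got {noise_sd}")
    v_h = ramp.grid()
    out = divider_voltage(sensor_resistance(v_h, mix, params, ramp), circuit)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        out = out + rng.normal(0.0, noise_sd, size=out.shape)
    out = np.clip(out, 0.0, circuit.v_c)
    return SensorSweep(heater_v=v_h, out_v=out, mix=mix, replicate=replicate, seed=seed)


def concentration_levels() -> np.ndarray:
    """The 13 serial-dilution mass fractions, 2^-7 % ... 2^-1 %, ratio sqrt(2).

    Endpoints are 0.0078125 % (78 ppm) and 0.5 % (5000 ppm).
    """
    exponents = np.arange(-14, -1) / 2.0
    return 2.0**exponents


def sweep_seed(master_seed: int, i_eth: int, i_ace: int, replicate: int) -> int:
    """Deterministic per-sweep seed fan-out from the master seed (< 2^31)."""
    ss = np.random.SeedSequence([int(master_seed), i_eth, i_ace, replicate])
    return int(ss.generate_state(1)[0] % 2**31)


def generate_dataset(
    levels_eth: Sequence[float] | None = None,
    levels_ace: Sequence[float] | None = None,
    replicates: int = 1,
    noise_sd: float = 0.02,
    seed: int = 0,
    ramp: HeaterRamp = HeaterRamp(),
    params: GasResponseParams = GasResponseParams(),
    circuit: CircuitParams = CircuitParams(),
) -> list[SensorSweep]:
    """Generate the full factorial sweep dataset.

    The default levels are the 13 serial dilutions for both analytes; with
    ``replicates=3`` this reproduces the reference design of
    13 x 13 x 3 = 507 recordings.  Per-sweep seeds are derived
    deterministically from the master seed, so the whole dataset is
    reproducible and individual sweeps can be regenerated in isolation.
    """
    if levels_eth is None:
        levels_eth = concentration_levels()
    if levels_ace is None:
        levels_ace = concentration_levels()
    levels_eth = np.asarray(levels_eth, dtype=float)
    levels_ace = np.asarray(levels_ace, dtype=float)
    if levels_eth.size == 0 or levels_ace.size == 0:
        raise ValueError("concentration level lists must be non-empty")
    if replicates < 1:
        raise ValueError(f"replicates must be >= 1, got {replicates}")
    sweeps: list[SensorSweep] = []
    for i, c_eth in enumerate(levels_eth):
        for j, c_ace in enumerate(levels_ace):
            for r in range(replicates):
                mix = AnalyteMix(c_ethanol=float(c_eth), c_acetone=float(c_ace))
                sweeps.append(
                    simulate_sweep(
                        mix,
                        ramp=ramp,
                        params=params,
                        circuit=circuit,
                        noise_sd=noise_sd,
                        seed=sweep_seed(seed, i, j, r),
                        replicate=r,
                    )
                )
    return sweeps
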