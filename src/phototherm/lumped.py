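"""Lumped-capacitance model of laser-heated colloidal samples.

A colloidal nanoparticle suspension in a vial, irradiated by a continuous
laser, is treated as a single uniform-temperature body with total heat
capacity ``sum(m_i * C_i)`` exchanging heat with the environment at a rate
proportional to its temperature rise.  Under a constant absorbed power the
rise above ambient follows

    dT(t) = tau * [I * (1 - 10**(-A)) * eta + Q0] / sum(m_i C_i) * (1 - exp(-t/tau))

where ``I`` is the incident laser power (W), ``A`` the optical density of
the sample at the excitation wavelength (so ``1 - 10**(-A)`` is the absorbed
fraction), ``eta`` the photothermal conversion efficiency, ``Q0`` the
parasitic power absorbed by solvent and container (W), and ``tau`` the
thermal time constant (s).  After the laser is switched off the rise relaxes
as ``dT(t) = dT_off * exp(-t/tau)`` with the same time constant.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Sequence

import numpy as np

__all__ = [
    "HeatCapacityComponent",
    "LumpedSystemParams",
    "ThermalTrace",
    "WATER_SPECIFIC_HEAT",
    "default_components",
    "predict_delta_t",
    "steady_state_delta_t",
    "simulate_cycles",
]

WATER_SPECIFIC_HEAT = 4.184  # J g^-1 degC^-1
POLYPROPYLENE_SPECIFIC_HEAT = 1.9  # J g^-1 degC^-1


@dataclass(frozen=True)
class HeatCapacityComponent:
    """One thermal mass in the lumped inventory (solvent, vial, ...).

    Parameters
    ----------
    label : str
        Human-readable name, e.g. ``"water"``.
    mass : float
        Mass in grams; must be positive.
    specific_heat : float
        Specific heat in J g^-1 degC^-1; must be positive.
    """

    label: str
    mass: float
    specific_heat: float

    def __post_init__(self) -> None:
        if not self.mass > 0:
            raise ValueError(f"mass must be > 0, got {self.mass}")
        if not self.specific_heat > 0:
            raise ValueError(f"specific_heat must be > 0, got {self.specific_heat}")

    @property
    def heat_capacity(self) -> float:
        """m * C in J degC^-1."""
        return self.mass * self.specific_heat


def default_components() -> list[HeatCapacityComponent]:
    """Default inventory: 1.0 g water plus a 1.0 g polypropylene tube."""
    return [
        HeatCapacityComponent("water", 1.0, WATER_SPECIFIC_HEAT),
        HeatCapacityComponent("polypropylene_tube", 1.0, POLYPROPYLENE_SPECIFIC_HEAT),
    ]


def total_heat_capacity(components: Sequence[HeatCapacityComponent]) -> float:
    """sum(m_i * C_i) in J degC^-1."""
    if not components:
        raise ValueError("components must be non-empty")
    return float(sum(c.heat_capacity for c in components))


@dataclass(frozen=True)
class LumpedSystemParams:
    """All parameters of the lumped heating model for one experiment.

    ``parasitic_power`` (Q0) is the power in watts absorbed by the solvent
    and container rather than by the nanoparticles; it is dimensionally a
    power, the only reading under which the heating law balances.
    """

    laser_power: float  # I, W
    absorbance: float  # A at the excitation wavelength, OD
    efficiency: float  # eta, dimensionless in [0, 1]
    time_constant: float  # tau, s
    components: tuple[HeatCapacityComponent, ...] = field(
        default_factory=lambda: tuple(default_components())
    )
    parasitic_power: float = 0.0  # Q0, W
    ambient_temp: float = 25.0  # degC

    def __post_init__(self) -> None:
        if self.laser_power < 0:
            raise ValueError("laser_power must be >= 0")
        if self.absorbance < 0:
            raise ValueError("absorbance must be >= 0")
        if not 0.0 <= self.efficiency <= 1.0:
            raise ValueError("efficiency must lie in [0, 1]")
        if not self.time_constant > 0:
            raise ValueError("time_constant must be > 0")
        if not self.components:
            raise ValueError("components must be non-empty")
        object.__setattr__(self, "components", tuple(self.components))

    @property
    def heat_capacity(self) -> float:
        """sum(m_i * C_i) in J degC^-1."""
        return total_heat_capacity(self.components)

    @property
    def absorbed_power(self) -> float:
        """Total heating power I*(1-10^-A)*eta + Q0 in watts."""
        return (
            self.laser_power * (1.0 - 10.0 ** (-self.absorbance)) * self.efficiency
            + self.parasitic_power
        )


@dataclass
class ThermalTrace:
    """A timestamped temperature record of one sample.

    Attributes
    ----------
    times : ndarray
        Sample times in seconds, strictly increasing from 0.
    temps : ndarray
        Temperatures in degC, same length as ``times``.
    ambient_temp : float
        Ambient reference temperature in degC.
    laser_on_time : float
        Time the laser was switched on (s).
    laser_off_time : float or None
        Time the laser was switched off (s); ``None`` when the trace only
        covers heating.
    metadata : dict
        Free-form annotations (ground-truth parameters, phase boundaries,
        instrument settings).
    """

    times: np.ndarray
    temps: np.ndarray
    ambient_temp: float
    laser_on_time: float = 0.0
    laser_off_time: float | None = None
    metadata: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.temps = np.asarray(self.temps, dtype=float)
        if self.times.ndim != 1 or self.times.shape != self.temps.shape:
            raise ValueError("times and temps must be 1-D arrays of equal length")
        if self.times.size < 2:
            raise ValueError("a trace needs at least 2 samples")
        if not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")
        if not np.all(np.isfinite(self.temps)):
            raise ValueError("temps must be finite")
        if self.laser_off_time is not None and not (
            self.laser_on_time < self.laser_off_time
        ):
            raise ValueError("laser_on_time must precede laser_off_time")

    @property
    def delta_t(self) -> np.ndarray:
        """Temperature rise above ambient, degC."""
        return self.temps - self.ambient_temp

    def heating_slice(self) -> tuple[np.ndarray, np.ndarray]:
        """(times, temps) of samples while the laser is on."""
        hi = self.laser_off_time if self.laser_off_time is not None else np.inf
        m = (self.times >= self.laser_on_time) & (self.times <= hi)
        return self.times[m], self.temps[m]

    def cooling_slice(self) -> tuple[np.ndarray, np.ndarray]:
        """(times, temps) of samples strictly after the laser went off."""
        if self.laser_off_time is None:
            return np.empty(0), np.empty(0)
        m = self.times > self.laser_off_time
        return self.times[m], self.temps[m]


def predict_delta_t(params: LumpedSystemParams, t: float | np.ndarray) -> float | np.ndarray:
    """Temperature rise above ambient at time ``t`` after laser-on.

    Evaluates ``tau * P_abs / sum(m_i C_i) * (1 - exp(-t / tau))`` where
    ``P_abs = I (1 - 10**(-A)) eta + Q0``.  Vectorised over ``t``.

    Raises
    ------
    ValueError
        If any ``t`` is negative.
    """
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("t must be >= 0")
    ss = steady_state_delta_t(params)
    out = ss * (1.0 - np.exp(-t_arr / params.time_constant))
    return float(out) if np.isscalar(t) or t_arr.ndim == 0 else out


def steady_state_delta_t(params: LumpedSystemParams) -> float:
    """Limiting (steady-state) temperature rise, degC."""
    return params.time_constant * params.absorbed_power / params.heat_capacity


def simulate_cycles(
    params: LumpedSystemParams,
    on_duration: float,
    off_duration: float,
    n_cycles: int = 1,
    dt: float = 60.0,
) -> ThermalTrace:
    """Simulate repeated laser on/off irradiation cycles.

    Heating phases follow the saturating-exponential law from the rise at
    phase start; cooling phases relax exponentially with the same time
    constant.  Phase boundaries are chained in closed form, so the result is
    exact at every sample regardless of ``dt``.

    Parameters
    ----------
    on_duration, off_duration : float
        Laser-on and laser-off phase lengths, s.
    n_cycles : int
        Number of on/off cycles (>= 1).
    dt : float
        Sampling interval, s; must be < ``on_duration``.

    Returns
    -------
    ThermalTrace
        Sampled at ``0, dt, 2 dt, ...`` over all cycles, with
        ``metadata["cycles"]`` listing the (on, off) boundary times and
        ``laser_on_time``/``laser_off_time`` set to the first cycle's.
    """
    if on_duration <= 0 or off_duration <= 0:
        raise ValueError("on_duration and off_duration must be > 0")
    if n_cycles < 1:
        raise ValueError("n_cycles must be >= 1")
    if dt <= 0:
        raise ValueError("dt must be > 0")
    if dt >= on_duration:
        raise ValueError(
            f"dt ({dt} s) must be smaller than on_duration ({on_duration} s)"
        )

    tau = params.time_constant
    ss = steady_state_delta_t(params)
    total = n_cycles * (on_duration + off_duration)
    times = np.arange(0.0, total + dt / 2.0, dt)

    # Closed-form chaining: rise at the start of each phase.
    boundaries: list[tuple[float, float]] = []
    phase_starts: list[tuple[float, float, bool]] = []  # (t0, dT0, heating?)
    d0 = 0.0
    t0 = 0.0
    for _ in range(n_cycles):
        phase_starts.append((t0, d0, True))
        boundaries.append((t0, t0 + on_duration))
        d0 = ss + (d0 - ss) * np.exp(-on_duration / tau)
        t0 += on_duration
        phase_starts.append((t0, d0, False))
        d0 = d0 * np.exp(-off_duration / tau)
        t0 += off_duration

    delta = np.empty_like(times)
    starts = np.array([p[0] for p in phase_starts])
    idx = np.minimum(np.searchsorted(starts, times, side="right") - 1, len(starts) - 1)
    for i, (ts, d_start, heating) in enumerate(phase_starts):
        m = idx == i
        if not m.any():
            continue
        rel = times[m] - ts
        if heating:
            delta[m] = ss + (d_start - ss) * np.exp(-rel / tau)
        else:
            delta[m] = d_start * np.exp(-rel / tau)

    return ThermalTrace(
        times=times,
        temps=params.ambient_temp + delta,
        ambient_temp=params.ambient_temp,
        laser_on_time=0.0,
        laser_off_time=on_duration,
        metadata={
            "cycles": boundaries,
            "ground_truth": {
                "efficiency": params.efficiency,
                "time_constant_s": tau,
                "laser_power_W": params.laser_power,
                "absorbance": params.absorbance,
                "parasitic_power_W": params.parasitic_power,
                "heat_capacity_J_per_C": params.heat_capacity,
            },
        },
    )
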