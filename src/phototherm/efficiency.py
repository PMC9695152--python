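"""Photothermal conversion efficiency estimation from thermal traces.

The pipeline mirrors the standard energy-balance treatment of laser-heated
colloids:

1.  The cooling phase (laser off) is source-free, so the rise relaxes as
    ``theta(t) = exp(-t/tau)``; a weighted linear regression of ``ln theta``
    against time yields the time constant ``tau``.
2.  The lumped-capacitance closure links the two balance equations: at
    steady state the dissipated power ``hA * dT_max`` equals the absorbed
    power, and ``hA = sum(m_i C_i) / tau``.
3.  The steady-state rise ``dT_max`` is obtained by fitting the heating
    phase with ``dT(t) = dT_max * (1 - exp(-t/tau))`` (tau fixed from the
    cooling fit), matching the exponential fit applied to measured thermal
    curves; this extrapolates correctly even when heating is stopped before
    a full plateau.
4.  A water-only control trace calibrates the parasitic fraction
    ``zeta = hA * dT_max(water) / I`` absorbed by solvent and container.
5.  The efficiency follows from the energy balance

        eta = (hA * dT_max - I * zeta) / (I * (1 - zeta) * (1 - 10**(-A)))
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Sequence

import numpy as np

from .errors import CalibrationError, InsufficientDataError
from .lumped import HeatCapacityComponent, ThermalTrace, total_heat_capacity

__all__ = [
    "EfficiencyEstimate",
    "delta_t_max",
    "estimate_tau",
    "estimate_hA",
    "calibrate_zeta",
    "estimate_eta",
]

#: trailing samples averaged for the plateau estimate
STEADY_STATE_WINDOW = 3


@dataclass
class EfficiencyEstimate:
    """Fitted outputs of the efficiency pipeline.

    ``eta`` is reported unclipped; values outside [0, 1] set ``warning``
    rather than being silently truncated, preserving their diagnostic value.
    """

    eta: float  # photothermal conversion efficiency
    tau: float  # cooling time constant, s
    hA: float  # heat-transfer coefficient x area, W/degC
    delta_t_max: float  # steady-state rise, degC
    zeta: float  # parasitic absorbed fraction
    fit_r2: float  # r^2 of the cooling-phase regression
    residual_rms: float  # RMS residual of the heating-phase fit, degC
    warning: str | None = None

    def to_dict(self) -> dict:
        return asdict(self)


def _heating_samples(trace: ThermalTrace) -> tuple[np.ndarray, np.ndarray]:
    t, temps = trace.heating_slice()
    if t.size < 3:
        raise InsufficientDataError(
            f"need >= 3 heating-phase samples, found {t.size}"
        )
    return t, temps


def delta_t_max(trace: ThermalTrace) -> float:
    """Steady-state temperature rise above ambient, degC.

    Estimated as the mean of the last ``STEADY_STATE_WINDOW`` heating-phase
    samples minus the ambient temperature.  Assumes the heating phase was
    long enough to plateau; for short heating phases prefer the
    exponential extrapolation performed inside :func:`estimate_eta`.
    """
    _, temps = _heating_samples(trace)
    return float(np.mean(temps[-STEADY_STATE_WINDOW:]) - trace.ambient_temp)


def estimate_tau(trace: ThermalTrace) -> tuple[float, float]:
    """Cooling time constant from the laser-off phase.

    Linearizes the relaxation ``theta(t) = (T - T_amb)/(T_off - T_amb)`` and
    regresses ``ln theta`` on time with weights proportional to
    ``(T - T_amb)^2`` — the inverse variance of ``ln theta`` under additive
    camera noise, so late low-signal samples do not dominate the fit.
    Samples with ``theta <= 0`` are dropped.

    Returns
    -------
    (tau, r2) : tuple of float
        Time constant in seconds and the (weighted) coefficient of
        determination of the regression.

    Raises
    ------
    InsufficientDataError
        If the trace has no cooling phase, fewer than 3 usable cooling
        samples, no positive initial rise, or a non-decaying cooling phase.
    """
    if trace.laser_off_time is None:
        raise InsufficientDataError("trace has no cooling phase (laser_off_time unset)")
    t_cool, temps_cool = trace.cooling_slice()
    t_off = trace.laser_off_time
    temp_off = float(np.interp(t_off, trace.times, trace.temps))
    rise_off = temp_off - trace.ambient_temp
    if rise_off <= 0:
        raise InsufficientDataError("no positive temperature rise at laser-off")

    theta = (temps_cool - trace.ambient_temp) / rise_off
    keep = theta > 0
    t_rel = t_cool[keep] - t_off
    theta = theta[keep]
    if theta.size < 3:
        raise InsufficientDataError(
            f"need >= 3 positive cooling samples, found {theta.size}"
        )

    y = np.log(theta)
    w = theta**2  # inverse variance of ln(theta) for additive noise
    sw = w.sum()
    tbar = (w * t_rel).sum() / sw
    ybar = (w * y).sum() / sw
    cov_ty = (w * (t_rel - tbar) * (y - ybar)).sum()
    var_t = (w * (t_rel - tbar) ** 2).sum()
    var_y = (w * (y - ybar) ** 2).sum()
    if var_t == 0:
        raise InsufficientDataError("cooling samples are not spread in time")
    slope = cov_ty / var_t
    if slope >= 0:
        raise InsufficientDataError("cooling phase does not decay")
    r2 = 1.0 if var_y == 0 else float(cov_ty**2 / (var_t * var_y))
    return float(-1.0 / slope), r2


def estimate_hA(tau: float, components: Sequence[HeatCapacityComponent]) -> float:
    """Heat-transfer coefficient x area, ``hA = sum(m_i C_i) / tau`` (W/degC)."""
    if tau <= 0:
        raise ValueError("tau must be > 0")
    return total_heat_capacity(components) / tau


def calibrate_zeta(
    water_trace: ThermalTrace, hA: float, laser_power: float
) -> float:
    """Parasitic absorbed fraction from a water-only control trace.

    ``zeta = hA * dT_max(water) / I``: at the control's steady state the
    power dissipated equals the power the solvent and container absorb.
    The same quantity enters the forward model as ``Q0 = zeta * I``.
    """
    if laser_power <= 0:
        raise ValueError("laser_power must be > 0")
    zeta = hA * delta_t_max(water_trace) / laser_power
    if zeta >= 1.0:
        raise CalibrationError(
            f"zeta = {zeta:.3f} >= 1: water control heated more than the "
            "laser power allows"
        )
    return max(zeta, 0.0)


def _fit_heating_amplitude(
    trace: ThermalTrace, tau: float
) -> tuple[float, float]:
    """Least-squares steady-state rise with tau fixed.

    Fits ``dT(t) = a * (1 - exp(-(t - t_on)/tau))`` over the heating phase;
    the single linear parameter has the closed form
    ``a = sum(y f) / sum(f^2)``.  Returns (a, residual_rms).
    """
    t, temps = _heating_samples(trace)
    y = temps - trace.ambient_temp
    f = 1.0 - np.exp(-(t - trace.laser_on_time) / tau)
    denom = float(np.dot(f, f))
    if denom == 0:
        raise InsufficientDataError("heating phase has no usable samples")
    a = float(np.dot(y, f) / denom)
    rms = float(np.sqrt(np.mean((y - a * f) ** 2)))
    return a, rms


def estimate_eta(
    trace: ThermalTrace,
    laser_power: float,
    absorbance: float,
    components: Sequence[HeatCapacityComponent],
    water_trace: ThermalTrace | None = None,
) -> EfficiencyEstimate:
    """Full estimation pipeline for the photothermal conversion efficiency.

    Parameters
    ----------
    trace : ThermalTrace
        Heating + cooling record of the nanoparticle sample.
    laser_power : float
        Incident laser power I, W.
    absorbance : float
        Optical density of the sample at the excitation wavelength.
    components : sequence of HeatCapacityComponent
        Thermal-mass inventory entering ``sum(m_i C_i)``.
    water_trace : ThermalTrace, optional
        Water-only control under identical irradiation; calibrates the
        parasitic fraction ``zeta`` (``zeta = 0`` when absent).

    Returns
    -------
    EfficiencyEstimate
        With ``eta`` unclipped and ``warning`` set when it falls outside
        [0, 1].
    """
    if absorbance <= 0:
        raise ValueError("absorbance must be > 0")
    if laser_power <= 0:
        raise ValueError("laser_power must be > 0")

    tau, r2 = estimate_tau(trace)
    hA = estimate_hA(tau, components)
    zeta = 0.0
    if water_trace is not None:
        # Estimate the control's steady state the same way as the sample's:
        # from its own cooling tau and a fixed-tau amplitude fit.  Fall back
        # to the trailing-plateau estimate when the control has no cooling
        # phase.
        try:
            tau_w, _ = estimate_tau(water_trace)
            hA_w = estimate_hA(tau_w, components)
            dt_w, _ = _fit_heating_amplitude(water_trace, tau_w)
            zeta = hA_w * dt_w / laser_power
            if zeta >= 1.0:
                raise CalibrationError(
                    f"zeta = {zeta:.3f} >= 1: water control heated more than "
                    "the laser power allows"
                )
            zeta = max(zeta, 0.0)
        except InsufficientDataError:
            zeta = calibrate_zeta(water_trace, hA, laser_power)
    dt_ss, rms = _fit_heating_amplitude(trace, tau)

    absorbed_fraction = 1.0 - 10.0 ** (-absorbance)
    eta = (hA * dt_ss - laser_power * zeta) / (
        laser_power * (1.0 - zeta) * absorbed_fraction
    )
    warning = None
    if not 0.0 <= eta <= 1.0:
        warning = f"eta = {eta:.4f} outside [0, 1]; check calibration inputs"

    return EfficiencyEstimate(
        eta=eta,
        tau=tau,
        hA=hA,
        delta_t_max=dt_ss,
        zeta=zeta,
        fit_r2=r2,
        residual_rms=rms,
        warning=warning,
    )
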