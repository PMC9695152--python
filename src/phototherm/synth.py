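"""Synthetic instrument outputs with known ground truth.

Every generator emulates one instrument of the photothermal evaluation
workflow — the infrared camera watching a laser-heated vial, the UV-Vis-NIR
spectrophotometer, the thermal camera watching a phantom, and the microplate
reader — and embeds its ground-truth parameters in the output metadata so
estimators can be validated end to end.  All randomness is additive Gaussian
noise driven by an explicit seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .lumped import LumpedSystemParams, ThermalTrace, simulate_cycles
from .phantom import BeamSource, PhantomConfig, PhantomGrid, build_phantom, simulate_heating, stable_dt
from .spectra import SpectrumRecord
from .thermography import ThermogramStack
from .viability import MttPlate

__all__ = [
    "NoiseSpec",
    "generate_trace",
    "generate_spectrum",
    "generate_mtt_plate",
    "generate_stack",
]


@dataclass(frozen=True)
class NoiseSpec:
    """Additive Gaussian noise: standard deviation (degC or OD) and seed."""

    sigma: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def generate_trace(
    params: LumpedSystemParams,
    on_duration: float = 900.0,
    off_duration: float = 900.0,
    sample_interval: float = 60.0,
    noise: NoiseSpec = NoiseSpec(),
    n_cycles: int = 1,
) -> ThermalTrace:
    """Noisy thermal trace of a laser heating/cooling experiment.

    Defaults mirror the irradiation protocol the pipeline targets: 15 min
    laser on, 15 min off, one thermographic sample per minute.  With
    ``noise.sigma == 0`` the output is bitwise identical to
    :func:`~phototherm.lumped.simulate_cycles`.
    """
    if sample_interval <= 0:
        raise ValueError("sample_interval must be > 0")
    trace = simulate_cycles(
        params, on_duration, off_duration, n_cycles=n_cycles, dt=sample_interval
    )
    if noise.sigma > 0:
        trace.temps = trace.temps + noise.rng().normal(
            0.0, noise.sigma, size=trace.temps.shape
        )
    trace.metadata["noise_sigma_C"] = noise.sigma
    trace.metadata["noise_seed"] = noise.seed
    return trace


def generate_spectrum(
    modes: Sequence[tuple[float, float, float]],
    grid: tuple[float, float, float] = (400.0, 1100.0, 1.0),
    noise: NoiseSpec = NoiseSpec(),
    label: str = "",
) -> SpectrumRecord:
    """Sum-of-Lorentzians extinction spectrum.

    ``modes`` are (center_nm, fwhm_nm, height_od) triples; plasmon bands are
    homogeneously broadened, so each contributes
    ``h / (1 + ((wl - c) / (w/2))**2)`` and peaks at exactly ``h``.

    Raises
    ------
    ValueError
        If no mode is given or a mode centre lies off the wavelength grid.
    """
    if not modes:
        raise ValueError("at least one spectral mode is required")
    lo, hi, step = grid
    wl = np.arange(lo, hi + step / 2, step)
    ext = np.zeros_like(wl)
    for center, width, height in modes:
        if not lo <= center <= hi:
            raise ValueError(f"mode centre {center} nm outside grid [{lo}, {hi}] nm")
        if width <= 0 or height < 0:
            raise ValueError("mode width must be > 0 and height >= 0")
        ext += height / (1.0 + ((wl - center) / (width / 2.0)) ** 2)
    if noise.sigma > 0:
        ext = ext + noise.rng().normal(0.0, noise.sigma, size=ext.shape)
    rec = SpectrumRecord(wavelengths=wl, extinction=ext, label=label)
    return rec


def generate_mtt_plate(
    group_effects: Mapping[str, float],
    replicates: int = 3,
    control_od: float = 1.0,
    noise_cv: float = 0.0,
    seed: int | None = None,
    control_group: str = "untreated",
    irradiated_effects: Mapping[str, float] | None = None,
    od670: float = 0.04,
) -> MttPlate:
    """Synthetic MTT plate with group-level true viability fractions.

    ``group_effects`` maps each non-irradiated group to its true viability
    fraction (the control must be present with effect 1.0);
    ``irradiated_effects`` optionally adds post-irradiation arms.  Each
    well's net OD is ``control_od * effect * (1 + eps)`` with
    ``eps ~ N(0, noise_cv)``; the 670 nm reference reading is a fixed small
    constant.
    """
    if control_group not in group_effects or group_effects[control_group] != 1.0:
        raise ValueError(
            f"control group {control_group!r} must be present with effect 1.0"
        )
    if replicates < 3:
        raise ValueError("need >= 3 replicate wells per group")
    rng = np.random.default_rng(seed)
    rows = []
    well = 0

    def add(group: str, effect: float, irradiated: bool) -> None:
        nonlocal well
        if effect < 0:
            raise ValueError(f"group {group!r} effect must be >= 0")
        for _ in range(replicates):
            eps = rng.normal(0.0, noise_cv) if noise_cv > 0 else 0.0
            net = control_od * effect * (1.0 + eps)
            rows.append(
                {
                    "well": f"W{well:03d}",
                    "group": group,
                    "od570": max(net, 0.0) + od670,
                    "od670": od670,
                    "irradiated": irradiated,
                }
            )
            well += 1

    for group, effect in group_effects.items():
        add(group, effect, False)
    for group, effect in (irradiated_effects or {}).items():
        add(group, effect, True)
    return MttPlate(pd.DataFrame(rows))


def generate_stack(
    config: PhantomConfig | dict | None = None,
    beam: BeamSource | None = None,
    duration: float = 300.0,
    frame_interval: float = 60.0,
    laser_off_at: float | None = None,
    noise: NoiseSpec = NoiseSpec(),
    dt: float | None = None,
) -> tuple[ThermogramStack, PhantomGrid]:
    """Phantom thermogram stack from the finite-difference simulator.

    Convenience wrapper: builds the phantom, centres a 1.5 mm-radius beam on
    the inclusion when none is given, picks a stable time step, and runs the
    simulation with seeded camera noise.  Returns (stack, grid).
    """
    grid = build_phantom(config)
    if beam is None:
        rows, cols = np.nonzero(grid.inclusion_mask)
        beam = BeamSource(
            center=(float(rows.mean()), float(cols.mean())),
            radius=1.5e-3,
            power=0.196,
            absorbed_fraction=1.0 - 10.0**-0.56,
            efficiency=0.8,
        )
    if dt is None:
        dt = 0.8 * stable_dt(grid)
    stack = simulate_heating(
        grid,
        beam,
        duration=duration,
        dt=dt,
        frame_interval=frame_interval,
        laser_off_at=laser_off_at,
        noise_sigma=noise.sigma,
        seed=noise.seed,
    )
    return stack, grid
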