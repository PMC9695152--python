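"""Finite-difference heat diffusion in a layered skin-mimicking phantom.

The phantom is a 2-D cross-section (unit depth) of an agarose skin model:
an epidermal band on top of a thicker dermal band, with a narrow
nanoparticle-doped inclusion ("tumor") punched into the epidermal band.  A
NIR laser beam deposits power only in the inclusion — the optics of the
scattering layers are collapsed into the absorbed fraction — and heat
spreads by conduction:

    rho_c * dT/dt = div(k grad T) + S

solved with an explicit forward-time central-space (FTCS) scheme in flux
form (harmonic-mean face conductivities), which conserves energy discretely
and is guarded by the hard stability bound
``dt <= dx^2 * min(rho_c) / (4 * max(k))``.

Agarose hydrogels are mostly water, so layers default to water-like thermal
properties (k = 0.6 W m^-1 degC^-1, rho_c = 4.18e6 J m^-3 degC^-1).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, NamedTuple

import numpy as np

from .errors import ConfigError, StabilityError
from .thermography import ThermogramStack

__all__ = [
    "Boundary",
    "PhantomConfig",
    "PhantomGrid",
    "BeamSource",
    "EnergyAudit",
    "WATER_LIKE",
    "build_phantom",
    "stable_dt",
    "simulate_heating",
    "energy_audit",
    "tune_power_for_hotspot",
]

#: thermal properties of water-dominated hydrogel
WATER_LIKE = {"conductivity": 0.6, "rho_c": 4.18e6}  # W/m/degC, J/m^3/degC


@dataclass(frozen=True)
class Boundary:
    """Edge condition: perfectly insulated or convective exchange.

    ``kind`` is ``"insulated"`` or ``"convective"``; a convective boundary
    exchanges ``h * (T - T_ext)`` W/m^2 across every domain edge.
    """

    kind: str = "insulated"
    h: float = 0.0  # W m^-2 degC^-1
    T_ext: float = 25.0  # degC

    def __post_init__(self) -> None:
        if self.kind not in ("insulated", "convective"):
            raise ConfigError(f"unknown boundary kind {self.kind!r}")
        if self.kind == "convective" and self.h <= 0:
            raise ConfigError("convective boundary requires h > 0")


@dataclass
class PhantomConfig:
    """Geometry and material configuration of the layered phantom.

    Physical extents are given in millimetres; cell counts follow from
    ``dx_mm``, so refining the grid leaves the geometry unchanged.
    """

    dx_mm: float = 0.25
    width_mm: float = 24.0
    depth_mm: float = 16.0
    epidermal_mm: float = 4.0
    dermal_mm: float = 8.0
    inclusion_width_mm: float = 1.25
    inclusion_depth_mm: float = 4.0
    initial_temp_C: float = 25.0
    boundary: Boundary = field(default_factory=Boundary)
    materials: dict[str, dict[str, float]] = field(
        default_factory=lambda: {
            "epidermal": dict(WATER_LIKE),
            "dermal": dict(WATER_LIKE),
            "inclusion": dict(WATER_LIKE),
        }
    )

    @classmethod
    def from_dict(cls, cfg: dict[str, Any]) -> "PhantomConfig":
        """Build from a nested mapping (e.g. parsed YAML)."""
        kw: dict[str, Any] = {}
        grid = cfg.get("grid", {})
        for key in ("dx_mm", "width_mm", "depth_mm"):
            if key in grid:
                kw[key] = float(grid[key])
        layers = cfg.get("layers", {})
        if "epidermal_mm" in layers:
            kw["epidermal_mm"] = float(layers["epidermal_mm"])
        if "dermal_mm" in layers:
            kw["dermal_mm"] = float(layers["dermal_mm"])
        inc = cfg.get("inclusion", {})
        if "width_mm" in inc:
            kw["inclusion_width_mm"] = float(inc["width_mm"])
        if "depth_mm" in inc:
            kw["inclusion_depth_mm"] = float(inc["depth_mm"])
        if "initial_temp_C" in cfg:
            kw["initial_temp_C"] = float(cfg["initial_temp_C"])
        bnd = cfg.get("boundary")
        if bnd:
            kw["boundary"] = Boundary(
                kind=bnd.get("kind", "insulated"),
                h=float(bnd.get("h_W_m2C", 0.0)),
                T_ext=float(bnd.get("T_ext_C", 25.0)),
            )
        if "materials" in cfg:
            kw["materials"] = cfg["materials"]
        return cls(**kw)


@dataclass
class PhantomGrid:
    """Discretised phantom: material labels, thermal fields, temperatures.

    Arrays are (ny, nx) with row 0 at the irradiated (epidermal) surface.
    """

    dx: float  # m per cell
    material_map: np.ndarray  # str labels
    rho_c: np.ndarray  # J m^-3 degC^-1
    conductivity: np.ndarray  # W m^-1 degC^-1
    temps: np.ndarray  # degC
    boundary: Boundary = field(default_factory=Boundary)

    def __post_init__(self) -> None:
        for name in ("rho_c", "conductivity", "temps"):
            arr = np.asarray(getattr(self, name), dtype=float)
            setattr(self, name, arr)
            if arr.shape != self.material_map.shape:
                raise ConfigError(f"{name} shape must match material_map")
        if not (self.rho_c > 0).all() or not (self.conductivity > 0).all():
            raise ConfigError("rho_c and conductivity must be positive everywhere")

    @property
    def shape(self) -> tuple[int, int]:
        return self.material_map.shape

    @property
    def ny(self) -> int:
        return self.material_map.shape[0]

    @property
    def nx(self) -> int:
        return self.material_map.shape[1]

    @property
    def inclusion_mask(self) -> np.ndarray:
        return self.material_map == "inclusion"


@dataclass(frozen=True)
class BeamSource:
    """Gaussian laser beam heating the inclusion.

    ``center`` is (row, col) in grid coordinates; ``radius`` the 1/e^2
    Gaussian radius in metres; the deposited power is
    ``power * absorbed_fraction * efficiency`` watts (per unit depth),
    distributed over inclusion cells with the beam's Gaussian weight.
    """

    center: tuple[float, float]
    radius: float  # m
    power: float  # W
    absorbed_fraction: float  # 1 - 10^(-A) of the inclusion
    efficiency: float = 1.0

    def __post_init__(self) -> None:
        if not self.radius > 0:
            raise ConfigError("beam radius must be > 0")
        if not 0.0 <= self.absorbed_fraction <= 1.0:
            raise ConfigError("absorbed_fraction must lie in [0, 1]")
        if self.power < 0:
            raise ConfigError("power must be >= 0")

    @property
    def deposited_power(self) -> float:
        return self.power * self.absorbed_fraction * self.efficiency


class EnergyAudit(NamedTuple):
    """Joules (per unit depth) put in, stored, and lost through the boundary."""

    input_J: float
    stored_J: float
    boundary_loss_J: float


def build_phantom(config: PhantomConfig | dict[str, Any] | None = None) -> PhantomGrid:
    """Construct the layered phantom grid from a configuration.

    The epidermal band occupies the top ``epidermal_mm`` of the domain, the
    dermal band the next ``dermal_mm``; any remaining depth is dermal
    backing.  The inclusion is a centred vertical puncture of
    ``inclusion_width_mm`` starting at the surface.
    """
    if config is None:
        config = PhantomConfig()
    elif isinstance(config, dict):
        config = PhantomConfig.from_dict(config)

    dx_mm = config.dx_mm
    if dx_mm <= 0:
        raise ConfigError("dx_mm must be > 0")
    nx = round(config.width_mm / dx_mm)
    ny = round(config.depth_mm / dx_mm)
    n_epi = round(config.epidermal_mm / dx_mm)
    n_derm = round(config.dermal_mm / dx_mm)
    if n_epi + n_derm > ny:
        raise ConfigError("epidermal + dermal bands exceed the domain depth")
    n_inc_w = round(config.inclusion_width_mm / dx_mm)
    n_inc_d = round(config.inclusion_depth_mm / dx_mm)
    if n_inc_w < 1 or config.inclusion_width_mm <= 0:
        raise ConfigError("inclusion width must be at least one cell")
    if config.inclusion_depth_mm > config.epidermal_mm:
        raise ConfigError(
            "inclusion deeper than the epidermal layer "
            f"({config.inclusion_depth_mm} > {config.epidermal_mm} mm)"
        )
    if n_inc_w >= nx:
        raise ConfigError("inclusion wider than the domain")

    material = np.full((ny, nx), "dermal", dtype="<U10")
    material[:n_epi, :] = "epidermal"
    c0 = (nx - n_inc_w) // 2
    material[: max(n_inc_d, 1), c0 : c0 + n_inc_w] = "inclusion"

    rho_c = np.empty((ny, nx))
    cond = np.empty((ny, nx))
    for label in ("epidermal", "dermal", "inclusion"):
        props = config.materials.get(label, WATER_LIKE)
        m = material == label
        rho_c[m] = props["rho_c"]
        cond[m] = props["conductivity"]

    temps = np.full((ny, nx), config.initial_temp_C, dtype=float)
    return PhantomGrid(
        dx=dx_mm * 1e-3,
        material_map=material,
        rho_c=rho_c,
        conductivity=cond,
        temps=temps,
        boundary=config.boundary,
    )


def stable_dt(grid: PhantomGrid) -> float:
    """Largest stable explicit time step, ``dx^2 min(rho_c) / (4 max(k))``."""
    return grid.dx**2 * float(grid.rho_c.min()) / (4.0 * float(grid.conductivity.max()))


def _source_field(grid: PhantomGrid, beam: BeamSource) -> np.ndarray:
    """Volumetric source S (W/m^3, unit depth) on inclusion cells only."""
    mask = grid.inclusion_mask
    if beam.deposited_power == 0:
        return np.zeros(grid.shape)
    if not mask.any():
        raise ConfigError("beam has power but the grid has no inclusion cells")
    rows, cols = np.mgrid[0 : grid.ny, 0 : grid.nx]
    r2 = ((rows - beam.center[0]) ** 2 + (cols - beam.center[1]) ** 2) * grid.dx**2
    w = np.where(mask, np.exp(-2.0 * r2 / beam.radius**2), 0.0)
    total = w.sum() * grid.dx**2
    return w / total * beam.deposited_power


def simulate_heating(
    grid: PhantomGrid,
    beam: BeamSource,
    duration: float,
    dt: float,
    frame_interval: float,
    laser_off_at: float | None = None,
    noise_sigma: float = 0.0,
    seed: int | None = None,
) -> ThermogramStack:
    """Run the explicit FTCS simulation and emit a thermogram stack.

    Frames (with additive Gaussian camera noise of ``noise_sigma`` degC)
    are emitted every ``frame_interval`` seconds, starting with the initial
    state at t = 0.  The laser source is active until ``laser_off_at``
    (or for the whole run when ``None``).  The returned stack carries the
    noise-free energy bookkeeping retrievable via :func:`energy_audit`.

    Raises
    ------
    StabilityError
        If ``dt`` exceeds the explicit stability bound; the message reports
        the computed bound.
    """
    bound = stable_dt(grid)
    if dt > bound:
        raise StabilityError(
            f"dt = {dt:g} s exceeds the explicit stability bound {bound:g} s"
        )
    if dt <= 0 or duration <= 0:
        raise ValueError("dt and duration must be > 0")
    if frame_interval < dt:
        raise ValueError("frame_interval must be >= dt")

    rng = np.random.default_rng(seed)
    dx = grid.dx
    T = grid.temps.astype(float).copy()
    T0 = T.copy()
    S = _source_field(grid, beam)
    cell_area = dx * dx

    k = grid.conductivity
    # harmonic-mean conductivity at interior faces
    k_e = 2.0 * k[:, 1:] * k[:, :-1] / (k[:, 1:] + k[:, :-1])  # vertical faces
    k_s = 2.0 * k[1:, :] * k[:-1, :] / (k[1:, :] + k[:-1, :])  # horizontal faces

    convective = grid.boundary.kind == "convective"
    h = grid.boundary.h
    T_ext = grid.boundary.T_ext
    edge = np.zeros(grid.shape)
    if convective:
        edge[0, :] += 1.0
        edge[-1, :] += 1.0
        edge[:, 0] += 1.0
        edge[:, -1] += 1.0  # corners exchange across two faces

    n_steps = int(round(duration / dt))
    steps_per_frame = max(int(round(frame_interval / dt)), 1)

    def emit(t_now: float) -> np.ndarray:
        frame = T.copy()
        if noise_sigma > 0:
            frame = frame + rng.normal(0.0, noise_sigma, size=frame.shape)
        return frame

    frames = [emit(0.0)]
    timestamps = [0.0]
    input_J = 0.0
    loss_J = 0.0
    source_power = S.sum() * cell_area  # W per unit depth

    for step in range(1, n_steps + 1):
        t_prev = (step - 1) * dt
        on = laser_off_at is None or t_prev < laser_off_at
        div = np.zeros_like(T)
        fx = k_e * (T[:, 1:] - T[:, :-1])  # W/m per unit depth across face / dx
        div[:, :-1] += fx
        div[:, 1:] -= fx
        fy = k_s * (T[1:, :] - T[:-1, :])
        div[:-1, :] += fy
        div[1:, :] -= fy
        div /= dx * dx  # -> W/m^3

        rate = div / grid.rho_c
        if on:
            rate = rate + S / grid.rho_c
            input_J += source_power * dt
        if convective:
            q = h * edge * (T - T_ext) / dx  # W/m^3
            rate = rate - q / grid.rho_c
            loss_J += float(q.sum()) * cell_area * dt
        T = T + dt * rate

        if step % steps_per_frame == 0 or step == n_steps:
            t_now = step * dt
            if not timestamps or t_now > timestamps[-1]:
                frames.append(emit(t_now))
                timestamps.append(t_now)

    stored_J = float((grid.rho_c * (T - T0)).sum()) * cell_area
    audit = EnergyAudit(input_J=input_J, stored_J=stored_J, boundary_loss_J=loss_J)

    return ThermogramStack(
        frames=np.array(frames),
        timestamps=np.array(timestamps),
        pixel_pitch_mm=dx * 1e3,
        ambient_temp=float(T0.mean()),
        metadata={
            "laser_on_s": 0.0,
            "laser_off_s": laser_off_at,
            "energy_audit": audit._asdict(),
            "final_field": T,
            "noise_sigma_C": noise_sigma,
        },
    )


def energy_audit(stack: ThermogramStack) -> EnergyAudit:
    """Energy bookkeeping of a simulation run: input = stored + loss."""
    try:
        d = stack.metadata["energy_audit"]
    except KeyError as exc:
        raise ValueError("stack carries no energy audit (not a simulation?)") from exc
    return EnergyAudit(**d)


def tune_power_for_hotspot(
    grid: PhantomGrid,
    beam: BeamSource,
    target_rise: float,
    at_time: float,
    dt: float,
) -> float:
    """Beam power giving a ``target_rise`` degC inclusion hotspot at ``at_time``.

    The conduction problem is linear in the source, so one unit-power run
    suffices: the required power is ``target_rise / rise_per_watt``.
    """
    probe = BeamSource(
        center=beam.center,
        radius=beam.radius,
        power=1.0,
        absorbed_fraction=beam.absorbed_fraction,
        efficiency=beam.efficiency,
    )
    stack = simulate_heating(
        grid, probe, duration=at_time, dt=dt, frame_interval=at_time, noise_sigma=0.0
    )
    final = stack.metadata["final_field"]
    rise = float((final - grid.temps)[grid.inclusion_mask].max())
    if rise <= 0:
        raise ConfigError("unit-power run produced no inclusion heating")
    return target_rise / rise
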