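"""Finite-difference phantom simulator: geometry, conservation, accuracy."""

import numpy as np
import pytest
from scipy.ndimage import distance_transform_edt

import phototherm as pt
from phototherm.phantom import (
    BeamSource,
    Boundary,
    PhantomConfig,
    build_phantom,
    energy_audit,
    simulate_heating,
    stable_dt,
)

WATER_ALPHA = 0.6 / 4.18e6  # m^2/s


def centered_beam(grid, power=0.1, radius=1.5e-3, efficiency=0.8):
    rows, cols = np.nonzero(grid.inclusion_mask)
    return BeamSource(
        center=(float(rows.mean()), float(cols.mean())),
        radius=radius,
        power=power,
        absorbed_fraction=1.0 - 10.0**-0.56,
        efficiency=efficiency,
    )


class TestGeometry:
    def test_default_inclusion_spans_five_cells(self):
        grid = build_phantom()
        inc_cols = np.unique(np.nonzero(grid.inclusion_mask)[1])
        assert inc_cols.size == 5  # 1.25 mm at 0.25 mm/cell
        # epidermal band is 4 mm deep, dermal band below it
        assert (grid.material_map[0, 0] == "epidermal")
        assert (grid.material_map[16, 0] == "dermal")

    def test_refining_grid_preserves_physical_extents(self):
        coarse = build_phantom(PhantomConfig(dx_mm=0.5))
        fine = build_phantom(PhantomConfig(dx_mm=0.25))
        assert fine.nx == 2 * coarse.nx and fine.ny == 2 * coarse.ny
        assert fine.nx * fine.dx == pytest.approx(coarse.nx * coarse.dx)
        n_inc_coarse = np.unique(np.nonzero(coarse.inclusion_mask)[1]).size
        n_inc_fine = np.unique(np.nonzero(fine.inclusion_mask)[1]).size
        assert n_inc_fine in (2 * n_inc_coarse, 2 * n_inc_coarse + 1)

    def test_zero_width_inclusion_rejected(self):
        with pytest.raises(pt.ConfigError):
            build_phantom(PhantomConfig(inclusion_width_mm=0.0))

    def test_inclusion_deeper_than_epidermis_rejected(self):
        with pytest.raises(pt.ConfigError):
            build_phantom(PhantomConfig(inclusion_depth_mm=6.0, epidermal_mm=4.0))

    def test_inclusion_is_one_connected_component(self):
        from scipy.ndimage import label

        grid = build_phantom()
        _, n = label(grid.inclusion_mask)
        assert n == 1


class TestStepping:
    def test_zero_power_field_constant(self):
        grid = build_phantom(PhantomConfig(dx_mm=0.5, width_mm=8, depth_mm=6,
                                           dermal_mm=2))
        beam = centered_beam(grid, power=0.0)
        stack = simulate_heating(grid, beam, 10.0, 0.8 * stable_dt(grid), 5.0)
        assert np.allclose(stack.frames, grid.temps[None], atol=1e-12)

    def test_unstable_dt_rejected_with_bound(self):
        grid = build_phantom()
        beam = centered_beam(grid)
        bound = stable_dt(grid)
        with pytest.raises(pt.StabilityError, match="bound"):
            simulate_heating(grid, beam, 10.0, 2 * bound, 5.0)

    def test_mean_temperature_rises_at_energy_rate(self):
        """Insulated domain: spatial mean rises as P_dep / sum(rho_c dx^2)."""
        grid = build_phantom(PhantomConfig(dx_mm=0.5, width_mm=8, depth_mm=6,
                                           dermal_mm=2))
        beam = centered_beam(grid, power=0.5)
        t_end = 30.0
        stack = simulate_heating(grid, beam, t_end, 0.8 * stable_dt(grid), t_end)
        t_act = stack.timestamps[-1]
        mean_rise = (stack.metadata["final_field"] - grid.temps).mean()
        total_capacity = (grid.rho_c * grid.dx**2).sum()
        expected = beam.deposited_power * t_act / total_capacity
        assert mean_rise == pytest.approx(expected, rel=1e-9)

    def test_discrete_maximum_principle_source_free(self):
        grid = build_phantom(PhantomConfig(dx_mm=0.5, width_mm=8, depth_mm=6,
                                           dermal_mm=2))
        rng = np.random.default_rng(3)
        grid.temps = 25.0 + rng.uniform(0, 10, size=grid.shape)
        lo, hi = grid.temps.min(), grid.temps.max()
        beam = centered_beam(grid, power=0.0)
        stack = simulate_heating(grid, beam, 20.0, 0.8 * stable_dt(grid), 20.0)
        final = stack.metadata["final_field"]
        assert final.max() <= hi + 1e-9 and final.min() >= lo - 1e-9

    def test_source_free_energy_conserved(self):
        grid = build_phantom(PhantomConfig(dx_mm=0.5, width_mm=8, depth_mm=6,
                                           dermal_mm=2))
        rng = np.random.default_rng(5)
        grid.temps = 25.0 + rng.uniform(0, 10, size=grid.shape)
        before = (grid.rho_c * grid.temps * grid.dx**2).sum()
        beam = centered_beam(grid, power=0.0)
        stack = simulate_heating(grid, beam, 20.0, 0.8 * stable_dt(grid), 20.0)
        after = (grid.rho_c * stack.metadata["final_field"] * grid.dx**2).sum()
        assert abs(after - before) / before < 1e-6

    def test_matches_heat_kernel_within_2pct_rms(self):
        """A Gaussian temperature pulse spreads per the 2-D heat kernel:
        sigma^2(t) = sigma0^2 + 2 alpha t, amplitude scaled to conserve
        energy.  FD solution agrees within 2% RMS of the peak."""
        cfg = PhantomConfig(dx_mm=0.25, width_mm=16, depth_mm=16)
        grid = build_phantom(cfg)
        sig0 = 1.0e-3
        amp = 10.0
        yy, xx = np.mgrid[0 : grid.ny, 0 : grid.nx]
        cy, cx = (grid.ny - 1) / 2, (grid.nx - 1) / 2
        r2 = ((yy - cy) ** 2 + (xx - cx) ** 2) * grid.dx**2
        grid.temps = 25.0 + amp * np.exp(-r2 / (2 * sig0**2))
        beam = centered_beam(grid, power=0.0)
        t_end = 30.0
        stack = simulate_heating(grid, beam, t_end, 0.8 * stable_dt(grid), t_end)
        t_act = stack.timestamps[-1]
        s2 = sig0**2 + 2 * WATER_ALPHA * t_act
        exact = 25.0 + amp * sig0**2 / s2 * np.exp(-r2 / (2 * s2))
        peak = amp * sig0**2 / s2
        rms = np.sqrt(np.mean((stack.metadata["final_field"] - exact) ** 2))
        assert rms / peak < 0.02

    def test_heating_stays_local_before_diffusion_time(self):
        """A cell 2 mm from the inclusion rises < 10% of the inclusion rise
        at a quarter of the diffusion time (2 mm)^2 / alpha."""
        grid = build_phantom()
        beam = centered_beam(grid)
        t_diff = (2e-3) ** 2 / WATER_ALPHA
        stack = simulate_heating(
            grid, beam, 0.25 * t_diff, 0.8 * stable_dt(grid), 0.25 * t_diff
        )
        rise = stack.metadata["final_field"] - grid.temps
        dist = distance_transform_edt(~grid.inclusion_mask) * grid.dx
        assert rise[dist >= 2e-3].max() < 0.10 * rise[grid.inclusion_mask].max()


class TestEnergyAudit:
    def test_idle_insulated_run_moves_no_energy(self):
        grid = build_phantom(PhantomConfig(dx_mm=0.5, width_mm=8, depth_mm=6,
                                           dermal_mm=2))
        beam = centered_beam(grid, power=0.0)
        stack = simulate_heating(grid, beam, 10.0, 0.8 * stable_dt(grid), 10.0)
        audit = energy_audit(stack)
        assert audit.input_J == 0.0
        assert abs(audit.stored_J) < 1e-9
        assert audit.boundary_loss_J == 0.0

    def test_insulated_source_input_equals_stored(self):
        grid = build_phantom(PhantomConfig(dx_mm=0.5, width_mm=8, depth_mm=6,
                                           dermal_mm=2))
        beam = centered_beam(grid, power=0.3)
        stack = simulate_heating(grid, beam, 60.0, 0.8 * stable_dt(grid), 60.0)
        audit = energy_audit(stack)
        assert audit.input_J > 0
        assert audit.stored_J == pytest.approx(audit.input_J, rel=0.01)

    def test_convective_balance_and_loss_growth(self):
        cfg = PhantomConfig(
            dx_mm=0.5, width_mm=8, depth_mm=6, dermal_mm=2,
            boundary=Boundary("convective", h=50.0, T_ext=25.0),
        )
        grid = build_phantom(cfg)
        beam = centered_beam(grid, power=0.3)
        short = energy_audit(
            simulate_heating(grid, beam, 30.0, 0.8 * stable_dt(grid), 30.0)
        )
        grid2 = build_phantom(cfg)
        long = energy_audit(
            simulate_heating(grid2, beam, 120.0, 0.8 * stable_dt(grid2), 120.0)
        )
        for audit in (short, long):
            assert audit.input_J == pytest.approx(
                audit.stored_J + audit.boundary_loss_J, rel=0.01
            )
        assert long.boundary_loss_J > short.boundary_loss_J
        # losses claim a growing share as the surface warms
        assert (long.boundary_loss_J / long.input_J) > (
            short.boundary_loss_J / short.input_J
        )


class TestPowerTuning:
    def test_linearity_based_power_tuning(self):
        grid = build_phantom(PhantomConfig(dx_mm=0.5, width_mm=8, depth_mm=6,
                                           dermal_mm=2))
        beam = centered_beam(grid, power=1.0)
        dt = 0.8 * stable_dt(grid)
        power = pt.tune_power_for_hotspot(grid, beam, target_rise=5.0, at_time=30.0, dt=dt)
        tuned = BeamSource(beam.center, beam.radius, power,
                           beam.absorbed_fraction, beam.efficiency)
        stack = simulate_heating(grid, tuned, 30.0, dt, 30.0)
        rise = stack.metadata["final_field"] - grid.temps
        assert rise[grid.inclusion_mask].max() == pytest.approx(5.0, rel=1e-6)
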