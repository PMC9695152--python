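"""Efficiency estimation pipeline: exact identities, noise robustness,
round-trip recovery against the forward model."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import phototherm as pt
from phototherm.efficiency import (
    calibrate_zeta,
    delta_t_max,
    estimate_eta,
    estimate_hA,
    estimate_tau,
)
from conftest import make_cooling_trace, LASER_POWER_W, ABSORBANCE

WATER = (pt.HeatCapacityComponent("water", 1.0, 4.184),)


class TestDeltaTMax:
    def test_constant_trace_gives_zero(self):
        tr = pt.ThermalTrace(np.arange(0, 300, 60.0), np.full(5, 25.0), 25.0)
        assert delta_t_max(tr) == 0.0

    def test_recovers_22C_plateau_sampled_to_10tau(self, params_factory):
        """A rise of 22 degC (the in-resonance sample's) sampled to 10 tau."""
        p = params_factory(efficiency=0.8)
        scale = 22.0 / pt.steady_state_delta_t(p)
        comp = (pt.HeatCapacityComponent("water", 1.0 / scale, 4.184),)
        p = params_factory(components=comp)
        assert pt.steady_state_delta_t(p) == pytest.approx(22.0)
        tr = pt.simulate_cycles(p, 10 * p.time_constant, 900, dt=60)
        assert delta_t_max(tr) == pytest.approx(22.0, abs=0.01)

    def test_two_samples_insufficient(self):
        tr = pt.ThermalTrace([0.0, 60.0], [25.0, 26.0], 25.0)
        with pytest.raises(pt.InsufficientDataError):
            delta_t_max(tr)


class TestEstimateTau:
    def test_exact_on_noiseless_exponential(self):
        tr = make_cooling_trace(tau=100.0)
        tau, r2 = estimate_tau(tr)
        assert tau == pytest.approx(100.0, rel=1e-12)
        assert r2 == pytest.approx(1.0, abs=1e-12)

    def test_within_5pct_under_camera_noise(self):
        """sigma = 0.1 degC on a 20 degC decay; cross-checked against an
        independent nonlinear least-squares fit (lmfit)."""
        lmfit = pytest.importorskip("lmfit")
        tr = make_cooling_trace(tau=100.0, rise=20.0, noise_sigma=0.1, seed=0)
        tau, _ = estimate_tau(tr)
        assert tau == pytest.approx(100.0, rel=0.05)

        t_cool, temps_cool = tr.cooling_slice()
        model = lmfit.Model(
            lambda t, amp, tau_: tr.ambient_temp + amp * np.exp(-t / tau_)
        )
        fit = model.fit(temps_cool, t=t_cool - tr.laser_off_time, amp=20.0, tau_=150.0)
        assert tau == pytest.approx(fit.params["tau_"].value, rel=0.02)

    def test_no_cooling_phase_rejected(self):
        tr = pt.ThermalTrace(np.arange(0, 300, 60.0), np.full(5, 30.0), 25.0)
        with pytest.raises(pt.InsufficientDataError):
            estimate_tau(tr)

    def test_nonpositive_theta_samples_dropped(self):
        times = np.arange(0.0, 600.0, 60.0)
        temps = 25.0 + 20.0 * np.exp(-np.maximum(times - 120.0, 0) / 60.0)
        temps[-3:] = 24.0  # below ambient: dropped, still >= 3 usable left
        tr = pt.ThermalTrace(times, temps, 25.0, 0.0, 120.0)
        tau, _ = estimate_tau(tr)
        assert tau == pytest.approx(60.0, rel=1e-9)


class TestHaAndZeta:
    def test_hA_exact_division(self, water_only):
        assert estimate_hA(300.0, water_only) == pytest.approx(0.01394666667)

    def test_hA_scaling(self, water_only):
        assert estimate_hA(600.0, water_only) == estimate_hA(300.0, water_only) / 2
        one = (pt.HeatCapacityComponent("unit", 1.0, 1.0),)
        assert estimate_hA(1.0, one) == 1.0

    def test_zeta_zero_for_unheated_water(self):
        tr = pt.ThermalTrace(np.arange(0, 300, 60.0), np.full(5, 25.0), 25.0)
        assert calibrate_zeta(tr, 0.013947, LASER_POWER_W) == 0.0

    def test_zeta_reference_value(self):
        tr = make_cooling_trace(rise=1.0, tau=100.0)
        zeta = calibrate_zeta(tr, 0.013947, LASER_POWER_W)
        assert zeta == pytest.approx(0.013947 / 0.196, rel=1e-9)  # ~0.0712

    def test_impossible_calibration_rejected(self):
        tr = make_cooling_trace(rise=1.0)
        with pytest.raises(pt.CalibrationError):
            calibrate_zeta(tr, 1.0, 0.5)


class TestEstimateEta:
    def test_perfect_converter_round_trip(self, params_factory, water_only):
        tr = pt.generate_trace(params_factory(efficiency=1.0))
        est = estimate_eta(tr, LASER_POWER_W, ABSORBANCE, water_only)
        assert est.eta == pytest.approx(1.0, abs=1e-9)

    def test_parasitic_only_sample_gives_zero(self, params_factory, water_only):
        """Sample identical to the water control: all heating is parasitic."""
        p = params_factory(efficiency=0.0, parasitic_power=0.01)
        tr = pt.generate_trace(p)
        water = pt.generate_trace(p)
        est = estimate_eta(tr, LASER_POWER_W, ABSORBANCE, water_only, water_trace=water)
        assert est.eta == pytest.approx(0.0, abs=1e-6)
        assert 0 < est.zeta < 1

    @given(
        eta=st.floats(0.1, 0.9),
        tau=st.floats(60.0, 600.0),
    )
    @settings(deadline=None, max_examples=40, derandomize=True)
    def test_noiseless_round_trip_recovery(self, eta, tau):
        p = pt.LumpedSystemParams(
            laser_power=LASER_POWER_W, absorbance=ABSORBANCE, efficiency=eta,
            time_constant=tau, components=WATER,
        )
        tr = pt.generate_trace(p)
        est = estimate_eta(tr, LASER_POWER_W, ABSORBANCE, WATER)
        assert est.eta == pytest.approx(eta, abs=1e-3)
        assert est.tau == pytest.approx(tau, rel=1e-6)

    def test_unbiased_under_camera_noise(self, params_factory, water_only):
        """1 sample/min, 15-min phases, sigma = 0.2 degC, 200 replicates."""
        p = params_factory(efficiency=0.8)
        etas = [
            estimate_eta(
                pt.generate_trace(p, noise=pt.NoiseSpec(0.2, seed)),
                LASER_POWER_W, ABSORBANCE, water_only,
            ).eta
            for seed in range(200)
        ]
        assert abs(np.mean(etas) - 0.8) <= 0.05

    def test_monotone_in_temperature_rise(self, params_factory, water_only):
        p = params_factory()
        tr = pt.generate_trace(p)
        hotter = pt.ThermalTrace(
            tr.times, p.ambient_temp + 1.3 * tr.delta_t, p.ambient_temp,
            tr.laser_on_time, tr.laser_off_time,
        )
        e1 = estimate_eta(tr, LASER_POWER_W, ABSORBANCE, water_only).eta
        e2 = estimate_eta(hotter, LASER_POWER_W, ABSORBANCE, water_only).eta
        assert e2 > e1

    def test_opaque_limit_is_hA_dT_over_I(self, params_factory, water_only):
        p = params_factory()
        tr = pt.generate_trace(p)
        est = estimate_eta(tr, LASER_POWER_W, 12.0, water_only)
        assert est.eta == pytest.approx(est.hA * est.delta_t_max / LASER_POWER_W, rel=1e-6)

    def test_efficiency_ordering_reproduced(self, water_only):
        """Samples simulated at eta = 0.80 / 0.73 / 0.64 / 0.12 keep their
        strict ordering after noisy re-estimation."""
        recovered = []
        for eta in (0.80, 0.73, 0.64, 0.12):
            p = pt.LumpedSystemParams(
                laser_power=LASER_POWER_W, absorbance=ABSORBANCE, efficiency=eta,
                time_constant=300.0, components=water_only,
            )
            tr = pt.generate_trace(p, noise=pt.NoiseSpec(0.2, 42))
            recovered.append(estimate_eta(tr, LASER_POWER_W, ABSORBANCE, water_only).eta)
        assert recovered == sorted(recovered, reverse=True)

    def test_out_of_range_eta_flagged_not_clipped(self, params_factory, water_only):
        p = params_factory(efficiency=1.0)
        tr = pt.generate_trace(p)
        hotter = pt.ThermalTrace(
            tr.times, p.ambient_temp + 1.5 * tr.delta_t, p.ambient_temp,
            tr.laser_on_time, tr.laser_off_time,
        )
        est = estimate_eta(hotter, LASER_POWER_W, ABSORBANCE, water_only)
        assert est.eta > 1.0
        assert est.warning is not None

    def test_bad_inputs_rejected(self, params_factory, water_only):
        tr = pt.generate_trace(params_factory())
        with pytest.raises(ValueError):
            estimate_eta(tr, LASER_POWER_W, 0.0, water_only)
        heating_only = pt.ThermalTrace(tr.times, tr.temps, tr.ambient_temp)
        with pytest.raises(pt.InsufficientDataError):
            estimate_eta(heating_only, LASER_POWER_W, ABSORBANCE, water_only)
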