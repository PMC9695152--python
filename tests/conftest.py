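import numpy as np
import pytest

import phototherm as pt

#: experimental settings shared across tests: 196 mW laser, OD 0.56 sample,
#: 1 g water thermal inventory, 5-min time constant
LASER_POWER_W = 0.196
ABSORBANCE = 0.56
TAU_S = 300.0
AMBIENT_C = 25.0


@pytest.fixture
def water_only():
    """Minimal component inventory: 1 g of water (4.184 J/g/degC)."""
    return (pt.HeatCapacityComponent("water", 1.0, 4.184),)


@pytest.fixture
def params_factory(water_only):
    """LumpedSystemParams with study defaults, overridable per test."""

    def make(**kw):
        defaults = dict(
            laser_power=LASER_POWER_W,
            absorbance=ABSORBANCE,
            efficiency=0.8,
            time_constant=TAU_S,
            components=water_only,
            ambient_temp=AMBIENT_C,
        )
        defaults.update(kw)
        return pt.LumpedSystemParams(**defaults)

    return make


def make_cooling_trace(
    tau=100.0, rise=20.0, ambient=25.0, t_off=180.0, t_end=780.0, step=60.0,
    noise_sigma=0.0, seed=None,
):
    """Trace with a short flat heating plateau then an exponential decay."""
    t_heat = np.arange(0.0, t_off + step / 2, step)
    t_cool = np.arange(t_off + step, t_end + step / 2, step)
    temps_heat = np.full(t_heat.shape, ambient + rise)
    temps_cool = ambient + rise * np.exp(-(t_cool - t_off) / tau)
    times = np.concatenate([t_heat, t_cool])
    temps = np.concatenate([temps_heat, temps_cool])
    if noise_sigma > 0:
        temps = temps + np.random.default_rng(seed).normal(0, noise_sigma, temps.shape)
    return pt.ThermalTrace(times, temps, ambient, 0.0, t_off)
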