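"""Check photothermal stability over repeated irradiation cycles.

Simulates four 15-min-on / 15-min-off laser cycles of a nanoparticle-doped
sample.  A thermally stable agent reaches the same peak temperature every
cycle; the forward model reproduces that plateau behaviour exactly when the
sample relaxes fully between cycles.
"""

import phototherm as pt

params = pt.LumpedSystemParams(
    laser_power=0.196,
    absorbance=0.56,
    efficiency=0.80,
    time_constant=150.0,
    components=(pt.HeatCapacityComponent("water", 1.0, 4.184),),
)

trace = pt.simulate_cycles(params, on_duration=900, off_duration=900,
                           n_cycles=4, dt=30)

for i, (on, off) in enumerate(trace.metadata["cycles"], start=1):
    window = (trace.times >= on) & (trace.times <= off)
    peak = trace.temps[window].max() - params.ambient_temp
    print(f"cycle {i}: peak rise {peak:.3f} degC")
# Identical per-cycle maxima (within well under 1%) mean no loss of
# light-to-heat conversion between cycles — the reusability signature.
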