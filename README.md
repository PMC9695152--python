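# phototherm

Evaluation toolkit for plasmonic photothermal agents: estimate the
photothermal conversion efficiency of laser-heated nanoparticle suspensions
from infrared thermal traces, locate LSPR bands in extinction spectra,
simulate heat diffusion in layered skin-mimicking phantoms, and reduce
thermogram stacks and MTT viability plates — with a synthetic-data module
that emulates every instrument so the whole pipeline can be validated
end to end against known ground truth.

It is written for researchers screening gold nanoparticles (nanotriangles,
nanospheres, nanorods, ...) as photothermal-therapy agents: given the
heating/cooling curve of an irradiated colloid, how much of the absorbed
laser power actually becomes heat?

## The model

A vial of colloid under a continuous laser is treated as a single
uniform-temperature body (lumped capacitance).  While the laser is on, the
temperature rise above ambient follows

```
ΔT(t) = τ · [ I (1 − 10^(−A_λ)) η + Q₀ ] / Σᵢ mᵢCᵢ · (1 − e^(−t/τ))
```

and after switch-off it relaxes as `ΔT(t) = ΔT_off · e^(−t/τ)`, where

| symbol | meaning | units |
|---|---|---|
| `I` | incident laser power | W |
| `A_λ` | optical density at the excitation wavelength | – |
| `η` | photothermal conversion efficiency | – |
| `Q₀` | parasitic power absorbed by solvent + container | W |
| `Σ mᵢCᵢ` | heat-capacity inventory (solvent, vial) | J/°C |
| `τ` | thermal time constant | s |

The estimator inverts this: `τ` comes from a weighted log-linear fit of the
cooling phase, the heat-transfer product from the closure `hA = Σ mᵢCᵢ/τ`,
the steady-state rise `ΔT_max` from an exponential fit of the heating
phase, and the efficiency from the energy balance

```
η = (hA·ΔT_max − I ζ) / ( I (1 − ζ) (1 − 10^(−A_λ)) )
```

with the parasitic fraction `ζ` calibrated from a water-only control
(`ζ = 0` when no control is available).

A 2-D finite-difference solver (`∂T/∂t = ∇·(k∇T)/ρc + S/ρc`, explicit
scheme with a hard stability check and exact discrete energy bookkeeping)
models the companion experiment: a nanoparticle-doped "tumor" puncture in
a layered agarose skin phantom under the same beam.

## Worked example

`examples/fit_efficiency.py` simulates the standard protocol — 196 mW
laser, OD 0.56 sample, 15 min on / 15 min off, one camera reading per
minute with 0.2 °C noise — and re-estimates the efficiency:

```
$ python examples/fit_efficiency.py
ground-truth efficiency : 0.80
estimated efficiency    : 0.778
cooling time constant   : 314.2 s (r^2 = 0.9729)
steady-state rise       : 8.30 degC
heat transfer hA        : 13.317 mW/degC
```

The estimate recovers the ground truth to within a few percent under
camera noise (and exactly on noiseless traces).  The other scripts in
`examples/` each exercise one capability: LSPR peak picking and OD
normalization (`spectra_peaks.py`), multi-cycle photothermal stability
(`irradiation_cycles.py`), phantom heat diffusion with tumor/healthy
contrast metrics (`phantom_heating.py`), and MTT viability reduction
(`mtt_viability.py`).

A thin CLI mirrors the file-based workflow:

```
phototherm synth trace --efficiency 0.8 --out trace.csv
phototherm fit-efficiency --trace trace.csv --out estimate.json
phototherm spectra-peaks --in spectrum.csv
phototherm simulate-phantom --config phantom.yaml --out stackdir/
phototherm thermo-extract --stack stackdir/ --roi roi.json --out roi.csv
phototherm viability --plate plate.csv --control untreated
```

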