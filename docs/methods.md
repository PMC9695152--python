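# Methods

## Lumped-capacitance heating model

The forward model treats a laser-irradiated colloid (sample + solvent +
vial) as one uniform-temperature body with total heat capacity
`Σ mᵢCᵢ` exchanging heat with the environment at rate `hA·ΔT`.  With a
constant absorbed power `P = I(1 − 10^(−A_λ))η + Q₀`, the rise above
ambient saturates as `ΔT(t) = (τP/ΣmᵢCᵢ)(1 − e^(−t/τ))`; after switch-off
it decays as a single exponential with the same time constant.  Heating
and cooling deliberately share one `τ`: both are governed by the same
`hA/ΣmᵢCᵢ`, and the cooling phase is the cleaner place to measure it
because it is source-free.

`Q₀` is treated as a *power* in watts (the rate at which solvent and
container absorb laser energy).  The heating law only balances
dimensionally under that reading, and it makes `Q₀` interchangeable with
the parasitic fraction `ζ` of the energy-balance estimator through
`Q₀ = ζI` — the two symbols describe one physical quantity, which the
package calibrates once from a water-only control.

Default heat-capacity inventory: 1.0 g water (4.184 J/g°C) plus a 1.0 g
polypropylene tube (1.9 J/g°C), overridable everywhere.  Temperatures are
°C, times seconds, powers watts throughout.

Multi-cycle irradiation (`simulate_cycles`) chains phases in closed form:
each heating phase relaxes toward the steady state from the rise at phase
start, each cooling phase decays from the switch-off rise.  Samples are
therefore exact at any sampling interval, and per-cycle maxima are
provably equal once the sample relaxes fully between cycles — the
photothermal-stability signature the tests assert.

## Efficiency estimation

The pipeline composes four steps, each testable in isolation:

1. **Time constant.**  The cooling phase is linearized as
   `ln θ(t) = −t/τ` with `θ = (T − T_amb)/(T_off − T_amb)` and fitted by
   *weighted* least squares with weights `∝ (T − T_amb)²`.  Under additive
   camera noise the variance of `ln θ` grows as the inverse square of the
   remaining signal, so inverse-variance weighting keeps the low-SNR tail
   from dominating; on noiseless data it coincides with the ordinary fit.
   Samples at or below ambient are dropped; fewer than three usable
   samples, or a non-decaying phase, raise `InsufficientDataError`.
2. **Heat-transfer closure.**  At steady state, dissipation `hA·ΔT_max`
   balances absorption; combined with the relaxation rate this gives
   `hA = Σ mᵢCᵢ/τ`.
3. **Steady-state rise.**  `ΔT_max` is the amplitude of a one-parameter
   least-squares fit of `ΔT(t) = a(1 − e^(−t/τ))` to the heating phase
   with `τ` fixed from step 1 (`a = Σyf/Σf²`).  Fitting the whole heating
   curve — the standard exponential fit applied to measured thermal
   curves — extrapolates correctly even when heating stops before a full
   plateau (at 3τ a trailing-sample mean would still sit ~6 % low).  The
   simpler trailing-3-sample plateau estimate remains available as
   `delta_t_max` for traces known to have saturated.
4. **Energy balance.**  `η = (hA·ΔT_max − Iζ)/(I(1 − ζ)(1 − 10^(−A_λ)))`.
   When a water control is supplied, `ζ` is computed from the control's
   own cooling `τ` and fitted steady state (falling back to the plateau
   estimate if the control never cooled), so sample and control are
   measured identically; `ζ ≥ 1` is rejected as a calibration error.
   Estimates outside [0, 1] are reported unclipped with a warning flag —
   an out-of-range η is a diagnostic, not a value to hide.

On noiseless synthetic traces the round trip is exact to machine
precision for any η and τ, because the cooling regression, amplitude fit
and closure all invert the forward model algebraically.  With 0.2 °C
camera noise at one sample per minute over 15-min phases, the estimator
is unbiased within ±0.05 over 200 seeded replicates (asserted in the
suite).

## Spectra

LSPR bands are local maxima ranked by prominence (threshold 0.02 OD); the
most prominent peak in 450–620 nm is the out-of-plane dipole band, in
620–1300 nm the in-plane band.  The windows separate the ~534 nm
nanosphere/out-of-plane region from all NIR in-plane bands of interest;
overlapping bands are *not* deconvolved.  `A_λ` is linear interpolation —
at 1 nm instrument resolution higher-order schemes buy nothing.
Normalization rescales the whole spectrum so the *measured* in-plane peak
OD equals the target (0.56 by convention); it is a pure scaling, hence
idempotent and shape-preserving.

The synthetic generator uses Lorentzian line shapes (plasmon resonances
are homogeneously broadened); the choice is cosmetic for testing.

## Thermography

Thermogram stacks are plain-text directories (`frame_####.csv` +
`manifest.json`) because camera vendor formats are proprietary.  ROI
reduction defaults to the per-frame *maximum* (hotspot convention, what
thermal-camera readouts report); `mean` is available.  Whether measured
hotspots are maxima or spot means is generally ambiguous in practice —
max is the documented default here.  The ambient reference comes from the
recording metadata, else the ROI complement of the first frame.  Thermal
contrast is last frame minus a baseline frame; dissipation metrics are
the contrast maxima over disjoint tumor/healthy masks.

## Phantom heat-diffusion simulator

A 2-D cross-section (unit depth) of the layered phantom: 4 mm epidermal
band over an 8 mm dermal band (deeper domains get dermal backing), with a
centred 1.25 mm-wide inclusion punched into the epidermal band.  All
layers default to water-like constants (k = 0.6 W/m°C,
ρc = 4.18×10⁶ J/m³°C) — agarose gels are mostly water, and the scattering
additives affect optics, not thermal transport.  Optics are collapsed
into the beam's absorbed fraction; power is deposited only in inclusion
cells with a Gaussian beam weight, so the epidermis itself never absorbs.

The solver is explicit FTCS in flux form with harmonic-mean face
conductivities, which makes interior fluxes telescope: insulated
source-free runs conserve `Σ ρc T dx²` to round-off, and the energy audit
(input = stored + boundary loss) is an exact discrete identity, asserted
to 1 % in the tests.  Time steps above `dx²·min(ρc)/(4·max(k))` are
rejected with the computed bound.  Boundaries are insulated or uniformly
convective.  Accuracy is checked against the 2-D heat kernel (a Gaussian
pulse spreading with σ²(t) = σ₀² + 2αt), agreeing within 2 % RMS of the
peak on the default resolution.  A pre-cooled phantom is just an
initial-temperature setting.

Because the model is linear in the source, `tune_power_for_hotspot`
calibrates beam power from a single unit-power run.  Note the unit-depth
convention: powers are watts per metre of depth, so scenario powers are
calibrated to a target hotspot rather than copied from a laser nameplate.

**Known limitation — heat confinement.**  Measured phantom experiments
report the healthy region ≥2 mm from the tumor staying within ~2–3 °C
while the tumor rises ~20 °C.  A sustained pure-conduction model cannot
reproduce that bound at 300 s: the thermal diffusion length
`√(4αt) ≈ 13 mm` dwarfs 2 mm, and the simulator yields ≈12 °C at 2 mm in
this 2-D geometry (≈7 °C even in a fully 3-D axisymmetric treatment of
the cylindrical puncture).  Tight confinement in real experiments rests
on short exposure bursts, surface losses (convection/evaporation) and
measurement geometry that this model intentionally omits; the
corresponding acceptance check is left failing rather than tuned to pass,
and the locality the model *does* predict (rise at 2 mm under 10 % of the
hotspot before a quarter of the diffusion time) is asserted instead.

## Viability

Per-well background subtraction first (`net = OD570 − OD670`), then group
averaging: `viability% = 100·mean(net)/mean(net_control)` against the
non-irradiated control arm, with the replicate SD propagated on the same
scale.  Subtraction order is a documented choice; the wavelengths are the
assay's standard read/reference pair.  Omnibus statistics (ANOVA etc.)
are out of scope — the output table is designed to feed any stats tool.

## Synthetic data

Generators mirror the study conditions they emulate: thermal traces
default to 15-min on/off phases sampled each minute (the thermographic
cadence) with additive Gaussian camera noise; spectra are two-band
Lorentzian sums; plates draw well ODs as `control_od·effect·(1 + ε)`,
`ε ~ N(0, cv)`, with a fixed small reference OD.  Every generator embeds
its ground truth in the output metadata, and every estimator must recover
it within documented tolerance — that loop is the backbone of the test
suite.  All randomness flows through explicit seeds
(`numpy.random.default_rng`), making the suite bit-reproducible.

What the generators do *not* emulate: baseline drift or emissivity error
of the camera, spectrometer scatter backgrounds, convective plumes in the
vial, optical attenuation profiles inside the phantom, or plate-edge
effects.  Passing tests therefore demonstrate correctness of the
estimators under the stated noise model, not robustness to every
instrument artefact.

## Problem sizes

Reference computations use the trace protocol above (31 samples), a
64×96-cell phantom at 0.25 mm resolution stepped at ~0.09 s for 300 s
runs, 200-replicate noise ensembles, and 3-replicate plates — all chosen
as the natural desk-scale sizes of the experiments they mirror; the full
suite runs in a few seconds.
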