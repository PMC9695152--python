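"""Locate LSPR bands in an extinction spectrum and extract A_lambda.

Builds a synthetic two-band nanotriangle spectrum (out-of-plane dipole mode
near 534 nm, in-plane mode at 780 nm), normalizes the in-plane band to the
working optical density of 0.56, and reads the OD at the 785 nm laser line
— the A_lambda input of the efficiency estimator.
"""

import phototherm as pt

spectrum = pt.generate_spectrum(
    modes=[(534, 60, 1.6), (780, 90, 1.12)],  # (center nm, FWHM nm, height OD)
    noise=pt.NoiseSpec(sigma=0.005, seed=2),
    label="AuNTs@780",
)

peaks = pt.find_lspr_peaks(spectrum)
print(f"out-of-plane band : {peaks.out_of_plane_nm:.0f} nm")
print(f"in-plane band     : {peaks.in_plane_nm:.0f} nm (OD {peaks.in_plane_od:.3f})")

working = pt.normalize_to_od(spectrum, 0.56)
a_lambda = pt.od_at_wavelength(working, 785.0)
print(f"after normalization to OD 0.56, A(785 nm) = {a_lambda:.3f}")
print(f"absorbed fraction 1 - 10^-A = {1 - 10**-a_lambda:.3f}")
# The absorbed fraction converts incident laser power into the power
# available for heating in the energy-balance model.
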