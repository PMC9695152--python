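"""Extinction spectra: LSPR band location and optical-density extraction.

Triangular gold nanoparticles show two dipolar plasmon bands: an
out-of-plane mode near 534 nm and an in-plane mode tunable across the
near-infrared biological window (650-1200 nm).  The optical density at the
excitation wavelength (A_lambda) feeds the efficiency estimator, and samples
are compared after normalizing the in-plane band to a common OD.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.signal import find_peaks

__all__ = [
    "SpectrumRecord",
    "LsprPeaks",
    "find_lspr_peaks",
    "od_at_wavelength",
    "normalize_to_od",
    "OUT_OF_PLANE_WINDOW_NM",
    "IN_PLANE_WINDOW_NM",
    "DEFAULT_PROMINENCE_OD",
]

# Band-search windows: the out-of-plane (and nanosphere) band sits well below
# 620 nm; all in-plane bands of interest lie in the NIR window above it.
OUT_OF_PLANE_WINDOW_NM = (450.0, 620.0)
IN_PLANE_WINDOW_NM = (620.0, 1300.0)
DEFAULT_PROMINENCE_OD = 0.02


@dataclass
class SpectrumRecord:
    """A UV-Vis-NIR extinction spectrum."""

    wavelengths: np.ndarray  # nm, strictly increasing
    extinction: np.ndarray  # OD
    label: str = ""

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.extinction = np.asarray(self.extinction, dtype=float)
        if self.wavelengths.shape != self.extinction.shape or self.wavelengths.ndim != 1:
            raise ValueError("wavelengths and extinction must be 1-D, equal length")
        if self.wavelengths.size < 10:
            raise ValueError("a spectrum needs at least 10 samples")
        if not np.all(np.diff(self.wavelengths) > 0):
            raise ValueError("wavelengths must be strictly increasing")
        if self.wavelengths[0] < 300.0 or self.wavelengths[-1] > 1400.0:
            raise ValueError("wavelengths must lie within [300, 1400] nm")


@dataclass(frozen=True)
class LsprPeaks:
    """Located plasmon band centres; a band may be absent."""

    out_of_plane_nm: float | None = None
    in_plane_nm: float | None = None
    in_plane_od: float | None = None

    def __post_init__(self) -> None:
        if (
            self.out_of_plane_nm is not None
            and self.in_plane_nm is not None
            and not self.out_of_plane_nm < self.in_plane_nm
        ):
            raise ValueError("out-of-plane band must sit below the in-plane band")


def find_lspr_peaks(
    spectrum: SpectrumRecord, prominence: float = DEFAULT_PROMINENCE_OD
) -> LsprPeaks:
    """Locate the out-of-plane and in-plane LSPR bands.

    Local maxima are ranked by prominence; the most prominent peak inside
    each search window is reported.  A window with no peak above the
    prominence threshold yields ``None`` for that band.
    """
    idx, props = find_peaks(spectrum.extinction, prominence=prominence)
    wl = spectrum.wavelengths[idx]
    prom = props["prominences"]

    def best_in(window: tuple[float, float]) -> int | None:
        lo, hi = window
        m = (wl >= lo) & (wl < hi)
        if not m.any():
            return None
        local = np.flatnonzero(m)
        return int(local[np.argmax(prom[local])])

    oop = best_in(OUT_OF_PLANE_WINDOW_NM)
    inp = best_in(IN_PLANE_WINDOW_NM)
    return LsprPeaks(
        out_of_plane_nm=float(wl[oop]) if oop is not None else None,
        in_plane_nm=float(wl[inp]) if inp is not None else None,
        in_plane_od=float(spectrum.extinction[idx[inp]]) if inp is not None else None,
    )


def od_at_wavelength(spectrum: SpectrumRecord, wavelength: float) -> float:
    """Optical density at ``wavelength`` by linear interpolation.

    Exact at sample points; raises ``ValueError`` outside the recorded range.
    """
    if not spectrum.wavelengths[0] <= wavelength <= spectrum.wavelengths[-1]:
        raise ValueError(
            f"wavelength {wavelength} nm outside recorded range "
            f"[{spectrum.wavelengths[0]}, {spectrum.wavelengths[-1]}] nm"
        )
    return float(np.interp(wavelength, spectrum.wavelengths, spectrum.extinction))


def normalize_to_od(spectrum: SpectrumRecord, target_od: float) -> SpectrumRecord:
    """Rescale so the in-plane LSPR band has optical density ``target_od``.

    Pure scaling: peak positions and band shape are unchanged.  Raises
    ``ValueError`` when no in-plane band is detectable.
    """
    peaks = find_lspr_peaks(spectrum)
    if peaks.in_plane_od is None:
        raise ValueError("no in-plane LSPR band detected; cannot normalize")
    scale = target_od / peaks.in_plane_od
    return replace(spectrum, extinction=spectrum.extinction * scale)
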