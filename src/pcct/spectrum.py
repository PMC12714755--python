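"""Filtered-bremsstrahlung X-ray tube spectrum model.

The unfiltered fluence follows the classic thick-target bremsstrahlung
approximation: photon fluence proportional to (kVp - E) for E below the
tube voltage and zero above.  Inherent plus added filtration is modelled
as Beer-Lambert attenuation through an aluminum slab.  Characteristic
lines are not modelled.  The spectrum is normalised so that the total
fluence equals a configurable photons-per-pixel budget, which stands in
for tube current x exposure time x pixel solid angle of the real system.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .materials import get_material

__all__ = ["SpectrumModel", "generate_spectrum"]

AL_DENSITY_G_CM3 = 2.699


@dataclasses.dataclass(frozen=True)
class SpectrumModel:
    """Photon fluence per 1 keV energy bin, per detector pixel, per view."""

    energies_keV: np.ndarray
    fluence: np.ndarray
    kvp: float
    filter_mm_al: float

    def __post_init__(self) -> None:
        e = np.asarray(self.energies_keV, dtype=float)
        f = np.asarray(self.fluence, dtype=float)
        if e.shape != f.shape or e.ndim != 1:
            raise ValueError("energies and fluence must be matched 1-D arrays")
        if np.any(f < 0):
            raise ValueError("fluence must be non-negative")
        if np.any(f[e >= self.kvp] > 0):
            raise ValueError("fluence must vanish at and above the tube voltage")
        if not np.any(f > 0):
            raise ValueError("spectrum has zero total fluence")
        object.__setattr__(self, "energies_keV", e)
        object.__setattr__(self, "fluence", f)

    @property
    def total_fluence(self) -> float:
        return float(self.fluence.sum())

    def binned(self, threshold_keV: float) -> np.ndarray:
        """Fluence restricted to E >= threshold (counting-bin selection)."""
        return np.where(self.energies_keV >= threshold_keV, self.fluence, 0.0)

    def mean_energy(self, threshold_keV: float = 0.0) -> float:
        """Fluence-weighted mean energy of the bin at/above ``threshold_keV``."""
        f = self.binned(threshold_keV)
        if f.sum() <= 0:
            raise ValueError("empty energy bin")
        return float((self.energies_keV * f).sum() / f.sum())


def generate_spectrum(
    kvp: float = 80.0,
    filter_mm_al: float = 0.5,
    photons_per_pixel: float = 3200.0,
    e_min_keV: float = 10.0,
) -> SpectrumModel:
    """Analytic 80 kV-class tube spectrum on a 1 keV grid.

    Parameters
    ----------
    kvp:
        Tube voltage in kV; fluence is zero at and above this energy.
    filter_mm_al:
        Aluminum filtration thickness in mm (>= 0).
    photons_per_pixel:
        Total fluence budget the spectrum is normalised to.  The real
        system's budget is set by tube current and exposure time, which
        are not recoverable from the protocol alone, so it is exposed as
        a free parameter.  The default keeps an unattenuated flat field
        (including realistic gain variation and counting noise) safely
        below the 12-bit counter ceiling, mirroring the real system's
        exposure choice of staying inside the detector's dynamic range.
    e_min_keV:
        Lowest tabulated energy (the grid must stay inside the bundled
        attenuation tables).
    """
    if not 40.0 <= kvp <= 120.0:
        raise ValueError(f"kvp {kvp} outside supported range [40, 120]")
    if filter_mm_al < 0:
        raise ValueError("filter thickness must be non-negative")
    if photons_per_pixel <= 0:
        raise ValueError("photon budget must be positive")
    energies = np.arange(e_min_keV, kvp + 1.0)
    raw = np.clip(kvp - energies, 0.0, None)
    if filter_mm_al > 0:
        al = get_material("aluminum")
        mu_lin_per_mm = al.mass_attenuation(energies) * AL_DENSITY_G_CM3 / 10.0
        raw = raw * np.exp(-mu_lin_per_mm * filter_mm_al)
    total = raw.sum()
    fluence = raw * (photons_per_pixel / total)
    return SpectrumModel(energies, fluence, kvp=kvp, filter_mm_al=filter_mm_al)
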