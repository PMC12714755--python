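"""Reconstructed 3-D volumes tagged with physical units."""

from __future__ import annotations

import dataclasses

import numpy as np

__all__ = ["Volume", "UNITS"]

UNITS = ("mu_per_mm", "HU", "mg_per_cm3")


@dataclasses.dataclass(frozen=True)
class Volume:
    """A 3-D grid indexed ``[ix, iy, iz]`` (z = rotation axis).

    ``units`` is one of ``mu_per_mm`` (linear attenuation), ``HU``
    (Hounsfield) or ``mg_per_cm3`` (basis-material density); ``bin``
    optionally records the energy bin the volume was reconstructed from.
    """

    values: np.ndarray
    voxel_mm: tuple[float, float, float]
    units: str
    bin: str | None = None

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 3:
            raise ValueError("volume values must be 3-D")
        if not np.all(np.isfinite(v)):
            raise ValueError("volume contains non-finite values")
        if self.units not in UNITS:
            raise ValueError(f"units must be one of {UNITS}, got {self.units!r}")
        vox = tuple(float(s) for s in np.broadcast_to(self.voxel_mm, (3,)))
        if any(s <= 0 for s in vox):
            raise ValueError("voxel spacing must be positive")
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "voxel_mm", vox)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def n_slices(self) -> int:
        """Number of axial (z) planes."""
        return self.values.shape[2]

    def axial_slice(self, k: int) -> np.ndarray:
        """Axial plane k as a (ny, nx) image (row = y, column = x)."""
        return self.values[:, :, k].T

    def replace(self, **kw) -> "Volume":
        return dataclasses.replace(self, **kw)
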