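"""Image-domain two-material decomposition and virtual monoenergetic imaging.

Each voxel is modelled as a mixture of two basis materials, so its
linear attenuation at any energy is mu = sum_m (mu/rho)_m * rho_m.  With
two energy-binned measurements this is a per-voxel 2x2 solve.  All
algebra runs on the water-normalised attenuation

    NA = mu / mu_water * 1000 = HU + 1000,

which makes the decomposition matrix entries dimensionless per unit
density: entry(b, m) = (mu/rho)_m(E_b) / mu_water(E_b) * 1000 per
(g/cm^3), and a pure-water voxel has NA = 1000 in every bin.  Densities
are reported in mg/cm^3; negative values (decomposition noise) are kept
un-clipped but summarised.

Virtual monoenergetic images (VMI) re-synthesise mu at a chosen energy
from water/hydroxyapatite density maps using cubic-interpolated mass
attenuation tables, then convert to HU against water at that same
energy, so pure water reads 0 HU at every VMI energy.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .materials import Material, get_material
from .volume import Volume

__all__ = [
    "MdMatrix",
    "DensityPair",
    "na_from_hu",
    "md_matrix_from_samples",
    "md_matrix_from_materials",
    "decompose",
    "synthesize_vmi",
]


@dataclasses.dataclass(frozen=True)
class MdMatrix:
    """2x2 water-normalised decomposition matrix.

    ``entries[b, m]`` couples bin b (row: low, high) to basis material m
    (column) in NA units per (g/cm^3).
    """

    basis_names: tuple[str, str]
    entries: np.ndarray
    bins: tuple[str, str] = ("low", "high")

    def __post_init__(self) -> None:
        e = np.asarray(self.entries, dtype=float)
        if e.shape != (2, 2):
            raise ValueError("decomposition matrix must be 2x2")
        if not np.all(np.isfinite(e)):
            raise ValueError("non-finite matrix entries")
        cond = np.linalg.cond(e)
        if not np.isfinite(cond) or cond > 1e12:
            raise ValueError(
                f"singular decomposition matrix (cond={cond:.3g}): basis materials "
                f"{self.basis_names} are spectrally collinear"
            )
        object.__setattr__(self, "entries", e)

    @property
    def condition_number(self) -> float:
        return float(np.linalg.cond(self.entries))

    @property
    def inverse(self) -> np.ndarray:
        return np.linalg.inv(self.entries)

    def save(self, path) -> None:
        import yaml
        from pathlib import Path
        Path(path).write_text(yaml.safe_dump({
            "basis_names": list(self.basis_names),
            "bins": list(self.bins),
            "entries_na_per_g_cm3": self.entries.tolist(),
            "condition_number": self.condition_number,
        }))

    @classmethod
    def load(cls, path) -> "MdMatrix":
        import yaml
        from pathlib import Path
        d = yaml.safe_load(Path(path).read_text())
        return cls(tuple(d["basis_names"]), np.array(d["entries_na_per_g_cm3"]),
                   tuple(d["bins"]))


@dataclasses.dataclass(frozen=True)
class DensityPair:
    """Two co-registered basis-material density volumes (mg/cm^3)."""

    rho1: Volume
    rho2: Volume
    basis_names: tuple[str, str]

    def __post_init__(self) -> None:
        if self.rho1.shape != self.rho2.shape:
            raise ValueError("density volumes must be co-registered")
        for v in (self.rho1, self.rho2):
            if v.units != "mg_per_cm3":
                raise ValueError("density volumes must be in mg/cm^3")

    def negative_fraction(self) -> tuple[float, float]:
        """Fraction of voxels with negative density (decomposition noise)."""
        return (float(np.mean(self.rho1.values < 0)),
                float(np.mean(self.rho2.values < 0)))


def na_from_hu(hu: Volume) -> np.ndarray:
    """Normalised attenuation NA = HU + 1000 (water=1000, air=0)."""
    if hu.units != "HU":
        raise ValueError(f"expected HU volume, got units={hu.units!r}")
    return hu.values + 1000.0


def md_matrix_from_samples(mean_hu: dict, densities_g_cm3: dict,
                           basis_names: tuple[str, str] | None = None,
                           bins: tuple[str, str] = ("low", "high")) -> MdMatrix:
    """Calibrate the matrix from measured pure-sample mean HU values.

    ``mean_hu[bin][material]`` are the mean HU of a pure sample of each
    basis material in each bin; ``densities_g_cm3[material]`` its known
    density.  entry(b, m) = (HU + 1000) / density.
    """
    names = basis_names or tuple(densities_g_cm3)
    if len(names) != 2:
        raise ValueError("exactly two basis materials required")
    for m in names:
        if densities_g_cm3[m] <= 0:
            raise ValueError(f"density of {m!r} must be positive")
    entries = np.array([[ (mean_hu[b][m] + 1000.0) / densities_g_cm3[m]
                          for m in names] for b in bins])
    return MdMatrix(tuple(names), entries, bins)


def md_matrix_from_materials(mat1: Material, mat2: Material,
                             e_low_keV: float, e_high_keV: float,
                             water: Material | None = None,
                             bins: tuple[str, str] = ("low", "high")) -> MdMatrix:
    """Analytic matrix from attenuation tables at effective bin energies."""
    water = water or get_material("water")
    entries = np.empty((2, 2))
    for bi, e in enumerate((e_low_keV, e_high_keV)):
        mu_w = water.mass_attenuation(e) * water.density_g_cm3  # 1/cm
        for mi, m in enumerate((mat1, mat2)):
            entries[bi, mi] = m.mass_attenuation(e) / mu_w * 1000.0
    return MdMatrix((mat1.name, mat2.name), entries, bins)


def decompose(hu_low: Volume, hu_high: Volume, matrix: MdMatrix) -> DensityPair:
    """Per-voxel 2x2 solve for basis densities from two HU volumes."""
    if hu_low.shape != hu_high.shape:
        raise ValueError(f"shape mismatch {hu_low.shape} vs {hu_high.shape}")
    na = np.stack([na_from_hu(hu_low), na_from_hu(hu_high)])  # (2, ...)
    rho_g = np.einsum("mb,b...->m...", matrix.inverse, na)  # (2, ...) g/cm^3
    rho = rho_g * 1000.0
    vox = hu_low.voxel_mm
    return DensityPair(
        Volume(rho[0], vox, units="mg_per_cm3", bin=None),
        Volume(rho[1], vox, units="mg_per_cm3", bin=None),
        matrix.basis_names,
    )


def synthesize_vmi(densities: DensityPair, energy_keV: float,
                   materials: tuple[Material, Material] | None = None) -> Volume:
    """Virtual monoenergetic image at ``energy_keV`` in HU.

    mu_E = (mu/rho)_1(E) * rho_1 + (mu/rho)_2(E) * rho_2, converted to
    HU against water's linear attenuation at the same energy, so a pure
    water voxel (1000 mg/cm^3 water, 0 HAP) reads 0 HU at every energy.
    By default the bases are the water/hydroxyapatite pair.
    """
    if materials is None:
        materials = (get_material("water"), get_material("hap"))
    if not 15.0 <= energy_keV <= 80.0:
        raise ValueError(f"VMI energy {energy_keV} keV outside the [15, 80] keV tables")
    m1, m2 = materials
    water = get_material("water")
    mu = (m1.mass_attenuation(energy_keV) * densities.rho1.values / 1000.0
          + m2.mass_attenuation(energy_keV) * densities.rho2.values / 1000.0)  # 1/cm
    mu_w = water.mass_attenuation(energy_keV) * water.density_g_cm3
    hu = mu / mu_w * 1000.0 - 1000.0
    return Volume(hu, densities.rho1.voxel_mm, units="HU",
                  bin=f"vmi_{energy_keV:g}keV")
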