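"""Materials with energy-resolved mass attenuation.

A :class:`Material` couples a density with a tabulated mass attenuation
coefficient mu/rho(E) on a 1 keV energy grid.  Queries between grid nodes
use cubic interpolation; extrapolation outside the tabulated range is a
hard error because photoelectric attenuation diverges rapidly below the
table and the tube voltage bounds it above.

The bundled tables (``pcct/data/*.tsv``) are synthetic stand-ins generated
from a two-component analytic model -- a photoelectric term proportional to
E^-3 plus a Klein-Nishina (incoherent-scatter) energy shape -- with
per-material coefficients anchored so that water, PMMA and aluminum agree
with standard reference values at 20 and 60 keV to within a few percent.
The walnut shell and pulp tables are explicitly synthetic: no reference
measurements exist for them, so their coefficients were chosen to make
shell distinctly more attenuating (mineral-like photoelectric excess) and
pulp slightly oil-like, keeping the two spectrally separable.  Any table in
the same two-column TSV format (energy_keV, mu_over_rho cm^2/g) can be
dropped in, e.g. real NIST data.
"""

from __future__ import annotations

import dataclasses
from importlib import resources
from pathlib import Path

import numpy as np
from scipy.interpolate import CubicSpline

__all__ = [
    "Material",
    "mass_attenuation",
    "load_material_table",
    "save_material_table",
    "get_material",
    "mixture",
    "BUNDLED_MATERIALS",
]

# density in g/cm^3 for the bundled materials; shell/pulp are synthetic
_BUNDLED_DENSITY = {
    "water": 1.000,
    "pmma": 1.190,
    "aluminum": 2.699,
    "hap": 3.160,
    "walnut_shell": 1.200,
    "walnut_pulp": 0.950,
}

BUNDLED_MATERIALS = tuple(_BUNDLED_DENSITY)


@dataclasses.dataclass(frozen=True)
class Material:
    """A named material: density plus a mass-attenuation table.

    Parameters
    ----------
    name:
        Label used in phantoms and calibration files.
    density_mg_cm3:
        Physical density in mg/cm^3 (> 0).
    energies_keV:
        Strictly increasing energy grid, nominally 1 keV spacing.
    mu_over_rho:
        Mass attenuation coefficient in cm^2/g at each grid energy, > 0.
    """

    name: str
    density_mg_cm3: float
    energies_keV: np.ndarray
    mu_over_rho: np.ndarray

    def __post_init__(self) -> None:
        e = np.asarray(self.energies_keV, dtype=float)
        m = np.asarray(self.mu_over_rho, dtype=float)
        if e.ndim != 1 or e.size < 4 or e.size != m.size:
            raise ValueError("attenuation table needs >= 4 matched (E, mu/rho) rows")
        if np.any(np.diff(e) <= 0):
            raise ValueError("energy grid must be strictly increasing")
        if np.any(m <= 0):
            raise ValueError("mu/rho must be positive everywhere")
        if self.density_mg_cm3 <= 0:
            raise ValueError(f"density must be positive, got {self.density_mg_cm3}")
        object.__setattr__(self, "energies_keV", e)
        object.__setattr__(self, "mu_over_rho", m)
        object.__setattr__(self, "_spline", CubicSpline(e, m))

    @property
    def density_g_cm3(self) -> float:
        return self.density_mg_cm3 / 1000.0

    def mass_attenuation(self, energy_keV):
        """Cubic-interpolated mu/rho (cm^2/g) at ``energy_keV``.

        Exact at table nodes.  Raises ``ValueError`` outside the table.
        """
        e = np.asarray(energy_keV, dtype=float)
        lo, hi = self.energies_keV[0], self.energies_keV[-1]
        if np.any(e < lo) or np.any(e > hi):
            raise ValueError(
                f"energy {energy_keV} keV outside table range [{lo}, {hi}] for {self.name!r}"
            )
        out = self._spline(e)
        return float(out) if np.isscalar(energy_keV) else out

    def linear_attenuation_per_mm(self, energy_keV):
        """mu (1/mm) at the material's bundled density."""
        return self.mass_attenuation(energy_keV) * self.density_g_cm3 / 10.0

    def with_density(self, density_mg_cm3: float) -> "Material":
        """Same attenuation table at a different physical density."""
        return Material(self.name, density_mg_cm3, self.energies_keV, self.mu_over_rho)


def mass_attenuation(material: Material, energy_keV):
    """Functional alias for :meth:`Material.mass_attenuation`."""
    return material.mass_attenuation(energy_keV)


def load_material_table(path, name: str | None = None, density_mg_cm3: float | None = None) -> Material:
    """Read a two-column TSV (energy_keV, mu_over_rho) into a Material."""
    path = Path(path)
    rows = np.loadtxt(path, delimiter="\t", comments="#")
    if rows.ndim != 2 or rows.shape[1] != 2:
        raise ValueError(f"{path}: expected two tab-separated columns")
    stem = name or path.stem
    dens = density_mg_cm3 if density_mg_cm3 is not None else _BUNDLED_DENSITY.get(stem, 1000.0) * 1000.0 if stem in _BUNDLED_DENSITY else 1000.0
    if density_mg_cm3 is None and stem in _BUNDLED_DENSITY:
        dens = _BUNDLED_DENSITY[stem] * 1000.0
    return Material(stem, dens, rows[:, 0], rows[:, 1])


def save_material_table(material: Material, path) -> None:
    """Write the attenuation table in the package TSV format."""
    header = "energy_keV\tmu_over_rho_cm2_g"
    np.savetxt(path, np.column_stack([material.energies_keV, material.mu_over_rho]),
               delimiter="\t", header=header, fmt="%.6g")


_cache: dict[str, Material] = {}


def get_material(name: str) -> Material:
    """Load a bundled material by name (cached)."""
    if name not in _cache:
        if name not in _BUNDLED_DENSITY:
            raise KeyError(f"no bundled material {name!r}; available: {sorted(_BUNDLED_DENSITY)}")
        ref = resources.files("pcct.data").joinpath(f"{name}.tsv")
        with resources.as_file(ref) as p:
            _cache[name] = load_material_table(p, name=name,
                                              density_mg_cm3=_BUNDLED_DENSITY[name] * 1000.0)
    return _cache[name]


def mixture(name: str, components: list[tuple[Material, float]]) -> Material:
    """Material representing a physical mixture.

    ``components`` is a list of (material, partial density mg/cm^3) pairs;
    the result's mu/rho is the mass-weighted combination evaluated on the
    intersection of the component grids.  Used e.g. for hydroxyapatite
    calibration rods: HAP dispersed in a water-equivalent base.
    """
    if not components:
        raise ValueError("mixture needs at least one component")
    lo = max(m.energies_keV[0] for m, _ in components)
    hi = min(m.energies_keV[-1] for m, _ in components)
    grid = np.arange(np.ceil(lo), np.floor(hi) + 1.0)
    total = sum(rho for _, rho in components)
    if total <= 0:
        raise ValueError("mixture total density must be positive")
    mu_lin = sum(m.mass_attenuation(grid) * (rho / 1000.0) for m, rho in components)
    return Material(name, total, grid, mu_lin / (total / 1000.0))
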