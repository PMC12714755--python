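"""Voxel phantoms: walnut-like objects and calibration inserts.

Label grids are indexed ``[ix, iy, iz]`` with the grid centred on the
rotation isocenter; ``z`` is the rotation (couch) axis.  Label 0 is
air/vacuum and attenuates nothing; every nonzero label maps to a
:class:`~pcct.materials.Material` carrying its own density.

Builders are pure functions of (kind, params, seed): the same arguments
always give the same grid.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.ndimage import gaussian_filter

from .materials import Material, get_material, mixture

__all__ = ["VoxelPhantom", "build_phantom"]


@dataclasses.dataclass(frozen=True)
class VoxelPhantom:
    labels: np.ndarray              # (nx, ny, nz) small ints, 0 = air
    voxel_mm: float                 # isotropic voxel size
    material_of: dict[int, Material]

    def __post_init__(self) -> None:
        if self.labels.ndim != 3:
            raise ValueError("labels must be a 3-D grid")
        if self.voxel_mm <= 0:
            raise ValueError("voxel size must be positive")
        present = set(np.unique(self.labels)) - {0}
        missing = present - set(self.material_of)
        if missing:
            raise ValueError(f"labels without material: {sorted(missing)}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    @property
    def extent_mm(self) -> tuple[float, float, float]:
        return tuple(n * self.voxel_mm for n in self.labels.shape)

    def label_index(self) -> dict[int, int]:
        """Dense 0-based index over the nonzero labels, in sorted order."""
        return {lab: i for i, lab in enumerate(sorted(self.material_of))}

    def support_radius_mm(self) -> float:
        """Radius (about the z axis) of the smallest cylinder holding all matter."""
        ix, iy, _ = np.nonzero(self.labels)
        if ix.size == 0:
            return 0.0
        nx, ny, _ = self.labels.shape
        x = (ix + 0.5 - nx / 2) * self.voxel_mm
        y = (iy + 0.5 - ny / 2) * self.voxel_mm
        return float(np.sqrt(x**2 + y**2).max())


def _centered_coords(n: int, voxel_mm: float) -> np.ndarray:
    return (np.arange(n) + 0.5 - n / 2) * voxel_mm


def _grid(shape, voxel_mm):
    x = _centered_coords(shape[0], voxel_mm)[:, None, None]
    y = _centered_coords(shape[1], voxel_mm)[None, :, None]
    z = _centered_coords(shape[2], voxel_mm)[None, None, :]
    return x, y, z


def _build_water_cylinder(shape, voxel_mm, params):
    diameter = params.get("diameter_mm", 20.0)
    height = params.get("height_mm", shape[2] * voxel_mm)
    x, y, z = _grid(shape, voxel_mm)
    inside = (x**2 + y**2 <= (diameter / 2) ** 2) & (np.abs(z) <= height / 2)
    labels = np.where(inside, 1, 0).astype(np.int8)
    return labels, {1: get_material("water")}


def _build_hap_rods(shape, voxel_mm, params):
    holder_d = params.get("holder_diameter_mm", 20.0)
    rod_d = params.get("rod_diameter_mm", 4.0)
    densities = params.get("rod_densities_mg_cm3", (50.0, 100.0, 200.0))
    ring_r = params.get("ring_radius_mm", holder_d / 4)
    x, y, z = _grid(shape, voxel_mm)
    height = params.get("height_mm", shape[2] * voxel_mm)
    in_z = np.abs(z) <= height / 2
    labels = np.where((x**2 + y**2 <= (holder_d / 2) ** 2) & in_z, 1, 0).astype(np.int8)
    water = get_material("water")
    hap = get_material("hap")
    materials: dict[int, Material] = {1: get_material("pmma")}
    for i, rho in enumerate(densities):
        ang = 2 * np.pi * i / len(densities)
        cx, cy = ring_r * np.cos(ang), ring_r * np.sin(ang)
        rod = ((x - cx) ** 2 + (y - cy) ** 2 <= (rod_d / 2) ** 2) & in_z
        labels[rod] = 2 + i
        # QRM-style insert: HAP dispersed in a water-equivalent base
        materials[2 + i] = mixture(f"hap{int(rho)}", [(water, 1000.0), (hap, float(rho))])
    return labels, materials


def _build_walnut(shape, voxel_mm, params, rng):
    outer_d = params.get("outer_diameter_mm", 32.0)
    if not 30.0 <= outer_d <= 45.0:
        raise ValueError(f"walnut outer diameter {outer_d} mm outside [30, 45] mm")
    aspect_z = params.get("aspect_z", 0.75)
    shell_mm = params.get("shell_thickness_mm", 1.8)
    pulp_fill = params.get("pulp_fill", 0.55)     # fraction of kernel volume that is pulp
    cavity_fill = params.get("cavity_fill", 0.12)  # fraction that is internal air pocket
    a = outer_d / 2
    c = a * aspect_z
    x, y, z = _grid(shape, voxel_mm)
    r_out = np.sqrt((x / a) ** 2 + (y / a) ** 2 + (z / c) ** 2)
    r_in = np.sqrt((x / (a - shell_mm)) ** 2 + (y / (a - shell_mm)) ** 2
                   + (z / (c - shell_mm)) ** 2)
    labels = np.zeros(shape, dtype=np.int8)
    labels[(r_out <= 1.0) & (r_in > 1.0)] = 1
    kernel = r_in <= 1.0
    # Irregular pulp lobes from band-limited noise; two thresholds carve
    # pulp and air cavities out of the kernel region.
    noise = gaussian_filter(rng.standard_normal(shape), sigma=3.0 / voxel_mm * 0.4)
    kv = noise[kernel]
    if kv.size:
        hi = np.quantile(kv, 1.0 - pulp_fill)
        lo = np.quantile(kv, cavity_fill)
        pulp = kernel & (noise >= hi)
        labels[pulp] = 2
        # thin septum of shell material dividing the two hemispheres
        septum = kernel & (np.abs(y) <= voxel_mm) & (noise >= lo)
        labels[septum] = 1
    return labels, {1: get_material("walnut_shell"), 2: get_material("walnut_pulp")}


def _build_slab_stack(shape, voxel_mm, params):
    slabs = params.get("slabs", [("pmma", 10.0)])  # (material name, thickness mm)
    labels = np.zeros(shape, dtype=np.int8)
    materials: dict[int, Material] = {}
    y0 = -sum(t for _, t in slabs) / 2
    ycoord = _centered_coords(shape[1], voxel_mm)
    for i, (mat, thick) in enumerate(slabs):
        sel = (ycoord >= y0) & (ycoord < y0 + thick)
        labels[:, sel, :] = i + 1
        materials[i + 1] = get_material(mat)
        y0 += thick
    return labels, materials


def build_phantom(kind: str, params: dict | None = None, seed: int = 0) -> VoxelPhantom:
    """Build a labelled voxel phantom.

    Kinds
    -----
    ``walnut``
        Ellipsoidal high-density shell enclosing irregular pulp lobes and
        air cavities (seeded blob noise), mimicking the hard symmetric
        shell / soft irregular kernel / internal air structure that makes
        walnuts popular CT test objects.
    ``water_cylinder``
        Uniform water disk, for HU calibration.
    ``hap_rods``
        PMMA holder with three hydroxyapatite rods (default 50/100/200
        mg/cm^3), for spectral calibration.
    ``slab_stack``
        Homogeneous slab(s) spanning the full beam, for flat-field style
        calibration scans.

    ``params`` may override geometry: ``shape`` (default (96, 96, 96)),
    ``voxel_mm`` (default 0.4), plus per-kind keys documented in the
    builders.  Deterministic given ``seed``.
    """
    params = dict(params or {})
    shape = tuple(params.pop("shape", (96, 96, 96)))
    voxel_mm = float(params.pop("voxel_mm", 0.4))
    if any(n <= 0 for n in shape) or voxel_mm <= 0:
        raise ValueError("grid shape and voxel size must be positive")
    rng = np.random.default_rng(seed)
    if kind == "water_cylinder":
        labels, mats = _build_water_cylinder(shape, voxel_mm, params)
    elif kind == "hap_rods":
        labels, mats = _build_hap_rods(shape, voxel_mm, params)
    elif kind == "walnut":
        labels, mats = _build_walnut(shape, voxel_mm, params, rng)
    elif kind == "slab_stack":
        labels, mats = _build_slab_stack(shape, voxel_mm, params)
    else:
        raise ValueError(f"unknown phantom kind {kind!r}")
    return VoxelPhantom(labels, voxel_mm, mats)
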