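"""Cone-beam scan simulation with a dual-threshold photon-counting detector.

The forward model is Beer-Lambert attenuation of a polychromatic tube
spectrum along exact Siddon ray paths, followed by an idealised
photon-counting detector: two counting thresholds (Total >= 15 keV,
High >= 30 keV; the Low bin 15-30 keV is never acquired, only derived by
subtraction downstream), a per-pixel multiplicative gain map with tile
structure, stuck pixels, Poisson counting noise and a 12-bit counter that
silently saturates at 4096 counts.

Geometry: the source rotates about the z (couch) axis at distance
``sid_mm`` from the isocenter, with a flat detector at ``sdd_mm``
centred on the central ray; detector rows run along z, channels in the
rotation plane.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np

from ._siddon import trace_view
from .io import ProjectionImage, ProjectionStack, write_raw_frame
from .materials import Material, get_material
from .phantoms import VoxelPhantom
from .spectrum import SpectrumModel

__all__ = [
    "ScanGeometry",
    "DetectorModel",
    "PathSinogram",
    "make_gain_map",
    "make_detector",
    "forward_paths",
    "detect_counts",
    "acquire_scan",
    "acquire_slab_series",
]


@dataclasses.dataclass(frozen=True)
class ScanGeometry:
    """Circular cone-beam geometry (distances in mm, angles in degrees)."""

    sid_mm: float = 140.0
    sdd_mm: float = 325.0
    pixel_mm: float = 0.1
    n_channels: int = 2063
    n_rows: int = 505
    angles_deg: np.ndarray = dataclasses.field(
        default_factory=lambda: np.arange(1440) * 0.25
    )
    couch_offset_mm: float = 0.0
    couch_spacing_mm: float = 15.0

    def __post_init__(self) -> None:
        if not 0 < self.sid_mm < self.sdd_mm:
            raise ValueError("require 0 < SID < SDD")
        a = np.asarray(self.angles_deg, dtype=float)
        if a.ndim != 1 or a.size == 0 or np.any(np.diff(a) <= 0):
            raise ValueError("angles must be strictly increasing")
        if a[-1] - a[0] > 360.0:
            raise ValueError("angular span exceeds 360 degrees")
        object.__setattr__(self, "angles_deg", a)

    @classmethod
    def desk_scale(cls, n_views: int = 180) -> "ScanGeometry":
        """Reduced-size profile for CPU-scale runs.

        Keeps the real SID/SDD but bins the detector down to 256 x 64
        pixels of 0.4 mm (the real pitch is 0.1 mm over 2063 x 505) and
        reduces the view count; the isocenter field of view stays ~44 mm
        wide so walnut-sized objects still fit radially.
        """
        return cls(pixel_mm=0.4, n_channels=256, n_rows=64,
                   angles_deg=np.arange(n_views) * (360.0 / n_views))

    @property
    def magnification(self) -> float:
        return self.sdd_mm / self.sid_mm

    @property
    def fov_radius_mm(self) -> float:
        """Radius of the cylinder seen by every view (at the isocenter)."""
        return 0.5 * self.n_channels * self.pixel_mm / self.magnification

    def source_frame(self, angle_deg: float):
        """(source, detector center, u, v) world positions for one view."""
        th = np.deg2rad(angle_deg)
        s, c = np.sin(th), np.cos(th)
        z = self.couch_offset_mm
        src = np.array([self.sid_mm * s, -self.sid_mm * c, z])
        det = np.array([-(self.sdd_mm - self.sid_mm) * s,
                        (self.sdd_mm - self.sid_mm) * c, z])
        u = np.array([c, s, 0.0])
        v = np.array([0.0, 0.0, 1.0])
        return src, det, u, v


@dataclasses.dataclass(frozen=True)
class DetectorModel:
    """Thresholds, response non-uniformity, stuck pixels and counter ceiling.

    Non-uniformity has two components.  ``gain`` is a static multiplicative
    per-pixel map; it shifts raw counts (saturation, bad-pixel statistics,
    the derived low bin) but cancels in per-bin flat-field division.
    ``threshold_offsets_keV`` models per-pixel comparator threshold
    dispersion -- the dominant mechanism by which counting detectors stay
    non-uniform *after* air correction, because a threshold error changes
    a pixel's spectral acceptance and the resulting count error depends on
    how much the object has hardened the beam.  This is what the STEPC and
    ring corrections exist to remove.
    """

    thresholds_keV: tuple[float, float] = (15.0, 30.0)
    counter_max: int = 4096
    gain: np.ndarray | None = None                    # (n_rows, n_channels), > 0
    threshold_offsets_keV: np.ndarray | None = None   # (2, n_rows, n_channels)
    bad_pixels: dict = dataclasses.field(default_factory=dict)
    exposure: float = 1.0                              # relative to the nominal 70 ms

    STUCK_LOW_VALUE = 2
    STUCK_HIGH_MARGIN = 2  # stuck-high pixels read counter_max - margin

    def __post_init__(self) -> None:
        lo, hi = self.thresholds_keV
        if not lo < hi:
            raise ValueError("thresholds must be strictly increasing")
        if self.gain is not None:
            g = np.asarray(self.gain, dtype=float)
            if np.any(~np.isfinite(g)) or np.any(g <= 0):
                raise ValueError("gain must be finite and positive")
            object.__setattr__(self, "gain", g)
        if self.threshold_offsets_keV is not None:
            t = np.asarray(self.threshold_offsets_keV, dtype=float)
            if t.ndim != 3 or t.shape[0] != 2 or not np.all(np.isfinite(t)):
                raise ValueError("threshold offsets must be finite, shape (2, rows, channels)")
            object.__setattr__(self, "threshold_offsets_keV", t)

    def _bin_index(self, bin: str) -> int:
        if bin == "total":
            return 0
        if bin == "high":
            return 1
        raise ValueError(f"bin {bin!r} is not an acquired bin (low is derived)")

    def threshold_for(self, bin: str) -> float:
        return self.thresholds_keV[self._bin_index(bin)]

    def threshold_map(self, bin: str, shape) -> np.ndarray:
        """Per-pixel effective threshold (keV) for an acquired bin."""
        b = self._bin_index(bin)
        thr = np.full(shape, self.thresholds_keV[b])
        if self.threshold_offsets_keV is not None:
            if self.threshold_offsets_keV.shape[1:] != tuple(shape):
                raise ValueError("threshold offset shape does not match detector")
            thr = thr + self.threshold_offsets_keV[b]
        return thr

    def gain_or_ones(self, shape) -> np.ndarray:
        if self.gain is None:
            return np.ones(shape)
        if self.gain.shape != tuple(shape):
            raise ValueError(f"gain shape {self.gain.shape} != detector {tuple(shape)}")
        return self.gain


@dataclasses.dataclass(frozen=True)
class PathSinogram:
    """Per-material exact intersection lengths (mm) for one view."""

    paths_mm: np.ndarray          # (n_materials, n_rows, n_channels)
    materials: tuple[Material, ...]
    angle_deg: float

    def __post_init__(self) -> None:
        if self.paths_mm.ndim != 3 or self.paths_mm.shape[0] != len(self.materials):
            raise ValueError("paths axis 0 must match the material list")
        if np.any(self.paths_mm < 0):
            raise ValueError("path lengths cannot be negative")


def make_gain_map(n_rows: int, n_channels: int, seed: int = 0, *,
                  tile_width: int = 128, sigma_tile: float = 0.03,
                  sigma_pixel: float = 0.005, smooth_amplitude: float = 0.02
                  ) -> np.ndarray:
    """Synthetic detector response map: smooth field x tile offsets x jitter.

    Real photon-counting panels show response variation both between
    detector tiles (visible as seams every ``tile_width`` channels) and
    between individual pixels; a gentle low-order polynomial field stands
    in for global drift.  All factors are multiplicative around 1.
    """
    rng = np.random.default_rng(seed)
    r = (np.arange(n_rows)[:, None] - n_rows / 2) / max(n_rows, 1)
    c = (np.arange(n_channels)[None, :] - n_channels / 2) / max(n_channels, 1)
    coef = rng.standard_normal(5)
    smooth = 1.0 + smooth_amplitude * (
        coef[0] * r + coef[1] * c + coef[2] * r * c + coef[3] * r**2 + coef[4] * c**2
    )
    n_tiles = int(np.ceil(n_channels / tile_width))
    tile_gain = rng.lognormal(0.0, sigma_tile, size=n_tiles)
    tiles = np.repeat(tile_gain, tile_width)[:n_channels][None, :]
    jitter = rng.lognormal(0.0, sigma_pixel, size=(n_rows, n_channels))
    return smooth * tiles * jitter


def make_threshold_offsets(n_rows: int, n_channels: int, seed: int = 0, *,
                           tile_width: int = 128, sigma_tile_keV: float = 1.0,
                           sigma_pixel_keV: float = 0.4) -> np.ndarray:
    """Per-pixel comparator threshold errors (keV) for both thresholds.

    Tile-structured plus per-pixel dispersion, independent between the
    two thresholds, zero-mean.  Shape (2, n_rows, n_channels).
    """
    rng = np.random.default_rng(seed)
    n_tiles = int(np.ceil(n_channels / tile_width))
    out = np.empty((2, n_rows, n_channels))
    for b in range(2):
        tiles = np.repeat(rng.normal(0.0, sigma_tile_keV, n_tiles),
                          tile_width)[:n_channels]
        out[b] = tiles[None, :] + rng.normal(0.0, sigma_pixel_keV,
                                             (n_rows, n_channels))
    return out


def make_detector(geom: ScanGeometry, seed: int = 0, *,
                  n_bad_pixels: int = 8, ideal: bool = False,
                  tile_width: int = 128, sigma_tile_keV: float = 1.0,
                  sigma_pixel_keV: float = 0.4,
                  **gain_kw) -> DetectorModel:
    """Detector with seeded gain map, threshold dispersion and stuck pixels.

    ``ideal=True`` returns a perfectly uniform detector (unit gain, exact
    thresholds, no bad pixels).
    """
    if ideal:
        return DetectorModel()
    rng = np.random.default_rng(seed + 1)
    gain = make_gain_map(geom.n_rows, geom.n_channels, seed=seed,
                         tile_width=tile_width, **gain_kw)
    offsets = make_threshold_offsets(geom.n_rows, geom.n_channels, seed=seed + 2,
                                     tile_width=tile_width,
                                     sigma_tile_keV=sigma_tile_keV,
                                     sigma_pixel_keV=sigma_pixel_keV)
    bad: dict = {}
    while len(bad) < n_bad_pixels:
        r = int(rng.integers(geom.n_rows))
        c = int(rng.integers(geom.n_channels))
        bad[(r, c)] = "stuck_low" if rng.random() < 0.5 else "stuck_high"
    return DetectorModel(gain=gain, threshold_offsets_keV=offsets, bad_pixels=bad)


def forward_paths(phantom: VoxelPhantom, geom: ScanGeometry,
                  angle_deg: float) -> PathSinogram:
    """Trace one view: exact per-material path lengths for every pixel."""
    if phantom.support_radius_mm() > geom.fov_radius_mm + 1e-9:
        warnings.warn(
            f"phantom radius {phantom.support_radius_mm():.1f} mm exceeds the "
            f"{geom.fov_radius_mm:.1f} mm field of view; projections are truncated"
        )
    index = phantom.label_index()
    materials = tuple(phantom.material_of[lab] for lab in sorted(index))
    lut = np.full(int(phantom.labels.max()) + 1, -1, dtype=np.int64)
    for lab, i in index.items():
        lut[lab] = i
    out = np.zeros((len(materials), geom.n_rows, geom.n_channels))
    src, det, u, v = geom.source_frame(angle_deg)
    trace_view(np.ascontiguousarray(phantom.labels, dtype=np.int8), lut,
               phantom.voxel_mm, src, det, u, v,
               geom.pixel_mm, geom.n_rows, geom.n_channels, out)
    return PathSinogram(out, materials, angle_deg % 360.0)


def _bin_weights(energies: np.ndarray, thr_map: np.ndarray) -> np.ndarray:
    """Per-pixel spectral acceptance of a counting bin, shape (nE, R, C).

    A unit ramp one energy-grid step wide at each pixel's effective
    threshold; for exact on-grid thresholds this reduces to a hard
    E >= threshold selection.
    """
    return np.clip(energies[:, None, None] - thr_map[None] + 1.0, 0.0, 1.0)


def expected_counts(paths: PathSinogram | None, spectrum: SpectrumModel,
                    det: DetectorModel, bin: str,
                    shape: tuple[int, int] | None = None) -> np.ndarray:
    """Noise-free expected counts lambda(i, j) for one view and bin."""
    if paths is None:
        if shape is None:
            raise ValueError("shape required for an air (zero-path) view")
    else:
        shape = paths.paths_mm.shape[1:]
    thr_map = det.threshold_map(bin, shape)
    w = _bin_weights(spectrum.energies_keV, thr_map)
    fl = spectrum.fluence * det.exposure
    if paths is None:
        lam = np.einsum("e,erc->rc", fl, w)
    else:
        mu_lin = np.stack([
            m.mass_attenuation(spectrum.energies_keV) * m.density_g_cm3 / 10.0
            for m in paths.materials
        ])  # (L, nE), per mm
        expo = np.einsum("le,lrc->erc", mu_lin, paths.paths_mm)
        lam = np.einsum("e,erc,erc->rc", fl, w, np.exp(-expo))
    return det.gain_or_ones(shape) * lam


def _record(lam: np.ndarray, det: DetectorModel, rng, noise: bool) -> np.ndarray:
    if noise:
        counts = rng.poisson(lam).astype(np.int64)
    else:
        counts = np.rint(lam).astype(np.int64)
    counts = np.clip(counts, 0, det.counter_max)
    for (r, c), mode in det.bad_pixels.items():
        counts[r, c] = (det.STUCK_LOW_VALUE if mode == "stuck_low"
                        else det.counter_max - det.STUCK_HIGH_MARGIN)
    return counts


def detect_counts(paths: PathSinogram, spectrum: SpectrumModel,
                  det: DetectorModel, bin: str, seed=None,
                  noise: bool = True) -> ProjectionImage:
    """Record one counting frame: Poisson(lambda) clipped to the counter.

    ``seed`` may be an int or a ``numpy.random.Generator``; with
    ``noise=False`` the rounded expectation is recorded instead.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    lam = expected_counts(paths, spectrum, det, bin)
    counts = _record(lam, det, rng, noise)
    return ProjectionImage(counts, bin=bin, angle_deg=paths.angle_deg, kind="counts")


def _mean_of_repeats(lam: np.ndarray, det: DetectorModel, rng,
                     n: int, noise: bool) -> np.ndarray:
    # sum of n independent Poisson(lam) is Poisson(n*lam); per-frame counter
    # clipping is neglected, valid while lam stays below the ceiling
    mean = rng.poisson(lam * n) / n if noise else lam.copy()
    mean = np.clip(mean, 0, det.counter_max)
    for (r, c), mode in det.bad_pixels.items():
        mean[r, c] = (det.STUCK_LOW_VALUE if mode == "stuck_low"
                      else det.counter_max - det.STUCK_HIGH_MARGIN)
    return mean


def acquire_scan(phantom: VoxelPhantom, geom: ScanGeometry, det: DetectorModel,
                 spectrum: SpectrumModel, seed: int = 0, *, noise: bool = True,
                 n_flat: int = 1440) -> dict:
    """Simulate a full circular scan: Total and High stacks plus flat fields.

    Returns ``{"total": ProjectionStack, "high": ProjectionStack,
    "flats": {bin: ProjectionImage}}``.  Flat fields are the average of
    ``n_flat`` noisy air frames, as in the released calibration tables.
    """
    rng = np.random.default_rng(seed)
    frames: dict[str, list[ProjectionImage]] = {"total": [], "high": []}
    for angle in geom.angles_deg:
        paths = forward_paths(phantom, geom, angle)
        for bin in ("total", "high"):
            frames[bin].append(detect_counts(paths, spectrum, det, bin,
                                             seed=rng, noise=noise))
    shape = (geom.n_rows, geom.n_channels)
    flats = {}
    for bin in ("total", "high"):
        lam = expected_counts(None, spectrum, det, bin, shape=shape)
        flats[bin] = ProjectionImage(_mean_of_repeats(lam, det, rng, n_flat, noise),
                                     bin=bin, kind="counts")
    return {"total": ProjectionStack(frames["total"]),
            "high": ProjectionStack(frames["high"]),
            "flats": flats}


def acquire_slab_series(pmma_mm, al_mm, geom: ScanGeometry, det: DetectorModel,
                        spectrum: SpectrumModel, seed: int = 0, *,
                        n_frames: int = 600, noise: bool = True,
                        out_dir=None) -> dict:
    """Scan every (PMMA, Al) slab combination as an averaged flat scan.

    Slabs span the whole beam perpendicular to the central ray, so each
    pixel's path is the stacked thickness divided by the cosine of its
    ray obliquity (exact for infinite flat slabs).  The default
    thickness lists {0, 5, 10, 15, 20, 30, 40} mm PMMA x {0, 0.5, 1,
    1.5, 2, 3, 4, 5} mm Al give the 56-scan calibration series.  Each
    scan is the average of ``n_frames`` counting frames.  With
    ``out_dir`` set, scans are also written as ``PMMA_<m>_AL_<n>/
    proj_{total,high}.raw`` (rounded to integer counts).
    """
    pmma_mm = [float(t) for t in pmma_mm]
    al_mm = [float(t) for t in al_mm]
    if any(t < 0 for t in pmma_mm + al_mm):
        raise ValueError("slab thickness cannot be negative")
    if 0.0 not in pmma_mm or 0.0 not in al_mm:
        raise ValueError("thickness lists must include 0 (absent slab)")
    rng = np.random.default_rng(seed)
    pm = get_material("pmma")
    al = get_material("aluminum")
    E = spectrum.energies_keV
    mu_p = pm.mass_attenuation(E) * pm.density_g_cm3 / 10.0   # 1/mm
    mu_a = al.mass_attenuation(E) * al.density_g_cm3 / 10.0
    # per-pixel obliquity of the ray through a beam-normal slab
    src, detc, u, v = geom.source_frame(0.0)
    uoff = (np.arange(geom.n_channels) - (geom.n_channels - 1) / 2) * geom.pixel_mm
    voff = (np.arange(geom.n_rows) - (geom.n_rows - 1) / 2) * geom.pixel_mm
    P = (detc[None, None, :] + uoff[None, :, None] * u[None, None, :]
         + voff[:, None, None] * v[None, None, :])
    d = P - src[None, None, :]
    axis = (detc - src) / np.linalg.norm(detc - src)
    cos_a = (d @ axis) / np.linalg.norm(d, axis=-1)
    gain = det.gain_or_ones((geom.n_rows, geom.n_channels))
    series: dict = {}
    fl = spectrum.fluence * det.exposure
    shape = (geom.n_rows, geom.n_channels)
    weights = {b: _bin_weights(E, det.threshold_map(b, shape))
               for b in ("total", "high")}
    for tp in pmma_mm:
        for ta in al_mm:
            trans = np.exp(-(mu_p * tp + mu_a * ta)[:, None, None]
                           / cos_a[None, :, :])
            scans = {}
            for bin in ("total", "high"):
                lam = gain * np.einsum("e,erc,erc->rc", fl, weights[bin], trans)
                mean = _mean_of_repeats(lam, det, rng, n_frames, noise)
                scans[bin] = ProjectionImage(mean, bin=bin, kind="counts")
            series[(tp, ta)] = scans
    if out_dir is not None:
        from pathlib import Path
        out_dir = Path(out_dir)
        for (tp, ta), scans in series.items():
            sub = out_dir / f"PMMA_{tp:g}_AL_{ta:g}"
            for bin, img in scans.items():
                write_raw_frame(img, sub / f"proj_{bin}.raw")
    return series
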