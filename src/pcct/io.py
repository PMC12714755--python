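"""Readers and writers for the dataset's on-disk conventions.

Raw detector frames are headerless 16-bit unsigned little-endian files,
row-major over (detector row, detector channel); the full-scale detector
is 2063 channels wide by 505 rows high.  Scan trees follow the released
folder layouts: per-couch ``{High,Total}/proj_<j>.raw`` for object scans,
``PMMA_<m>_AL_<n>/proj_{high,total}.raw`` for the slab calibration
series, and per-bin averaged flat-field tables for air scans.
"""

from __future__ import annotations

import dataclasses
import re
import warnings
from pathlib import Path

import numpy as np
import yaml

from .volume import Volume

__all__ = [
    "RawFrameSpec",
    "ProjectionImage",
    "ProjectionStack",
    "ScanManifest",
    "read_raw_frame",
    "write_raw_frame",
    "scan_directory",
    "export_volume",
    "write_manifest",
    "read_manifest",
]

BINS = ("total", "high", "low")
KINDS = ("counts", "log")


@dataclasses.dataclass(frozen=True)
class RawFrameSpec:
    """Shape/encoding contract for a headerless raw frame.

    Files hold ``height x width`` 16-bit unsigned little-endian words in
    row-major order; ``width`` runs along detector channels (horizontal),
    ``height`` along detector rows (vertical).
    """

    width: int = 2063
    height: int = 505

    def __post_init__(self) -> None:
        if self.width < 1 or self.height < 1:
            raise ValueError("frame dimensions must be >= 1")

    @property
    def nbytes(self) -> int:
        return 2 * self.width * self.height


@dataclasses.dataclass(frozen=True)
class ProjectionImage:
    """One detector frame: photon counts or an air-corrected log projection.

    ``values`` is a (rows, channels) grid.  Counts frames hold photon
    numbers in [0, counter ceiling] -- floats are tolerated so that
    frame-averaged flat fields keep sub-count precision.  Log frames are
    unitless line integrals and must be finite.
    """

    values: np.ndarray
    bin: str = "total"
    angle_deg: float = 0.0
    kind: str = "counts"

    def __post_init__(self) -> None:
        v = np.asarray(self.values)
        if v.ndim != 2:
            raise ValueError("projection values must be 2-D (rows, channels)")
        if self.bin not in BINS:
            raise ValueError(f"bin must be one of {BINS}, got {self.bin!r}")
        if self.kind not in KINDS:
            raise ValueError(f"kind must be one of {KINDS}, got {self.kind!r}")
        if not np.all(np.isfinite(v)):
            raise ValueError("projection contains non-finite values")
        if self.kind == "counts" and np.any(v < 0):
            raise ValueError("counts cannot be negative")
        if not 0.0 <= self.angle_deg < 360.0:
            raise ValueError("angle_deg must lie in [0, 360)")
        object.__setattr__(self, "values", v)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def replace(self, **kw) -> "ProjectionImage":
        return dataclasses.replace(self, **kw)


@dataclasses.dataclass(frozen=True)
class ProjectionStack:
    """An angle-ordered sequence of frames sharing bin, kind and shape."""

    frames: tuple[ProjectionImage, ...]

    def __init__(self, frames) -> None:
        frames = tuple(frames)
        if not frames:
            raise ValueError("stack needs at least one frame")
        f0 = frames[0]
        for f in frames[1:]:
            if f.shape != f0.shape or f.bin != f0.bin or f.kind != f0.kind:
                raise ValueError("all frames must share shape, bin and kind")
        angles = [f.angle_deg for f in frames]
        if any(b <= a for a, b in zip(angles, angles[1:])):
            raise ValueError("frame angles must be strictly increasing")
        object.__setattr__(self, "frames", frames)

    def __len__(self) -> int:
        return len(self.frames)

    def __iter__(self):
        return iter(self.frames)

    def __getitem__(self, i) -> ProjectionImage:
        return self.frames[i]

    @property
    def bin(self) -> str:
        return self.frames[0].bin

    @property
    def kind(self) -> str:
        return self.frames[0].kind

    @property
    def angles_deg(self) -> np.ndarray:
        return np.array([f.angle_deg for f in self.frames])

    def as_array(self) -> np.ndarray:
        """(n_views, rows, channels) array view of the stack."""
        return np.stack([f.values for f in self.frames])

    def with_values(self, arr: np.ndarray, kind: str | None = None) -> "ProjectionStack":
        """Same metadata, new per-frame values."""
        if arr.shape[0] != len(self.frames):
            raise ValueError("view count mismatch")
        kind = kind or self.kind
        return ProjectionStack(
            f.replace(values=arr[i], kind=kind) for i, f in enumerate(self.frames)
        )


def read_raw_frame(path, spec: RawFrameSpec = RawFrameSpec(), *,
                   bin: str = "total", angle_deg: float = 0.0) -> ProjectionImage:
    """Decode a headerless uint16-LE frame into a counts image."""
    path = Path(path)
    actual = path.stat().st_size
    if actual != spec.nbytes:
        raise ValueError(
            f"{path}: expected {spec.nbytes} bytes "
            f"({spec.height}x{spec.width} uint16), found {actual}"
        )
    data = np.fromfile(path, dtype="<u2").reshape(spec.height, spec.width)
    return ProjectionImage(data.astype(np.int64), bin=bin, angle_deg=angle_deg, kind="counts")


def write_raw_frame(img: ProjectionImage, path) -> Path:
    """Byte-exact inverse of :func:`read_raw_frame`."""
    if img.kind != "counts":
        raise ValueError("only counts frames can be written as raw")
    v = np.asarray(img.values)
    r = np.rint(v)
    if np.any(r < 0) or np.any(r > 0xFFFF):
        bad = v[(r < 0) | (r > 0xFFFF)]
        raise ValueError(f"values outside 16-bit range, e.g. {bad.flat[0]}")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    r.astype("<u2").tofile(path)
    return path


@dataclasses.dataclass
class ScanManifest:
    """Result of :func:`scan_directory`: files keyed by (bin, index/label)."""

    layout: str
    entries: dict      # (bin, key) -> Path; key = 0-based view index or (pmma, al)
    counts: dict       # bin -> number of files

    def paths_for(self, bin: str) -> list[Path]:
        keys = sorted(k for (b, k) in self.entries if b == bin)
        return [self.entries[(bin, k)] for k in keys]


_PROJ_RE = re.compile(r"proj_(\d+)\.raw$")
_SLAB_RE = re.compile(r"PMMA_([0-9.]+)_AL_([0-9.]+)$")


def scan_directory(root, layout: str) -> ScanManifest:
    """Index a scan tree.

    ``walnut_couch``: ``root/{High,Total}/proj_<j>.raw`` with 1-based
    angle indices in filenames, returned 0-based.  ``slab_series``:
    ``root/PMMA_<m>_AL_<n>/proj_{high,total}.raw`` keyed by the parsed
    (PMMA mm, Al mm) thicknesses.  ``flat``: per-bin averaged air tables
    ``air_table_<bin>.raw``.
    """
    root = Path(root)
    if not root.is_dir():
        raise FileNotFoundError(f"scan root {root} does not exist")
    entries: dict = {}
    if layout == "walnut_couch":
        for folder, bin in (("High", "high"), ("Total", "total")):
            sub = root / folder
            if not sub.is_dir():
                raise ValueError(f"missing bin folder {sub}")
            idx = []
            for p in sorted(sub.glob("proj_*.raw")):
                m = _PROJ_RE.search(p.name)
                if m:
                    j = int(m.group(1)) - 1  # filenames are 1-based
                    entries[(bin, j)] = p
                    idx.append(j)
            if not idx:
                raise ValueError(f"no projection files in {sub}")
            gaps = sorted(set(range(min(idx), max(idx) + 1)) - set(idx))
            if gaps:
                warnings.warn(f"{sub}: non-contiguous angle indices, missing {gaps}")
    elif layout == "slab_series":
        found = False
        for sub in sorted(root.iterdir()):
            m = _SLAB_RE.match(sub.name)
            if not (sub.is_dir() and m):
                continue
            label = (float(m.group(1)), float(m.group(2)))
            for fname, bin in (("proj_high.raw", "high"), ("proj_total.raw", "total")):
                p = sub / fname
                if not p.is_file():
                    raise ValueError(f"missing {p}")
                entries[(bin, label)] = p
                found = True
        if not found:
            raise ValueError(f"no PMMA_<m>_AL_<n> folders under {root}")
    elif layout == "flat":
        for bin in BINS:
            p = root / f"air_table_{bin}.raw"
            if p.is_file():
                entries[(bin, 0)] = p
        if not entries:
            raise ValueError(f"no air_table_<bin>.raw files under {root}")
    else:
        raise ValueError(f"unknown layout {layout!r}")
    counts = {}
    for (bin, _k) in entries:
        counts[bin] = counts.get(bin, 0) + 1
    return ScanManifest(layout=layout, entries=entries, counts=counts)


def export_volume(vol: Volume, out_dir, format: str = "dicom_series") -> list[Path]:
    """Write one file per axial slice, named ``<n>.dcm``/``<n>.raw``.

    DICOM series require HU volumes; stored values are signed 16-bit HU
    with identity rescale (slope 1, intercept 0), so read-back matches
    the input to 1 HU quantisation.  ``raw_stack`` writes float32-LE
    slices in any unit, plus a YAML sidecar with shape and spacing.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    if format == "dicom_series":
        if vol.units != "HU":
            raise ValueError(f"DICOM export requires HU volume, got units={vol.units!r}")
        for k in range(vol.n_slices):
            p = out_dir / f"{k + 1:05d}.dcm"
            _write_dicom_slice(vol, k, p)
            written.append(p)
    elif format == "raw_stack":
        for k in range(vol.n_slices):
            p = out_dir / f"{k + 1:05d}.raw"
            vol.axial_slice(k).astype("<f4").tofile(p)
            written.append(p)
        write_manifest(
            {"format": "raw_stack_float32_le", "units": vol.units,
             "slice_shape": list(vol.axial_slice(0).shape),
             "n_slices": vol.n_slices, "voxel_mm": list(vol.voxel_mm)},
            out_dir / "stack.yaml",
        )
    else:
        raise ValueError(f"unknown export format {format!r}")
    return written


def _write_dicom_slice(vol: Volume, k: int, path: Path) -> None:
    import pydicom
    from pydicom.dataset import Dataset, FileMetaDataset
    from pydicom.uid import CTImageStorage, ExplicitVRLittleEndian, generate_uid

    img = np.clip(np.rint(vol.axial_slice(k)), -32768, 32767).astype("<i2")
    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = CTImageStorage
    meta.MediaStorageSOPInstanceUID = generate_uid()
    meta.TransferSyntaxUID = ExplicitVRLittleEndian
    ds = Dataset()
    ds.file_meta = meta
    ds.SOPClassUID = CTImageStorage
    ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
    ds.Modality = "CT"
    ds.SeriesInstanceUID = generate_uid(entropy_srcs=[str(path.parent)])
    ds.StudyInstanceUID = generate_uid(entropy_srcs=[str(path.parent), "study"])
    ds.InstanceNumber = k + 1
    ds.Rows, ds.Columns = img.shape
    ds.PixelSpacing = [vol.voxel_mm[1], vol.voxel_mm[0]]
    ds.SliceThickness = vol.voxel_mm[2]
    ds.ImagePositionPatient = [0.0, 0.0, k * vol.voxel_mm[2]]
    ds.ImageOrientationPatient = [1, 0, 0, 0, 1, 0]
    ds.RescaleSlope = 1.0
    ds.RescaleIntercept = 0.0
    ds.RescaleType = "HU"
    ds.BitsAllocated = 16
    ds.BitsStored = 16
    ds.HighBit = 15
    ds.PixelRepresentation = 1  # signed
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.PixelData = img.tobytes()
    pydicom.dcmwrite(path, ds, enforce_file_format=True)


def write_manifest(data: dict, path) -> Path:
    """Serialise an acquisition/run manifest as YAML."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(yaml.safe_dump(data, sort_keys=True))
    return path


def read_manifest(path) -> dict:
    return yaml.safe_load(Path(path).read_text())
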