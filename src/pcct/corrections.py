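"""Projection-domain preprocessing for photon-counting detectors.

The chain, in acquisition order:

1. **Bin subtraction** -- the Low bin (15-30 keV) is derived as
   Total - High in the counts domain, clipped at zero (counts are
   physical; clips are counted and reported).
2. **Air correction** -- P = -ln(I_obj / I_air), the log projection.
3. **Signal-to-uniformity-error polynomial calibration (STEPC)** -- a
   per-pixel polynomial in the pixel's own Total/High log signals
   predicts its deviation from an ideal smooth detector response, fitted
   on a slab calibration series and subtracted during correction.
4. **Bad-pixel interpolation** -- counts below 5 or above 4090 flag a
   pixel; flagged pixels are replaced by 1-D linear interpolation along
   the channel direction.
5. **Ring correction** -- a static residual error map is estimated from
   angle-subset means (median across subsets, background-bias removed)
   and subtracted from every view.

All log-domain operations act on (rows, channels) frames; the STEPC and
ring error maps are additive in the log domain.
"""

from __future__ import annotations

import dataclasses
import warnings
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter, median_filter

import yaml

from .io import ProjectionImage, ProjectionStack

__all__ = [
    "StepcTable",
    "RingErrorMap",
    "derive_low",
    "air_correct",
    "air_correct_stack",
    "fit_uniformity_surface",
    "stepc_calibrate",
    "stepc_apply",
    "stepc_apply_frames",
    "detect_bad_pixels",
    "interp_bad_pixels",
    "ring_estimate",
    "ring_apply",
]

STEPC_BASIS = ("1", "S_T", "S_H", "S_T^2", "S_H^2")


def derive_low(total: ProjectionImage, high: ProjectionImage
               ) -> tuple[ProjectionImage, int]:
    """Low-bin counts = Total - High, clipped at zero.

    Returns the low frame and the number of clipped pixels (negative
    differences can only come from noise or detector misbehaviour).
    """
    if total.kind != "counts" or high.kind != "counts":
        raise ValueError("bin subtraction operates on counts frames")
    if total.shape != high.shape:
        raise ValueError(f"shape mismatch {total.shape} vs {high.shape}")
    if total.angle_deg != high.angle_deg:
        raise ValueError("total/high frames are from different angles")
    diff = np.asarray(total.values, dtype=float) - np.asarray(high.values, dtype=float)
    n_clipped = int(np.count_nonzero(diff < 0))
    if n_clipped:
        warnings.warn(f"low-bin subtraction clipped {n_clipped} negative pixels to 0")
    low = ProjectionImage(np.clip(diff, 0, None), bin="low",
                          angle_deg=total.angle_deg, kind="counts")
    return low, n_clipped


def air_correct(obj: ProjectionImage, air: ProjectionImage,
                eps: float = 1.0) -> ProjectionImage:
    """Air (flat-field) correction: P = -ln(I_obj / I_air).

    Both frames are clamped below at ``eps`` counts so zero-count pixels
    (dead pixels, total absorption) stay finite; the clamp value of one
    count is the smallest physically meaningful signal.
    """
    if obj.kind != "counts" or air.kind != "counts":
        raise ValueError("air correction operates on counts frames")
    if obj.shape != air.shape or obj.bin != air.bin:
        raise ValueError("object and air frames must share shape and bin")
    a = np.asarray(air.values, dtype=float)
    if np.all(a == 0):
        raise ValueError("air frame is identically zero: unusable flat field")
    p = -np.log(np.maximum(obj.values, eps) / np.maximum(a, eps))
    return ProjectionImage(p, bin=obj.bin, angle_deg=obj.angle_deg, kind="log")


def air_correct_stack(stack: ProjectionStack, air: ProjectionImage,
                      eps: float = 1.0) -> ProjectionStack:
    return ProjectionStack(air_correct(f, air, eps) for f in stack)


def fit_uniformity_surface(frame: ProjectionImage,
                           good_mask: np.ndarray | None = None
                           ) -> tuple[np.ndarray, np.ndarray]:
    """Fit the ideal smooth detector response as a 2-D quadratic surface.

    Least-squares fit of p(i, j) = c0 + c1*i + c2*j + c3*i^2 + c4*i*j +
    c5*j^2 over good pixels of a log frame; returns (surface, residual)
    where residual = measured - surface is the per-pixel uniformity
    error.
    """
    if frame.kind != "log":
        raise ValueError("uniformity surface is fitted on log frames")
    v = np.asarray(frame.values, dtype=float)
    n_rows, n_ch = v.shape
    if good_mask is None:
        good_mask = np.ones_like(v, dtype=bool)
    if good_mask.sum() < 6:
        raise ValueError("need at least 6 good pixels for a quadratic surface")
    i = np.arange(n_rows)[:, None] * np.ones((1, n_ch))
    j = np.ones((n_rows, 1)) * np.arange(n_ch)[None, :]
    # center/scale coordinates for conditioning; the fitted surface is identical
    i = (i - n_rows / 2) / max(n_rows, 1)
    j = (j - n_ch / 2) / max(n_ch, 1)
    design = np.stack([np.ones_like(i), i, j, i**2, i * j, j**2], axis=-1)
    A = design[good_mask]
    coef, *_ = np.linalg.lstsq(A, v[good_mask], rcond=None)
    surface = design @ coef
    return surface, v - surface


def _stepc_design(s_t: np.ndarray, s_h: np.ndarray) -> np.ndarray:
    """Design rows {1, S_T, S_H, S_T^2, S_H^2} stacked on the last axis."""
    return np.stack([np.ones_like(s_t), s_t, s_h, s_t**2, s_h**2], axis=-1)


@dataclasses.dataclass(frozen=True)
class StepcTable:
    """Per-pixel polynomial coefficients predicting uniformity error.

    ``coeffs[bin]`` has shape (n_rows, n_channels, 5) over the fixed
    basis {1, S_T, S_H, S_T^2, S_H^2}, where S_T and S_H are a pixel's
    air-corrected Total and High log signals.  ``fit_stats[bin]`` is the
    calibration residual RMS.
    """

    coeffs: dict
    fit_stats: dict = dataclasses.field(default_factory=dict)
    basis: tuple = STEPC_BASIS

    def __post_init__(self) -> None:
        for bin, c in self.coeffs.items():
            c = np.asarray(c, dtype=float)
            if c.ndim != 3 or c.shape[2] != 5:
                raise ValueError(f"{bin}: coefficient grid must be (rows, channels, 5)")
            if not np.all(np.isfinite(c)):
                raise ValueError(f"{bin}: non-finite coefficients")
            self.coeffs[bin] = c

    def predict(self, bin: str, s_t: np.ndarray, s_h: np.ndarray) -> np.ndarray:
        """Predicted non-uniformity error for one frame of ``bin``."""
        if bin not in self.coeffs:
            raise KeyError(f"no STEPC coefficients for bin {bin!r}")
        return np.einsum("rck,rck->rc", self.coeffs[bin], _stepc_design(s_t, s_h))

    def save(self, out_dir) -> None:
        """Float32 coefficient grids plus a YAML shape sidecar."""
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        meta = {"basis": list(self.basis), "bins": {}}
        for bin, c in self.coeffs.items():
            c.astype("<f4").tofile(out_dir / f"STEPC_table_{bin}.data")
            meta["bins"][bin] = {"shape": list(c.shape),
                                 "rms": float(self.fit_stats.get(bin, np.nan))}
        (out_dir / "STEPC_table.yaml").write_text(yaml.safe_dump(meta))

    @classmethod
    def load(cls, in_dir) -> "StepcTable":
        in_dir = Path(in_dir)
        meta = yaml.safe_load((in_dir / "STEPC_table.yaml").read_text())
        coeffs, stats = {}, {}
        for bin, info in meta["bins"].items():
            c = np.fromfile(in_dir / f"STEPC_table_{bin}.data", dtype="<f4")
            coeffs[bin] = c.reshape(info["shape"]).astype(float)
            stats[bin] = info.get("rms", float("nan"))
        return cls(coeffs, stats, tuple(meta["basis"]))


def stepc_calibrate(slab_scans: dict, good_mask: np.ndarray | None = None,
                    cond_limit: float = 1e10) -> StepcTable:
    """Fit the STEPC table from an air-corrected slab calibration series.

    ``slab_scans`` maps a scan label (e.g. the (PMMA, Al) thickness pair)
    to ``{bin: log ProjectionImage}``; every scan must include the
    acquired ``total`` and ``high`` bins, and any further bin present
    (e.g. derived ``low``) is calibrated too.  For each scan and bin the
    ideal response is a fitted quadratic surface; the per-pixel residuals
    across scans are regressed on {1, S_T, S_H, S_T^2, S_H^2} by least
    squares.
    """
    labels = sorted(slab_scans)
    if len(labels) < 6:
        raise ValueError(f"need >= 6 slab scans for a 5-term fit, got {len(labels)}")
    bins = set.intersection(*(set(slab_scans[k]) for k in labels))
    if not {"total", "high"} <= bins:
        raise ValueError("every slab scan must include total and high bins")
    shape = slab_scans[labels[0]]["total"].shape
    s_t = np.stack([slab_scans[k]["total"].values for k in labels])  # (S, R, C)
    s_h = np.stack([slab_scans[k]["high"].values for k in labels])
    design = _stepc_design(s_t, s_h)                                  # (S, R, C, 5)
    ata = np.einsum("srck,srcl->rckl", design, design)
    # pixels whose slab signals do not span the basis (e.g. stuck pixels with
    # constant response) have a singular design; they get zero coefficients
    # and are left to bad-pixel interpolation.  Widespread deficiency means
    # the series itself lacks distinct attenuations -> hard error.
    cond = np.linalg.cond(ata.reshape(-1, 5, 5))
    singular = (~np.isfinite(cond)) | (cond > cond_limit)
    n_sing = int(np.count_nonzero(singular))
    if n_sing > 0.005 * cond.size:
        raise ValueError(
            f"rank-deficient STEPC design at {n_sing} pixels: the slab series "
            "does not span enough distinct attenuations"
        )
    if n_sing:
        warnings.warn(f"STEPC: {n_sing} pixels with degenerate slab signals "
                      "get zero coefficients")
    ata_safe = ata.reshape(-1, 5, 5).copy()
    ata_safe[singular] = np.eye(5)
    coeffs, stats = {}, {}
    for bin in sorted(bins):
        resid = np.empty_like(s_t)
        for si, k in enumerate(labels):
            _, resid[si] = fit_uniformity_surface(slab_scans[k][bin], good_mask)
        aty = np.einsum("srck,src->rck", design, resid)
        c = np.linalg.solve(ata_safe, aty.reshape(-1, 5)[..., None])[..., 0]
        c[singular] = 0.0
        c = c.reshape(shape + (5,))
        predicted = np.einsum("rck,srck->src", c, design)
        stats[bin] = float(np.sqrt(np.mean((predicted - resid) ** 2)))
        coeffs[bin] = c
    return StepcTable(coeffs, stats)


def stepc_apply_frames(frames: dict, table: StepcTable) -> dict:
    """Correct one view's frames: corrected = measured - predicted error.

    ``frames`` maps bin -> log ProjectionImage and must contain the
    ``total`` and ``high`` signals the polynomial is driven by.
    """
    if "total" not in frames or "high" not in frames:
        raise ValueError("STEPC needs the paired total and high log signals")
    s_t = np.asarray(frames["total"].values, dtype=float)
    s_h = np.asarray(frames["high"].values, dtype=float)
    out = {}
    for bin, img in frames.items():
        if img.kind != "log":
            raise ValueError("STEPC operates on log frames")
        if bin not in table.coeffs:
            raise KeyError(f"no STEPC coefficients for bin {bin!r}")
        err = table.predict(bin, s_t, s_h)
        out[bin] = img.replace(values=img.values - err)
    return out


def stepc_apply(stacks: dict, table: StepcTable) -> dict:
    """Apply STEPC to paired per-bin stacks (same view ordering)."""
    if "total" not in stacks or "high" not in stacks:
        raise ValueError("STEPC needs paired total and high stacks")
    n = len(stacks["total"])
    if any(len(s) != n for s in stacks.values()):
        raise ValueError("stacks must have matching view counts")
    per_view = []
    for k in range(n):
        per_view.append(stepc_apply_frames({b: s[k] for b, s in stacks.items()}, table))
    return {b: ProjectionStack(v[b] for v in per_view) for b in stacks}


def detect_bad_pixels(stack, lo: int = 5, hi: int = 4090,
                      prior: set | None = None) -> set:
    """Flag pixels with counts below ``lo`` or above ``hi`` in any frame.

    The thresholds are strict: a count of exactly ``lo`` or ``hi`` is
    acceptable.  ``prior`` (pre-identified abnormal or tile-gap pixels)
    is unioned into the result.
    """
    frames = stack if isinstance(stack, (list, tuple, ProjectionStack)) else [stack]
    bad = np.zeros(frames[0].shape, dtype=bool)
    for f in frames:
        if f.kind != "counts":
            raise ValueError("bad-pixel detection operates on counts frames")
        v = np.asarray(f.values)
        bad |= (v < lo) | (v > hi)
    found = {(int(r), int(c)) for r, c in zip(*np.nonzero(bad))}
    return found | (set(prior) if prior else set())


def interp_bad_pixels(frame: ProjectionImage, bad: set) -> ProjectionImage:
    """Replace bad pixels by 1-D linear interpolation along the channel axis.

    Interior runs are bridged linearly between the nearest good
    neighbours; runs touching a row edge take the nearest good value.
    """
    v = np.array(frame.values, dtype=float)
    n_rows, n_ch = v.shape
    by_row: dict[int, list[int]] = {}
    for r, c in bad:
        if 0 <= r < n_rows and 0 <= c < n_ch:
            by_row.setdefault(r, []).append(c)
    for r, cols in by_row.items():
        good = np.setdiff1d(np.arange(n_ch), cols)
        if good.size == 0:
            raise ValueError(f"detector row {r} has no good pixels to interpolate from")
        cols = np.sort(cols)
        v[r, cols] = np.interp(cols, good, v[r, good])
    return frame.replace(values=v)


@dataclasses.dataclass(frozen=True)
class RingErrorMap:
    """Static additive log-domain error map, zero outside its channel window."""

    error: np.ndarray
    window: tuple[int, int] | None = None  # [c0, c1) channel range, None = all

    def __post_init__(self) -> None:
        e = np.asarray(self.error, dtype=float)
        if e.ndim != 2 or not np.all(np.isfinite(e)):
            raise ValueError("ring error map must be a finite 2-D grid")
        if self.window is not None:
            c0, c1 = self.window
            masked = np.zeros_like(e)
            masked[:, c0:c1] = e[:, c0:c1]
            e = masked
        object.__setattr__(self, "error", e)


def ring_estimate(stack: ProjectionStack, M: int = 8,
                  median_kernel: tuple[int, int] = (3, 9),
                  gauss_sigma: float = 10.0,
                  smooth_sigma: tuple[float, float] = (1.0, 3.0),
                  clip_mad: float | None = 3.0,
                  window: tuple[int, int] | None = None) -> RingErrorMap:
    """Estimate the static per-pixel ring error from a log-projection stack.

    Views are split into ``M`` contiguous-angle subsets.  Per subset the
    angular mean is median-filtered (kernel = rows x channels) and then
    Gaussian-smoothed (``smooth_sigma``, rows x channels) to form the
    artifact-free reference -- the median rejects stripe outliers while
    preserving object edges, and the extra blur suppresses the filtered
    noise the median alone would re-inject into the estimate.  The
    difference mean - reference is that subset's error; the pixel-wise
    median across subsets rejects object-edge leakage, and a wide 2-D
    Gaussian blur of that map (``gauss_sigma``, in channels) is
    subtracted as the background bias so only the high-frequency stripe
    pattern remains.  ``clip_mad`` finally clamps the map at that many
    robust standard deviations (median absolute deviation scale):
    genuine stripe errors are small, so large localised map values are
    object-edge leakage, not detector error.
    """
    if stack.kind != "log":
        raise ValueError("ring estimation operates on log stacks")
    if not 1 <= M <= len(stack):
        raise ValueError(f"need 1 <= M <= {len(stack)} subsets, got {M}")
    arr = stack.as_array()
    errors = []
    for sub in np.array_split(arr, M, axis=0):
        p_mean = sub.mean(axis=0)
        p_smooth = median_filter(p_mean, size=median_kernel, mode="nearest")
        if smooth_sigma is not None and max(smooth_sigma) > 0:
            p_smooth = gaussian_filter(p_smooth, smooth_sigma, mode="nearest")
        errors.append(p_mean - p_smooth)
    p_error = np.median(np.stack(errors), axis=0)
    bias = gaussian_filter(p_error, sigma=gauss_sigma, mode="nearest")
    err = p_error - bias
    if clip_mad is not None:
        mad = 1.4826 * np.median(np.abs(err - np.median(err)))
        if mad > 0:
            err = np.clip(err, -clip_mad * mad, clip_mad * mad)
    return RingErrorMap(err, window=window)


def ring_apply(stack: ProjectionStack, ring: RingErrorMap) -> ProjectionStack:
    """Subtract the static ring error map from every view."""
    arr = stack.as_array()
    if ring.error.shape != arr.shape[1:]:
        raise ValueError(f"map shape {ring.error.shape} != frames {arr.shape[1:]}")
    return stack.with_values(arr - ring.error[None])
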