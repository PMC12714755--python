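# Methods

This note documents the models behind `pcct`, the parameters that
matter, the numerical choices, and what the synthetic studies do and do
not demonstrate.

## Forward model

**Geometry.** Circular cone-beam orbit about the z axis: source at
140 mm from the isocenter (SID), flat detector at 325 mm (SDD), detector
rows along z, channels in the rotation plane. The full-scale profile is
2063 × 505 pixels of 0.1 mm with 1440 views at 0.25°; the desk-scale
profile (`ScanGeometry.desk_scale()`) bins the detector to 256 × 64
pixels of 0.4 mm and 180 views so every experiment runs on one CPU in
seconds to minutes. SID/SDD are kept at full scale, so magnification
and cone angle are realistic; the in-plane field of view is ~44 mm and
the axial coverage ~±5.5 mm at the isocenter. Reconstruction grids are
therefore limited axially to the illuminated slices (default
96 × 96 × 24).

**Ray tracing.** Per-material intersection lengths are computed with an
exact Siddon/Amanatides–Woo voxel traversal (numba kernel). A dense
ray-marching oracle at 0.01-voxel steps agrees to <0.5%.

**Spectrum.** Thick-target bremsstrahlung, fluence ∝ (kVp − E) on a
1 keV grid, filtered through 0.5 mm Al by Beer–Lambert. Characteristic
lines are omitted; none of the processing depends on line structure.
The photon budget (total fluence per pixel per view) stands in for tube
current × exposure time, which cannot be recovered from the acquisition
protocol alone; the default of 3200 photons/pixel keeps flat fields —
including gain variation and Poisson spread — inside the 12-bit counter
ceiling of 4096, the same dynamic-range constraint that drove the real
system's exposure choice.

**Materials.** Mass attenuation tables are bundled TSVs generated from
a two-component analytic model: a photoelectric term ∝ E⁻³ plus the
Klein–Nishina incoherent-scatter energy shape, with per-material
coefficients anchored at 20 and 60 keV. Water, PMMA and aluminum are
anchored to standard reference values (water agrees with them to ~1% at
30 and 80 keV); hydroxyapatite is anchored to an elemental-mixture
estimate. Walnut shell (1.20 g/cm³) and pulp (0.95 g/cm³) are
**synthetic stand-ins** — no reference data exist for them — chosen so
the shell is distinctly more attenuating with a mineral-like
photoelectric excess, which keeps the shell/pulp decomposition matrix
condition number near 11 (ill-conditioned enough to amplify noise, well
below the <100 target). Real tables in the same two-column TSV format
can be dropped in.

**Detector.** Two counting thresholds (15/30 keV); Total and High bins
are acquired, Low is derived. Non-uniformity has two components with
deliberately different roles:

- a static multiplicative *gain map* (smooth polynomial field × per-tile
  offsets × per-pixel log-normal jitter). This shifts raw counts — it
  drives saturation, bad-pixel statistics and the derived Low bin — but
  cancels exactly in per-bin flat-field division;
- per-pixel *threshold dispersion* (tile-structured + pixel-level
  comparator offsets, default σ = 1.0 keV per tile and 0.4 keV per
  pixel). A threshold error changes a pixel's spectral acceptance, so
  its count error depends on how much the object has hardened the beam —
  this is what survives air correction, what the STEPC polynomial model
  predicts from the attained signal levels, and what produces ring
  artifacts. A detector model with only multiplicative gain would make
  the entire correction chain a no-op after flat-fielding.

Counting is Poisson; the counter clips silently at 4096. Stuck pixels
read 2 (stuck low) or 4094 (stuck high), both inside the <5 / >4090
detection rule. Charge sharing, pile-up and spectral distortion are not
modelled.

## Correction chain

Order: bin subtraction (counts domain, clipped at zero with a clip
count) → air correction (counts clamped below at 1) → STEPC → bad-pixel
interpolation → ring correction. Each energy bin is corrected
independently.

**STEPC.** For each calibration slab scan the ideal response is a 2-D
quadratic surface fitted over good pixels; the per-pixel residuals are
regressed across scans on the fixed basis {1, S_T, S_H, S_T², S_H²}
(five coefficients, matching the released table shape). Pixels whose
slab signals cannot span the basis (stuck pixels) receive zero
coefficients and are left to bad-pixel interpolation; if more than 0.5%
of pixels are degenerate the series itself is rejected. The correction
is driven by a pixel's own measured signals, so it is *not* strictly
idempotent — re-applying the table to corrected data subtracts the
predicted error again. The meaningful convergence property, which the
tests verify, is that **recalibrating** on corrected slab scans finds
almost nothing left to predict (<20% of the first pass).

**Ring correction.** Views are split into M = 8 contiguous-angle
subsets; per subset, the angular mean is median-filtered (3 rows × 9
channels) and then Gaussian-smoothed (σ = 1 row × 3 channels) to form
the artifact-free reference. The extra Gaussian matters: a median alone
re-injects its own filtered noise into the error estimate at exactly
the spatial frequencies that reconstruct into visible rings. The
pixel-wise median across subsets rejects object-edge leakage, a wide
Gaussian blur (σ = 10 channels) of the map is subtracted as background
bias, and the map is finally clamped at ±3 robust standard deviations
(MAD scale) — genuine stripe errors are small, so large localised map
values are object-edge leakage, not detector error. All parameters are
configurable; none are prescribed by the source protocol. The
correction recovers offset fields whose spectral content lies above the
reference-smoothing cutoff; tile-scale (low-frequency) response errors
are STEPC's job, which is why the two corrections are complementary.

Known limitation: on an ideal detector the chain is a near-exact no-op
for radially smooth objects (<0.3% RMS change on the water cylinder),
but objects with fine texture near the rotation axis (e.g. walnut pulp)
move so little between views that some static texture is misread as
detector error; the perturbation can reach a few percent RMS there.
This is inherent to projection-domain ring estimation.

## Reconstruction and calibration

**FDK.** Standard Feldkamp weighting (cosine pre-weight on the virtual
detector through the isocenter), per-row ramp filtering via the
band-limited spatial kernel FFT'd with zero-padding to the next power
of two ≥ 2× channels (Hann apodisation optional and default), and
voxel-driven distance-weighted backprojection with bilinear detector
interpolation (numba kernel), scaled by half the angular increment.
Output is linear attenuation per mm; on the noiseless water cylinder
the interior mean matches the polychromatic transmission-effective μ
over the cylinder diameter to within ~2% (cupping included).

**TV denoising.** Rudin–Osher–Fatemi model
½‖x − x₀‖² + λ·TV(x), solved with Chambolle's dual projection
iteration at fixed step 1/12 (inside the 3-D stability bound),
default 100 iterations. λ is expressed in the volume's own value units;
the pipeline's default λ = 20 is an HU-domain weight and is rescaled by
μ_water/1000 ≈ 3.5 × 10⁻⁵ when applied to attenuation volumes. Larger λ
smooths more; the solver is deterministic and never increases total
variation in practice.

**HU calibration.** The per-bin scale factor 1000/μ_water is measured
on a reconstructed water cylinder using a narrow core ROI (r < 2.5 mm);
evaluating on the wider interior then exposes genuine beam-hardening
bias (~+20 HU in the Total bin at these conditions) instead of hiding
it in the calibration.

**Ring-power metric.** An axial slice is resampled to polar
coordinates; the metric is the variance over radius of the high-pass
component (Gaussian σ = 4 radial samples) of the angular-mean profile.
Rings are angle-independent, so this isolates their power; the radial
range must be kept inside a radially flat region (the `r_outer`
argument), because a genuine object edge is also angle-independent and
would dominate.

## Spectral analysis

All decomposition algebra runs on normalised attenuation
NA = μ/μ_water × 1000 = HU + 1000, which makes the matrix entries
dimensionless per unit density and pure water's column exactly
(1000, 1000)ᵀ. Densities are reported in mg/cm³ and negative values are
kept (clipping would bias recovery statistics); the fraction of
negative voxels is available as a summary. Decomposition noise
amplification equals the row norms of the matrix inverse, which the
tests verify on white-noise volumes.

Matrix calibration routes, in order of fidelity:

- `md_matrix_from_samples` — from measured per-bin mean HU of pure
  samples with known density (the route the pipeline uses; the
  shell/pulp matrix comes from a *separate* calibration walnut scan so
  recovery tests are not voxel-circular);
- `calibrate_water_hap` / the HAP-rod regression — water region mean
  plus the slope of rod NA against nominal HAP density (the rods are
  modelled as HAP dispersed in a water-equivalent base, so the
  intercept absorbs the base);
- `md_matrix_from_materials` — analytic, from the attenuation tables at
  chosen effective bin energies.

**VMI.** μ_E = (μ/ρ)_water(E)·ρ_water + (μ/ρ)_HAP(E)·ρ_HAP with
cubic-interpolated tables, converted to HU against water's linear
attenuation *at the same energy*. The alternative — a fixed reference
bin — was rejected so that pure water reads 0 HU at every VMI energy,
which is the behaviour users of monoenergetic images expect.

## Study conditions and what the tests show

The desk-scale study conditions are fixed: 256 × 64 detector (0.4 mm
pitch), 180 views over 360°, 96³ phantoms of 0.4 mm voxels,
3200 photons/pixel, slab series {0, 5, 10, 15, 20, 30, 40} mm PMMA ×
{0, 0.5, 1, 1.5, 2, 3, 4, 5} mm Al (56 scans averaged over 600 frames),
flat fields averaged over 1440 frames. Frame averages use the exact
Poisson identity (sum of n counts ~ Poisson(nλ)), neglecting per-frame
counter clipping, which is valid while λ stays below the ceiling.

Passing tests demonstrate internal consistency of the chain under this
generator — they do not certify performance on real detectors, whose
non-uniformity includes mechanisms not modelled here (charge sharing,
pile-up, temporal drift, energy-response tails). The synthetic walnut
reproduces the morphology class (hard shell, irregular kernel, air
pockets) but not real walnut attenuation, and scatter is absent
entirely.

## Degenerate inputs and tie-breaks

Zero-count pixels are clamped to 1 count before the log; negative
Low-bin differences clip to zero with a counted warning; fully-bad
detector rows are a hard error (no 2-D fallback); STEPC-degenerate
pixels get zero coefficients; decomposition matrices with condition
number above 10¹² are rejected as collinear; FDK refuses angular spans
short of 360°. Even-sized grids place voxel centres at half-integer
offsets from the isocenter, so rotational-symmetry comparisons use
whole-array rotations which are exact on that sampling.
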