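# Methods

This note records the model choices, parameter defaults and numerical
conventions behind `nucleomorph`, and what the synthetic phantoms do and do
not emulate.

## Measurement pipeline

A nucleus enters as a calibrated grayscale z-stack (`z, y, x`; pixel size and
z-step in µm, both strictly positive). The stages are deterministic:

1. **Focus plane.** The plane maximizing per-plane intensity variance (ties →
   lowest index). Variance is the simplest deterministic focus proxy; a
   Tenengrad (squared Sobel gradient) score is selectable for images whose
   in-focus plane is texture- rather than contrast-dominated.
2. **Global threshold.** One histogram threshold is computed on the focus
   plane (Otsu by default; isodata/li/mean/triangle/yen selectable) and
   applied to every plane; foreground is *strictly greater* than the
   threshold. Rationale: a per-plane threshold would segment out-of-focus
   planes inconsistently; a single plane-derived threshold treats the stack
   as one object. For discrete histograms the between-class criterion is
   flat across an empty gap, and library implementations return an arbitrary
   end of the plateau; we snap the returned value to the midpoint of the
   histogram gap it falls in. This leaves the partition of the reference
   plane unchanged and makes the propagated threshold canonical — without
   it, a two-level plane (background/shell) would admit a threshold just
   above background, silently including dim structures on other planes.
3. **3D median filter.** Ball neighbourhood, default radius 2 voxels,
   reflected boundaries; radius 0 is the identity. On binary masks the
   median is computed as a strict-majority vote (exactly equivalent for the
   odd-sized ball, much faster than a rank filter). The filter removes
   speckle noise at the cost of erasing structures thinner than ~the ball
   radius; the phantom geometry keeps all true structures above this scale.
   Note the filter is *not* strictly idempotent on curved discrete surfaces
   (it keeps smoothing a voxelised sphere for 2-3 passes before reaching a
   fixed point); a thick slab is exactly invariant.
4. **Labeling.** Connected components at 26-connectivity by default (6/18
   selectable). The object count is recorded, then all objects of the
   nucleus are merged into one composite mask for measurement.

## Shape descriptors

All moments are computed by summation over voxel centres in physical
coordinates (µm), each voxel weighted by its volume; anisotropic z-steps are
therefore handled by coordinate scaling, not voxel counts. There is no
intra-voxel spread term; the discretisation bias this leaves vanishes as
resolution grows and is covered by the analytic-limit tests (2% at the sizes
used).

With volume `V`, covariance `Σ = µ₂/V` (eigenvalues λ₁ ≥ λ₂ ≥ λ₃, µm²):

- `elongation = sqrt(λ₁/λ₂)`, `flatness = sqrt(λ₂/λ₃)` — the radius (square
  root) convention, so both equal 1 for a sphere and flatness is b/c for a
  solid ellipsoid with semi-axes a ≥ b ≥ c. λ₃ = 0 (planar object) reports
  flatness as +inf with a warning rather than failing.
- Scale-normalised moments `µ'_pqr = µ_pqr / V^((p+q+r+3)/3)` give five
  rotation- and scale-invariant descriptors:
  - moment1 = trace of the normalised second-order tensor,
  - moment2 = sum of its principal 2x2 minors,
  - moment3 = its determinant, equivalently det(Σ)/V²,
  - moment4 = full contraction `Σ T_ijk²` of the normalised third-order
    tensor `T = µ₃/V²`,
  - moment5 = squared norm of its vector contraction `Σ_i (Σ_j T_ijj)²`.

  For a solid unit-volume ball moment3 = 9/(2000π²) ≈ 4.56e-4; thin shells
  score roughly an order of magnitude higher (low volume, wide spread),
  which is what makes moment3 informative about envelope staining.

"Moment 3" admits more than one reading across 3D measurement suites
(second-order invariant set vs third-order set); we fix it to the
determinant invariant above and expose the cascade's feature choice in
configuration, so another convention can be swapped in without code changes.
Measurements are taken on the binary mask (the pipeline thresholds before
measuring); an intensity-weighted variant is available through the
`weights` argument of `central_moments`.

## The phenotype cascade

Subtractive selection with control-relative thresholds: at each step the
threshold is `k x mean(feature)` over the **control cells not yet assigned**
by earlier steps; cells meeting the criterion take that step's phenotype and
are removed. Boundary equality meets a "high" criterion (≥) and fails a
"low" criterion (<); this convention is fixed for bit-reproducibility.
Calibration is per replicate by default (a global flag pools replicates),
because absolute feature values shift with imaging conditions while the
control-relative structure does not.

Shipped default steps and multipliers:

| step | feature | direction | k | rationale |
|---|---|---|---|---|
| punctate | object count | high | 3.3 | many disconnected spots; the published multiplier |
| invagination | moment3 | low | 0.42 | interior sheets add compact volume: det(Σ)/V² falls because V grows faster than det(Σ) |
| diffuse | flatness | low | 0.84 | a complete shell stains deep in z (flatness near b/c); the remaining bowl-like classes are flatter |
| ring vs incomplete | moment3 | high | 0.77 | ring higher; a large-gap partial envelope is flatter and more compact, lowering det(Σ)/V² |

The non-published multipliers were fixed once by grid search
(`tune_multiplier`) on a clean labeled reference population with the control
composition below, maximising correctly-identified target cells minus
false positives at each step, midpoint of the optimal plateau; they are
ordinary config values and can be re-tuned on any labeled set. The
invagination step's direction deserves a note: with the determinant
definition of moment3, *adding* interior staining volume to a shell lowers
the invariant, so invaginated envelopes sit at the low end — a "high" rule
would be appropriate only under a different moment-3 convention, which is
why both the feature and direction are configurable.

The reference control composition (per ~32-cell replicate, within the
30-40 cells/replicate design): ring 18, diffuse 8, punctate 2,
invagination 2, incomplete 2 — a mostly-normal control population. The
object-count rule in particular assumes such a population: calibrating the
3.3x rule against a population that is itself 20% punctate inflates the
running mean and weakens the step.

Phenotype→group mapping is fixed: {ring, diffuse} → normal; {punctate,
invagination, incomplete} → abnormal. Percent abnormal is the per-replicate
summary statistic.

## Fluorescence quantification

For a nuclear ROI: `CMNF = mean_nuclear − mean_background` and
`CTNF = integrated_density − area x mean_background` (integrated density is
the nuclear pixel sum). The knockdown gate keeps cells with CMNF strictly
below `fraction` (default 0.5) of the control-group mean CMNF — CMNF rather
than CTNF because it does not depend on nuclear size.

ROIs derive from a nuclear-reference (DAPI) image: Otsu threshold, hole
filling, minimum-area filter (default 30 px). The cytoplasmic ROI is an
annulus from dilating each nucleus by 5 px (configurable) minus all nuclei —
the standard construction when no cytoplasmic marker is imaged; whole-cell
segmentation can be substituted by supplying ROIs directly. Background is
everything outside all cell footprints (nuclei dilated by the annulus radius
plus a 2 px margin); a user-supplied background ROI is accepted as an
alternative. N/C ratios background-correct both numerator and denominator,
making them invariant to global additive offsets and positive rescaling; a
non-positive corrected cytoplasmic mean is an error (undefined ratio), not a
silent NaN.

## Statistics

Two-group comparisons use Student's pooled-variance independent t-test by
default (treatment groups in this design have ≤3 replicates, where a
variance difference is undetectable anyway), Welch as an option, and paired
t-tests for designs where replicates share acquisition settings. One-tailed
variants apply when the treatment has an expected direction. Shapiro-Wilk
per group and a two-tailed variance-ratio F test (df = n₁−1, n₂−1) are
attached to every comparison. No multiple-testing correction is applied;
p-values are per comparison.

## Synthetic phantoms

Geometry (defaults; all configurable per spec):

- Nucleus: ellipsoid, semi-axes 6 x 5 x 4 µm (adherent cells flatten in z),
  shell thickness 0.8 µm, sampled isotropically at 0.25 µm in a 44 x 64 x 64
  stack. Population jitter: overall scale ±12%, per-axis ±4% (axis *ratios*
  stay in a narrow band, as in real nuclei), thickness tracking scale.
- ring: shell at amplitude 200 over background 10, with the top dome cap
  (direction cosine > ~0.45) at 20% intensity — an ideal threshold keeps a
  bowl. diffuse: complete shell at full intensity. punctate: ring base plus
  8-12 interior spheres (r = 0.45 µm) at 1.4x amplitude (bright aggregates),
  placed with clearances that survive blur and median filtering. invagination:
  ring base plus 2-3 vertical planar sheets (0.9-1.2 µm thick) spanning the
  interior, attached to the shell. incomplete: shell missing a top-centred
  solid-angle fraction (default gap 0.55-0.65), leaving a flat partial bowl.
  The gap is deliberately large: an envelope subset with a *small* gap is
  nearly indistinguishable from a ring on second-order moments (removing a
  little of a thin shell *raises* det(Σ)/V²); observable "incomplete"
  phenotypes correspond to envelopes missing a substantial cap.
- Imaging: optional Gaussian PSF (σ in µm) then additive Gaussian read noise,
  clipped at 0. The documented default noise condition is σ_PSF = 0.25 µm
  and noise sd 20 on the 200/10 signal (SNR ≈ 10). Ground truth (mask and
  object count) is always the pre-noise two-level geometry.
- 2D reporter scenes: non-overlapping nucleus disks (r = 8-12 px) with a
  6 px cytoplasm annulus over uniform background, intensities drawn from
  stated ranges; a matching DAPI-like image carries the nucleus disks. True
  N/C ratios follow from the drawn intensities.

What the phantoms do **not** emulate: textured chromatin-dependent staining,
depth-dependent attenuation and PSF anisotropy, shot noise (a Poisson term
is deliberately omitted from the default condition), touching nuclei,
mitotic figures, or partial-cell fields. Passing the recovery tests
therefore demonstrates that the pipeline and cascade are correct and
well-conditioned on idealized single-nucleus data with realistic size
jitter, blur and read noise — not that the shipped multipliers transfer to
any particular microscope; on real data the multipliers should be re-tuned
against a manually labeled replicate, exactly as done here on the reference
population.

Problem sizes in the shipped checks: recovery uses 250-cell balanced
populations (50 per class) calibrated on 3 control replicates (~96 cells);
oracle checks use 50 random 20³ masks; analytic limits use a 16-voxel-radius
sphere and an (8,6,3) µm ellipsoid at 0.2 µm voxels.

## Degenerate inputs and numerical conventions

- Constant focus plane → explicit degenerate-histogram error (no threshold).
- Empty mask after filtering → stage-tagged measurement error.
- λ₂ or λ₃ = 0 → elongation/flatness +inf with a warning.
- A calibration step that removes every remaining control cell → error
  (later steps would be calibrated on nothing).
- Inseparable classes in multiplier tuning (flat, non-positive objective) →
  grid midpoint with a warning.
- Knockdown gating with non-positive control mean → error.
- All thresholds/feature comparisons are float64; CSV output uses %.10g so
  repeated runs are byte-identical.
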