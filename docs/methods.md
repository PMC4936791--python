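# Methods

`fourdose` simulates a planning-study design for lung stereotactic body
radiotherapy (SBRT) on an MR-linac: for each case, four step-and-shoot IMRT
plans are created on the peak-exhale phase of a breathing cycle — two target
strategies (conventional ITV-based and tracking-oriented MTV-based), each
optimized with and without a 1.5 T magnetic field — delivered in silico to
all breathing phases, accumulated back onto the reference anatomy, and
compared by paired dose-volume statistics. Everything runs on a synthetic 4D
thorax phantom with analytically known motion, so no image registration is
involved and every geometric transform is exact by construction.

## The 4D phantom

The phantom emulates a 10-phase 4DCT: a soft-tissue body ellipsoid
(densities: air 0.001, lung 0.26, soft tissue and tumor 1.0 g/cc), two lung
ellipsoids, a spherical tumor inside one lung, a 5 mm outer skin shell, and a
mediastinal great-vessel cylinder. The default grid is 96x96x80 voxels at
2.5 mm isotropic spacing — the resolution the doses are evaluated on, chosen
so a full four-arm case simulates in about a minute on one CPU. This is
deliberately coarser than a clinical CT; it is a study of the *pipeline's*
comparative behavior, not of absolute patient dosimetry.

**Breathing model.** The tumor centroid displacement per axis is
`A * (1 - cos^2(pi p / n))` over phases `p = 0..n-1`: zero at phase 0
(peak-exhale, the reference used for planning and accumulation, chosen
because it is the most reproducible part of the cycle) and peaking at
mid-cycle with peak-to-peak amplitude `A`. The default amplitude vector
(1.0, 1.5, 5.4) mm has a 5.7 mm 3D magnitude, dominated by the
superior-inferior component as is typical for lower-lobe lung tumors.
Hysteresis, irregular breathing and cardiac motion are not modeled.

**Deformation fields.** Each phase's deformation is a rigid tumor
translation inside a C^1 smoothstep envelope around the tumor rest position
(plateau radius = tumor radius + maximum displacement + 2 mm, decaying to
zero over a further 15 mm, clipped to the lungs, zero elsewhere). The stored
field per phase maps reference-phase coordinates to that phase — the
pull-back direction that direct dose mapping needs — and is identically zero
for the reference phase. Because the tumor sits on the envelope plateau, the
tumor region deforms exactly rigidly and warping any phase GTV through its
field recovers the reference GTV up to voxelization.

**Cohort sampler.** Tumor volumes are drawn uniformly from 3.3-25.5 cc and
3D peak-to-peak motion from 1.5-14.1 mm (the span of a typical lung SBRT
cohort), with a predominantly superior-inferior, randomly tilted motion
direction. Seeded and fully reproducible.

## Targets

The ITV is the voxelwise union of the per-phase GTV masks; the MTV shifts
each phase's GTV by the (whole-voxel-rounded) centroid difference onto the
reference centroid before the union, capturing only residual deformation
since tracking compensates the translation. Boolean masks are never
resampled sub-voxel: centroid shifts round to the nearest voxel (error
bounded by half a voxel) to avoid interpolation-induced mask erosion. One
consequence is that with purely rigid but sub-voxel motion the MTV is a few
voxels larger than the reference GTV, because the voxelization of a sphere
depends on its sub-voxel position. Both targets are expanded by an isotropic
5 mm setup margin using an exact Euclidean distance transform ("isotropic
margin" taken literally, rather than a structuring-element approximation)
to form the PTVs.

## Machine model

An MR-linac treatment head: 7 MV beam, MLC with 80 leaf pairs of 7.15 mm
isocenter-projected width, collimator fixed at 90 deg (IEC-61217), maximum
field 272.0 mm along leaf travel and 571.5 mm along the leaf stack. (The 80
pairs x 7.15 mm = 572.0 mm slightly exceed the stated perpendicular maximum;
the 571.5 mm limit is enforced as a clamp, so the outermost rows are never
fully usable.) With this collimator angle the leaf stack runs
superior-inferior — parallel to the magnetic field and to the dominant tumor
motion, the conservative case for resnapping. The beams-eye-view projection
is parallel (non-divergent); tracking only needs rigid BEV translations, for
which divergence is a second-order effect at lung depths, and no
source-axis distance is assumed beyond a configurable default of 1000 mm.
The cryostat is reduced to an optional scalar transmission per gantry angle
(default 1.0).

## Dose engine

A kernel engine stands in for a Monte-Carlo calculation. Its contract is the
set of qualitative signatures the comparison rests on, not absolute
dosimetric accuracy; all parameters are configurable so a stronger engine
can replace it behind the same interfaces.

* **Fluence**: per segment, the aperture indicator on the BEV grid with
  fractional voxel coverage, blurred by a Gaussian penumbra (sigma 3 mm).
* **Depth dose**: `(1 - exp(-d/5mm)) * exp(-0.0046/mm * d)`, normalized to 1
  at its maximum (~19 mm water) — a 7 MV-like curve with buildup and
  sub-percent-per-mm falloff. Depth `d` is the radiological (density line
  integral) depth along the parallel beam.
* **Beam frame**: all per-beam work happens in a resampled frame with the
  beam along one array axis, produced by an involutory affine map (exact at
  gantry angles that are multiples of 90 deg; trilinear elsewhere).
  Near-zero matrix entries are snapped to zero so axis-aligned cases are
  bit-exact.
* **Deterministic by default**; a stochastic mode multiplies each voxel by
  independent Gaussian noise (sigma 2%, seeded) to mirror Monte-Carlo
  statistical uncertainty in robustness tests.

**Electron return effect (ERE).** In a 1.5 T superior-inferior field the
Lorentz force returns secondary electrons at tissue-to-air interfaces.  The
surrogate acts ray-by-ray along the beam:

* at a density *drop* larger than 0.3 g/cc per voxel (tissue -> air/lung
  exit), a fraction alpha = 0.35 of the dose in the downstream low-density
  run (up to 20 mm) is removed and re-deposited in the last high-density
  voxel, half of it displaced 4 mm laterally along `d x B`;
* at a density *rise* (entry), dose from the interior of the buildup region
  (up to 5 mm, the secondary-electron gyration scale at 1.5 T) is moved onto
  the first dense voxel — the entrance/skin hot spot and the shortened
  effective buildup.

Both moves conserve integral deposited energy (rho x dose x volume) exactly;
lateral deposits fall back to the source voxel at the grid border or where
the neighbor is much less dense. With B = 0 the perturbation is skipped and
the baseline engine is reproduced bit for bit; B-on and B-off doses of the
same plan differ only inside the flagged interface neighborhoods. alpha and
the displacement are tuned surrogate parameters (they produce skin-D2
increases of a few Gy on 54 Gy plans on the default phantom), not physical
constants.

## Planning

Per beam, a conformal aperture (with a 5 mm isotropic BEV block margin, about
1.7 penumbra sigmas, so the 50% fluence level does not sit on the PTV
surface) plus two concentrically shrunken sub-apertures provide the
optimizer's degrees of freedom. Segment weights minimize a one-sided
quadratic penalty — underdose below 54 Gy on the PTV (weight 1), overdose
above a 58 Gy ceiling on the PTV (weight 1, realizing "similar maximum
target dose" across plans), and overdose penalties on lungs, skin, vessels
and body — by projected gradient descent (zero initialization, step 1/L from
a power-iteration curvature bound, 500 iterations, deterministic). OAR
voxels are subsampled (seeded) with inverse-probability weight scaling; PTV
voxels are all kept. The influence matrix is computed with the plan's own
field configuration, so the magnetic field is genuinely inside the
optimization loop, and the four arms are optimized independently.

Each plan is then normalized so D95(PTV) = 54 Gy (3 fractions) on its own
planning-phase dose; by linearity of the deterministic engine this is an
exact rescaling. A configurable constraint table (defaults: GTV V54 = 100%,
R50 <= 6, skin D2 <= 40 Gy, mean lung dose <= 8 Gy — placeholders in the
spirit of lung-SBRT guidelines, not authoritative values) is evaluated per
arm; violations are reported as warnings, never fatal, since on this small
phantom geometry the generic lung-dose bound is genuinely exceeded for large
targets.

## Tracking

Tracked deliveries translate every segment by the tumor's BEV displacement
per phase, using the phantom's analytic centroids (perfect localization; no
leaf-speed or latency limits). The leaf-travel component is continuous and
exact (clamped at the field limit with a logged warning). The stack
component `s = (k + f) * leaf_width` resnaps to the leaf grid: row `i` takes
the `(1-f)/f`-weighted interpolation of source rows `i-k` and `i-k-1` when
both are open; a single open source row is copied iff its overlap fraction
is at least one half, else the row closes. The rule is the identity at zero
shift, an exact permutation at whole-leaf shifts, and deterministic; a
nearest-row snap is available as a sensitivity switch.

## Accumulation and metrics

Direct dose mapping: each phase dose is pulled back to the reference grid by
trilinear interpolation through the known deformation field and averaged
with weight 1/n_phases (0.1 for 10 phases). No mass- or energy-transfer
correction is applied — the known caveat of direct mapping is accepted, as
the fields here are smooth and modest.

`Dx` is the maximum dose level received by at least x% of a structure's
voxels (pure voxel-count percentile, lower interpolation — exact and
oracle-checkable; no volume interpolation). Integral deposited energy is
`sum_i rho_i D_i V_i` in joules. The skin is the outermost 5 mm body shell.
R50% is the ratio of the volume receiving at least half the prescription to
the PTV volume.

## Statistics

For each endpoint, four paired contrasts are formed (field effect within
each strategy; tracking effect at each field strength). The four primary
endpoints — GTV D98, skin D2%, mean lung dose, integral energy — are tested
with a two-sided paired t-test at the Bonferroni level 0.05/4 = 0.0125; all
other endpoints are exploratory at 0.05. Normality of the differences is
checked first with the Lilliefors test, whose p-value is obtained by seeded
Monte Carlo (default 10,000 standard-normal samples of the same size) rather
than lookup tables, for exact small-n behavior. Non-normal endpoints are
flagged but still t-tested; a Wilcoxon signed-rank p can be added as a
sensitivity analysis. The tracking benefit is regressed (OLS, with Pearson
r) on the per-case peak-to-peak motion amplitude; the regression requires at
least three cases with non-degenerate motion spread.

## What the synthetic conditions do and do not show

The phantom reproduces the *mechanisms*: interface hot/cold spots under the
field, target-volume inflation by motion under the ITV strategy, and
motion-proportional healthy-tissue sparing by tracking with preserved GTV
coverage. It does not reproduce patient-specific numbers: real thoraxes have
heterogeneous lungs, ribs, hysteresis motion, registration uncertainty and a
Monte-Carlo dose engine, so the absolute endpoint values here (e.g. integral
energies of ~10 J and skin-D2 shifts of 2-4 Gy) characterize the phantom and
the surrogate engine, not a clinical cohort. Passing tests demonstrate the
pipeline's internal consistency and the directional physics, not clinical
dosimetric accuracy.

## Numerical choices and degenerate inputs

* Zero motion collapses the design: ITV = MTV, tracked = conventional,
  accumulation = the single-phase dose — used as an end-to-end identity test.
* Zero-variance paired differences make the t-test degenerate; this is
  flagged, not raised.
* Normalization fails loudly on a zero D95; optimization fails on an
  all-zero influence matrix.
* All randomness (cohort sampling, OAR subsampling, Lilliefors Monte Carlo,
  stochastic engine noise) flows from explicit seeds; deterministic runs are
  bitwise reproducible.
* Problem sizes used in the shipped checks: the default 96x96x80 grid for
  single-case and 5-case cohort simulations; 48x48x40 at 5 mm for
  end-to-end identity tests.
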