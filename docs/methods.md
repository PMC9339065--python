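# Methods

`petprc` implements positron-range-corrected ordered-subset EM (OSEM)
reconstruction for small-animal 82Rb PET, together with the digital
phantoms, acquisition simulator, respiratory gating and NEMA NU-4 metric
suite needed to evaluate the correction without scanner data. This note
documents the models, their assumptions, the tunable parameters, and the
numerical choices; everything quantitative stated here is computed by the
test suite or `scripts/acceptance.py`.

## The annihilation kernel

82Rb emits high-energy positrons (endpoints 3.38 MeV at 81.8% branching
and 2.60 MeV at 13.1%), so the decay-to-annihilation distance — the
positron range — is the dominant resolution loss at rodent scale; the
accepted mean 3D range in water is 7.5 mm. The range blur is modeled as
an annihilation point-spread function (aPSF), the density of annihilation
sites per unit volume at radius `r` from the decay:

    aPSF(r) = C * [ (a*r + 1) * (1 - r/r0)^n - eps / r^n ] / r^2

clamped at zero where the bracket is negative and identically zero beyond
the maximum range `r0`. `C` normalizes the 3D integral to one. The
parameters are not prescribed; they are obtained by fitting this form to
a Monte Carlo reference profile (below). Fits are least-squares on the
radial mass density `4*pi*r^2*aPSF(r)` (finite at the origin and evenly
scaled across the profile), with positivity enforced through log
parametrization.

### Monte Carlo reference

The reference annihilation profile in water is generated by a simplified
condensed-history transport (`kernels.sample_rb82_displacements`):

1. kinetic energy sampled from the allowed-shape beta spectrum
   `N(T) ~ p*E*(Q-T)^2` of the two dominant branches (the Fermi function
   is neglected);
2. the energy is converted to a water path length by the Katz–Penfold
   CSDA range–energy relation, scaled by a single calibration factor
   `PATH_SCALE = 1.4451`;
3. the track is walked in 16 equal segments; at each segment the
   direction receives a Gaussian Highland multiple-scattering deflection
   evaluated at the energy remaining at that depth (water radiation
   length 361 mm);
4. the displacement is the end-of-track position, where the thermalized
   positron annihilates.

Multiple scattering is essential, not cosmetic: a straight-path
transport yields a `1/r^2` cusp whose planar spread is narrower than the
scanner resolution, i.e. an 82Rb system that would not actually be
range-limited. The segmented walk produces the broad-core,
long-tailed kernel (planar FWHM ≈ 4 mm) that makes uncorrected 82Rb
imaging infeasible at rodent scale — the premise of the whole method.
`PATH_SCALE` is the single calibrated constant; it absorbs the neglected
range straggling, hard collisions and annihilation in flight, and is
fixed so the mean 3D displacement in water equals 7.5 mm. Everything
else is standard transport physics with published constants.

### Density scaling and spatially variant kernels

Tissue scaling uses the water-equivalent distance `r_eq = r*rho/rho_ref`
(densities relative to water), which makes the mean range scale exactly
as `1/rho`. Discrete kernels integrate the aPSF over voxel cells; the
center cell integrates the radial mass over the half-voxel sphere, which
absorbs the `1/r^2` singularity exactly. Weights outside the fixed
stencil (21 or 41 voxels, following the naming convention "TDSV 41") are
discarded and the stencil renormalized.

Two correction models are provided:

* **TD (tissue-dependent)**: the density map is segmented into 1–3
  classes (water; air/water; lung/water/bone with thresholds 0.5 and
  {0.6, 1.4} g/cm³ and nominal class densities 0.0012/0.3/1.0/1.9);
  each class's voxels are spread with that class's uniform kernel.
* **TDSV (tissue-dependent spatially variant)**: each source voxel
  spreads with a kernel evaluated, offset by offset, at the
  length-weighted mean density of the voxels crossed by the straight
  segment from source to target (`kernels.ray_mean_density`, exact
  plane-crossing traversal, outside-grid voxels counted as air).

### The fast spatially variant operator

A literal per-voxel TDSV spread costs `n_vox * 41^3` operations per
application and OSEM applies the blur ~1300 times per 40-iteration run;
that is unusable on one CPU. The reconstruction operator
(`blur.VariantSuperpositionBlur`) therefore expands the source–target
pair over the density levels present in the map: the kernel between
level-`j` sources and level-`l` targets is the stationary kernel at
density `(rho_j+rho_l)/2`, combined with per-level interpolation masks —
`K^2` FFT convolutions (K ≤ 4) plus an exact per-source renormalization
that conserves activity. Raw (unnormalized) voxel-integral stencils are
used so the relative magnitudes across density pairs match the exact
ray-mean kernel's construction. On a homogeneous map the operator reduces
exactly to the TD kernel; across boundaries it is an endpoint
approximation of the ray mean, validated against the literal
implementation (`blur.ExactVariantBlur`, available in reconstruction via
`ReconConfig(tdsv_exact=True)`) on small grids: same mass, same
asymmetry direction (more spread into the less dense side), voxelwise
correlation >0.95 at tissue-realistic contrasts. The approximation is
crudest for paths that cross a third tissue between unlike endpoints.

## Acquisition simulation

The forward model applies the range blur in image space (decay →
annihilation), projects with a stacked-2D parallel-beam projector,
attenuates (`mu_water = 0.0096/mm` at 511 keV, scaled linearly with
density), adds an optional Gaussian detector-resolution blur in
projection space (default FWHM 1.6 mm, Inveon-class), scales the
expected sinogram to the requested count total and draws Poisson counts
from a single seeded generator.

Two choices deserve emphasis:

* **The truth blur is physical, the correction blur is the model.** The
  `aPSF(r_eq)` rule places annihilation density at the equivalent
  distance regardless of what is locally there — evaluated literally, it
  deposits annihilations *inside air*, and a simulated NEMA phantom then
  reconstructs its air chamber hotter than the uniform region, which is
  physically impossible. The simulator's ground truth therefore weights
  each target voxel by `rho_local * rho_ray^2 * aPSF_water(r*rho_ray)`
  (annihilation probability per unit path proportional to local
  density), while the TD/TDSV correction operators inside OSEM keep the
  plain `aPSF(r_eq)` form. Truth and correction model thus differ, as
  they do in reality.
* **The truth stencil covers the full range.** Correction kernels are
  truncated at 21/41 voxels by convention, but truncating the *truth*
  folds far-flung annihilations (e.g. positrons crossing into
  lung-density material, where the range stretches by `1/rho`) back
  toward the source and makes the simulated data sharper than physics
  allows. The truth stencil is sized to `3*r0` (capped at 151 voxels);
  FFT evaluation makes the cost insensitive to stencil size.

The projector is a per-slice sparse matrix (pixel-driven with 2×2
subpixel sampling and linear radial-bin interpolation, weights in mm of
path). Forward and back projection share the matrix, so the pair is an
exact adjoint by construction — the property OSEM's convergence relies
on.

## Reconstruction

Standard multiplicative OSEM over angle-interleaved subsets processed in
bit-reversed order; with one subset it is exact MLEM and the Poisson
log-likelihood is non-decreasing. With PRC enabled the system operator
is `att * P(B x)` and the update uses the exact transpose `B^T P^T`
(matched pair). Sensitivity images are precomputed per subset; voxels
below 1e-6 of the peak sensitivity are masked. The expected-data ratio
is floored at 1e-8 of the subset maximum so bins with stray counts but
(near-)zero model support cannot overflow the float32 pipeline. The
iteration count is the stopping rule; no convergence test is performed,
matching the 1–100 iteration sweep methodology. Reconstruction runs in
float32 with cached kernel FFTs; the functional `prc_blur` API uses
float64, and `osem(..., dtype=np.float64)` provides an exact-arithmetic
path for oracle comparisons.

## Phantoms

All phantoms rasterize geometric primitives with the center-of-voxel
membership rule (deterministic for a given voxel size), on grids with
the voxel-center world convention `world = origin + index*voxel_size`.

* **NEMA NU-4 image quality**: standard dimensions — 30 mm ⌀ × 50 mm
  water body; 20 mm rod section with five fillable rods (⌀ 1–5 mm on a
  7 mm radius) in cold solid; 15 mm uniform hot section; 15 mm section
  with two 8 mm ⌀ cold chambers (one water, one air). Analysis ROIs per
  the standard: 22.5 mm ⌀ × 10 mm uniform ROI, 4 mm ⌀ × 7.5 mm cold
  ROIs, per-rod ROIs of twice the rod diameter over the central 10 mm.
* **Two-compartment cardiac phantom**: an LV analog (annulus, 3 mm hot
  wall) and an RV analog (crescent, 2 mm hot wall, 3 mm cold lumen)
  inside a 50 mm ⌀ cylinder of density 0.4 g/cm³ emulating lung-like
  surroundings. The compartment dimensions beyond the wall thicknesses
  are package defaults: the chamber is modeled at phantom scale
  (LV lumen 16 mm ⌀, outer chamber ≈ 32 mm ⌀), i.e. a 3D-printed insert
  occupying a substantial fraction of the cylinder rather than a
  literal rat heart. This choice is deliberate: with a lumen small
  compared with the ~4 mm kernel core, the uncorrected wall profile has
  no measurable peak at all (the lumen fills in completely), whereas
  the reference measurements demonstrate a measurable uncorrected wall
  width — which pins the lumen-to-range ratio even though the chamber
  drawings carry no dimensions. All radii are module constants and
  configurable.
* **Rat thorax**: ellipsoidal-shell myocardium (hot, water density)
  around a cold blood pool, between lung fields (0.3 g/cm³), a spine
  insert (1.9 g/cm³) and soft tissue (1.0 g/cm³). Respiration is rigid
  axial translation of the whole heart by `A*sin(2*pi*phase)` with
  A = 2 mm (the dominant respiratory component). The optional infarct
  zeroes activity in an anteroapical wedge (±45° of azimuth about the
  anterior direction, apical half — exactly 1/8 of the shell).

What the phantoms do **not** emulate: anatomical realism (no rat atlas),
cardiac contraction (ECG gating is out of scope), intra-bin motion
(gated bins are frozen at midpoint phases), scatter and randoms. Passing
tests therefore demonstrate the correction's behavior under controlled
range blur, attenuation, detector blur and Poisson noise — not
performance on real scanner data.

## Respiratory gating

Equal-width phase bins (default 4) with midpoint representative phases;
each bin's acquisition is simulated from the phantom frozen at that
phase with `counts/n_bins` expected events and an independent child seed,
so the count partition is exact. Bins are reconstructed independently
with a shared configuration and summed voxelwise.

One consequence worth stating plainly: summing the reconstructed bins
*without realignment* (the standard workflow this package follows)
retains the frames' positional spread, so the summed image's wall width
does not beat the ungated reconstruction of the same events. The
resolution benefit of gating lives in the individual quasi-static
frames, whose wall widths are motion-free; the practical benefit of the
sum is artifact behavior (each reconstruction fits self-consistent
data), not FWHM. The gating tests measure exactly that: per-frame wall
width versus the ungated reconstruction.

## Metrics

* `%SD` = population SD / mean over the uniform ROI (ddof = 0; stated
  because the reporting convention is often left implicit).
* `SOR` = cold-ROI mean / uniform mean; its uncertainty is the relative
  SD of the cold-ROI voxels.
* `RC` = mean of per-slice transaxial maxima along the rod axis /
  uniform mean; its uncertainty combines the relative SD of the maxima
  with the uniform %SD in quadrature.
* Line profiles are trilinear interpolations at uniform steps; FWHM/FWTM
  locate half/tenth-maximum crossings by linear interpolation after
  subtracting a pedestal equal to the mean of the two minima flanking
  the peak (wall profiles sit on a spillover base). An optional
  `search_region` bounds the crossing search so that, on a profile with
  several structures, the measurement cannot walk across the lumen into
  the opposite wall.
* Cardiac wall widths are measured on `radial_wall_profile`: the radial
  profile from the LV axis averaged over the RV-free azimuth sector
  (100–260°) and ±4 mm axially. A single line through a 40-iteration
  OSEM image is speckle-dominated (apparent "widths" of 1–2 mm noise
  spikes); the chamber is axisymmetric, so azimuthal averaging recovers
  the physical width without smoothing the image itself.
* The Butterworth post-filter is zero-phase in the frequency domain,
  gain `1/sqrt(1+(f/fc)^(2*order))` on the 3D radial frequency, with the
  cutoff expressed as a fraction of the Nyquist frequency (0.2 means
  0.2·f_N — the convention of the clinical analysis software the filter
  settings come from).

## Problem sizes and runtime

The bundled studies are scaled to desk hardware while keeping the
physics conditions (0.4–0.5 mm voxels, 16 subsets, 40 iterations,
1.6 mm detector blur, spatially variant truth blur): cardiac
96×96×48 @ 0.4 mm with 96 angles and 6e6 counts; NEMA 68×68×104 @ 0.5 mm
with 64 angles and 4e9 counts (a ~50 MBq, 10-minute phantom acquisition
is count-rich — order 1e9 trues — and the rod metrics, which take
per-slice maxima, are noise-inflated if simulated orders of magnitude
below that); thorax 38×34×36 @ 1 mm with 48 angles. A TDSV-41
40-iteration reconstruction of the cardiac study takes a few minutes on
one CPU; the Poisson count level does not affect reconstruction time.

## Known limitations

* The superposition TDSV operator approximates ray-mean densities by
  source/target level pairs; it is exact on uniform maps and weakest
  where a path crosses a third tissue.
* Scatter, randoms, prompt gamma and dead time are not simulated; the
  attenuation model is mono-energetic narrow-beam. Absolute noise and
  spillover levels therefore differ from scanner data; orderings between
  correction modes are the meaningful output.
* The condensed-history transport has no range straggling or
  annihilation in flight; `PATH_SCALE` absorbs these in the mean. The
  kernel *shape* beyond its mean and gross width is therefore only as
  good as the Highland model.
* The matched-adjoint OSEM pair is a choice; implementations with
  unmatched pairs converge at different speeds, so absolute
  iteration-by-iteration comparisons with other software are not
  meaningful (iteration sweeps within this package are).
* The deconvolved wall's tenth-maximum width approaches the
  detector-limited floor (~4.6 mm for a 3 mm wall under 1.6 mm detector
  blur) because the simulation lacks the residual-tail physics of real
  acquisitions (scatter, registration error, kernel-form mismatch).
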