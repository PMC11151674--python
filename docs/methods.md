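# Methods

## Model

A diffraction measurement at wavelength λ sees each reflection attenuated by
the material it traverses.  Treating the segmented tomogram as the ground
truth for the sample's composition, the absorption correction factor of
reflection **h** is the volume-averaged transmission over the diffracting
(crystal) voxels exposed to the beam:

    A_h = (1/N) Σ_n exp( − Σ_m μ_m (L1_n^m + L2_n^m) ),   A_h ∈ (0, 1],

with per-material linear absorption coefficients μ_m (µm⁻¹) and per-voxel
incident/diffracted path lengths L1, L2 (µm) through material m.  Scaling
divides observed intensities (and their sigmas) by A_h.  The model assumes:

* the segmentation is correct and every voxel is exactly one material;
* a top-hat beam (uniform inside a rectangular footprint, zero outside) and
  no beam divergence, refraction or multiple scattering;
* absorption only — Lorentz/polarization/decay corrections are downstream;
* μ is constant per material at the experiment's wavelength.  Away from
  absorption edges μ scales ≈ λ³, which `MaterialCoefficients.
  rescaled_to_wavelength` implements (1.0 Å → 4.13 Å gives a ≈70× increase).

## Coordinate conventions

Volumes are `labels[z, y, x]` with isotropic voxel edge h; the model-frame
origin is the grid centre, which is also the rotation centre and the point the
beam axis passes through (the user is responsible for this registration when
importing real tomograms).  The lab frame defaults to beam along +z, scan
(ω) axis +y, a kappa axis tilted 50° from ω in the y–z plane, and φ parallel
to ω at κ = 0; all axes are configurable.  Rotations are active and
right-handed, composed as M = R_ω·R_κ·R_φ.  Because the tomogram is acquired
at κ = φ = 0, beam vectors are mapped into the model frame with Mᵀ rather
than rotating the volume — O(1) work per reflection instead of O(voxels).
Degrees at all interfaces, radians internally.

## Ray tracing

Path lengths are computed by an incremental grid traversal (Amanatides–Woo
DDA) that advances the exact parametric crossing of every voxel boundary and
accumulates length-in-cell per label — not by fixed-step sampling.  Summed
segment lengths therefore equal the analytic origin-to-exit distance to
~1e-15 relative, which the tests assert at 1e-6.  Rays for absorption
factors originate at the crystal-voxel *centre*; L1 is traced anti-parallel
to the incident beam (voxel → source), L2 along the diffracted beam.  When a
ray passes exactly through an edge or corner, all tied axes advance together
(the degenerate cell contributes zero length), so the result is independent
of axis order.  Outside the grid is vacuum; generated volumes are padded
with ≥ 1 vacuum voxel so every exit is well defined.  For real, cropped
tomograms the path is measured to the bounding-box exit: absorption by
material outside the field of view is not modelled.  All arithmetic is
double precision; kernels are numba-JIT-compiled.

## Crystal-voxel selection and systematic sampling

Crystal voxels are sorted lexicographically by (z, y, x) index, filtered by
the top-hat discriminator (voxel centres rotated to the lab frame by the
forward setting matrix), and every `interval`-th survivor (default 2000,
first index 0) is evaluated; A_h is the unweighted mean over the selected
voxels, systematic sampling of a sorted list being self-weighting.  An
un-illuminated reflection raises an explicit error rather than returning a
silent A_h.

A property of this estimator worth knowing: on lattice-aligned synthetic
solids the stride can become commensurate with the raster run lengths, in
which case the selected voxels collapse onto a sparse sublattice and the
sampled mean degrades badly (errors can exceed 100% for a cube whose edge
divides the interval).  Real segmented crystals have irregular row lengths
and do not show this degeneracy, but validation phantoms must avoid
commensurate dimensions (see below).  The sampling error also scales like
(number of sampled voxels)^(−1/2); with ~10⁴ samples it sits below the
voxelization-scale error, with only a few hundred it dominates.

## Absorption-coefficient estimation

Flat-field-corrected projections give per-pixel transmissions T = I/I₀.  The
segmented model is forward-projected with the same ray tracer (parallel beam
along +x at stage angle 0, rotation axis z, detector pixel = voxel size),
yielding per-material chord images that are exactly consistent with the
model.  Then:

1. **Mother liquor.**  Solvent-only pixels (positive liquor chord, zero
   chord through everything else) are eroded by a square structuring element
   of radius `shrink_px` (default 3 px) to drop phase-contrast fringes at
   material boundaries; of the survivors, pixels with liquor chords at or
   above the 50th percentile (computed over that same set, ties included)
   are kept, and μ_liquor = median(−ln T / L).
2. **Further materials.**  For a target material, pixels with a positive
   target chord whose other positive-chord materials all have known μ give
   μ_target = median((−ln T − Σ μ_m L_m) / L_target).  Isolated negative
   numerators are tolerated (expected under noise for short chords); a
   negative *median* numerator raises, flagging inconsistent inputs.
3. Loop coefficients are normally supplied from a per-beamline library of
   empty-loop measurements rather than estimated.

The median is robust: contaminating 10% of the selected pixels with 2×
darkening moves the estimate by < 1%.  Estimation is per projection; users
may median across stage angles.  The synthetic-projection generator inverts
this pipeline (T = exp(−Σ μ L), optional multiplicative Gaussian noise with
fixed seed).  Because generator and estimator share the forward projector,
noiseless round trips are exact to machine precision — passing them shows the
estimator's selection/median logic is right, not that registration errors,
contrast-transfer effects or beam hardening in real tomograms are handled
(they are out of scope).

## Oracles

The reference transmission factor A*(μR, 2θ) is computed on the *analytic*
solid with *analytic* chord lengths — no voxels — so it shares no code path
with the engine.  The validation geometry fixes the incident beam along +x
and rotates the diffracted beam by 2θ about z.  Both beams are then
perpendicular to z, so cube (beam ⊥ face) and cylinder (axis ∥ z) chords are
independent of z and the volume integrals reduce exactly to 2D integrals
over the square / disk cross-section; the disk uses polar and the sphere
spherical (r, cos θ, φ) midpoint quadrature so the integrand lives on a
rectangular domain and the rule converges cleanly (doubling the resolution
moves the sphere value by ~3e-5 at n = 256, the working resolution).  A
rejection-sampling Monte-Carlo evaluator provides a second, independent
scheme; the two agree to < 1e-3 in the tests.  Lengths are expressed in
units of the characteristic length R (sphere/cylinder radius, cube
half-edge), so A* depends only on μR and 2θ.

## Validation protocol

`validate_raytracer` voxelizes a shape at 0.3 µm (the tomography pixel size
of the instrument), runs the production pipeline at sampling interval 2000,
and tabulates |A_engine − A*|/A* over μR ∈ {0.1, 0.5, 1, 2} and 2θ ∈
{0, 30, 60, 120, 150, 180}°.  The shape dimensions are set at the scale of
real long-wavelength samples (tens to hundreds of µm), which also gives the
sampled-voxel counts (~10⁴) the interval-2000 estimator needs:

* cube: 90.3 µm edge = 301 voxels (odd, so the stride is not commensurate
  with the raster rows);
* cylinder: 15.15 µm radius — a 30 µm-wide rod, like rod-shaped membrane-
  protein crystals — with length 600 µm = interval × voxel size, so the
  systematic sample visits every cross-section position exactly once and the
  sampling is exactly self-weighting;
* sphere: 45 µm radius (90 µm diameter, a typical blocky-crystal size).

Measured maxima: cube 0.42%, cylinder 0.27%, sphere 0.59% (2θ = 90°
excluded for the sphere, where the discrepancy is known to be larger; the
suite logs it without asserting).  Halving the voxel linear density (0.6 µm
vs 0.3 µm) strictly increases every shape's maximum error, and full
enumeration vs interval 2000 changes A_h by less than the validation bound
(checked on 2θ ∈ {60, 150}°, μR ∈ {0.5, 2} for all three shapes — the full
sweep at interval 1 would trace several hundred million rays for no extra
information).

## Synthetic-data fixtures

Test phantoms are generated programmatically: crystal-only ideal shapes for
validation, and composite "droplet" samples (crystal rod or block plus an
aggregate blob inside a 40 µm liquor sphere at 0.5 µm voxels) for the
coefficient pipeline, with material coefficients set to the measured values
of the two study samples (porin-like at 3.54 Å: crystal 0.01053, liquor
0.01208, loop 0.00931, aggregate 0.0322 µm⁻¹; chlorite-dismutase-like at
4.13 Å: crystal 0.0160, liquor 0.01856, loop 0.01724 µm⁻¹).  The droplet
geometry keeps the aggregate laterally clear of the crystal so each material
has clean pixels in the face-on view.  Noise is multiplicative Gaussian at
1% — a flat-field-corrected counting-noise stand-in; it does not emulate
ring artefacts, phase contrast beyond a boundary band, or segmentation error.

## Numerical and design choices

* Voxel-centre membership for phantoms (no partial-volume antialiasing),
  matching the discrete sum the engine computes.
* Ray origin at the voxel centre; the half-voxel ambiguity this leaves is
  symmetric and cancels in the volume average.
* Corrections divide σ as well as I; no variance term is added for the
  uncertainty of A_h itself.
* Correction tables serialize with 17 significant digits; round trips are
  bit-exact (`float_precision="round_trip"` on read).
* Parallelism is per reflection with reduction in input order, so output
  files are byte-identical for any worker count.
* Reflections are evaluated at their supplied scan angle (one angle per
  observation); per-image evaluation is the caller's choice of inputs.

## Known limitations

* Cropped volumes truncate absorption of out-of-view material.
* Registration of a real tomogram to the diffraction frame must be supplied
  by the user (the generators guarantee it for synthetic data); subpixel
  superposition of model onto tomogram is not implemented.
* Systematic sampling degrades on lattice-commensurate synthetic solids (see
  above) and, generally, when fewer than a few thousand crystal voxels are
  sampled; for small crystals use a smaller interval.
* The 2θ = 90° sphere case exceeds the 0.75% validation bound and is
  reported, not hidden — consistent with the published behaviour of the
  method.
* Isotropic voxels only; anisotropic reconstructions must be resampled
  upstream.
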