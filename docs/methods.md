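# Methods

`echoplan` implements an all-ultrasound workflow for transcranial focused
ultrasound (FUS) planning: reconstruct a skull map from stacked 2D B-mode
images, estimate the beam's incidence angle on the skull, and predict the
transcranial pressure field with a heterogeneous acoustic simulation.
Because the primate skull data such a pipeline is normally validated on
(CT volumes, hydrophone raster scans, harmonic B-mode stacks) are not
publicly deposited, every stage is validated against synthetic phantoms
with closed-form ground truth and against analytic acoustics oracles.
This note records the models, the parameters that matter, and the design
choices made where the design was genuinely open.

## Phantoms and ground truth

Phantoms are analytic bone shells — flat slabs, spherical caps, or
ellipsoidal shells — voxelized by the center-in rule (a voxel belongs to
the shell iff its center satisfies the analytic inequality). Optional
carve-outs emulate anatomy: planar slots for sutures, cylindrical
punch-outs for eye sockets. Rotations are intrinsic Euler angles applied
about x, then y, then z, about the shell center; since ground truth is
regenerated analytically for every rotation, the choice of convention is
documentation, not physics.

Ground truth is never read back from the voxelization: the surface normal
is evaluated in closed form where the beam line first crosses the outer
surface, the incidence angle is `90° − arccos|n·d|`, thickness is the
generating parameter, and socket landmarks are rim-point pairs whose
separation equals the hole diameter exactly.

The B-mode emulator reproduces the *acquisition product*, not the
beamforming chain: the shell is resampled to the imaging lattice
(0.14 mm in-plane pixels by default; slices every 0.2 mm for a full map
or 0.5 mm for a partial map), given a two-level echogenicity template
(bone 0.8, background 0.05), and multiplied by unit-mean Rayleigh
speckle. This gives segmentation the intensity statistics it must
tolerate, but deliberately omits features of real transcranial B-mode:
depth-dependent attenuation and focusing, reverberation clutter,
refraction through soft tissue, spatially correlated speckle, and
shadowing below bone. Passing tests therefore demonstrate that the
geometry pipeline is correct and speckle-robust; they do not certify
segmentation quality on in-vivo images, which the workflow's origins in
manually segmented data (and its discussion of ML segmentation as future
work) also caution about.

## Skull-map reconstruction and morphometry

Each slice is thresholded (Otsu), cleaned of components below 20 px, and
closed with a 1 px disk. For whole stacks, `segment_stack` derives a
single threshold from the pooled histogram: a slice containing no bone is
unimodal, and a per-slice threshold would bisect its background speckle.
A polygon-ROI import (pixel-center in/out rule, degenerate and
self-intersecting polygons rejected) covers the manual-segmentation
path. Stacking assigns the third volume axis the slice pitch, so 500
slices at 0.2 mm span 100 mm and 70 slices at 0.5 mm span 35 mm.

Thickness along a probing line is the distance between first entry into
and last exit out of the mask, sampled every 0.02 mm with
nearest-neighbour lookup — internal gaps (diploë) count as bone, matching
the outer-to-inner caliper reading, and the fine step gives sub-voxel
consistency without interpolation ambiguity. Caliper distances are plain
Euclidean distances in mm.

## Incidence angle

The sonicated surface patch is gathered by marching rays parallel to the
beam through every lateral position inside the beam footprint and keeping
the first skull voxel on each ray. The footprint radius uses the
geometric converging-cone model `r = (OD/2)(F − depth)/F` evaluated at
the depth where the beam axis first meets the skull (a configurable
multiplier allows wider or narrower patches). Ray offsets are integer
multiples of the lateral voxel pitch so rays align with voxel centers
rather than straddling boundaries.

A total-least-squares plane (smallest principal direction of the centered
scatter) is fitted to the patch; the normal's sign is disambiguated
toward the propagation direction and the angle uses `|cos|`, so the
result is independent of normal orientation. Incidence is reported as
`90° − α` with α the normal-to-beam angle; 90° means perpendicular
incidence. The rms orthogonal residual is reported so users can flag
curved or suture-crossing patches where a plane is a poor model.

On noise-free slabs the pipeline recovers angles in [40°, 90°] to about
0.1°; with default speckle and automatic segmentation, to well under 2°.
On spherical shells the plane fit measures the patch-average normal,
which differs from the point normal at the beam axis by a curvature bias
of order (footprint/R)²; for a 60 mm sphere and the default 15 mm
footprint this is up to ~0.6°. That bias is a property of the
plane-patch model itself, not an implementation error, and shrinks with
the footprint multiplier.

## CT-to-acoustics conversion

HU are clamped to [0, 1000] and mapped to porosity Φ = 1 − HU/1000;
density, sound speed and absorption interpolate linearly between water
(1000 kg/m³, 1500 m/s, 0.0022 dB/cm) and dense-bone endpoints
(2200 kg/m³, 3000 m/s, 0.68 dB/cm at the 250 kHz reference with a
frequency power-law exponent of 2). The linear-in-porosity form is the
standard piecewise-polynomial family with a single segment; every
endpoint is configuration, so alternative published coefficient sets are
a config change. Clamping avoids unphysical extrapolation for air/fat
(negative HU) and metal. CT volumes are resampled trilinearly to the
isotropic simulation grid before conversion.

## Acoustic solver

The solver integrates the linear first-order acoustic equations
(pressure/density + particle velocity) with k-space pseudospectral
derivatives on staggered grids, the exact-for-homogeneous-media k-space
correction `sinc(c_ref k Δt/2)` with `c_ref = max(c)`, and a split-field
quartic-profile absorbing boundary layer. Numerical choices that matter:

- **Grid and step.** 0.4 mm gives 15 points per wavelength (ppw) in
  water at 250 kHz; the sweep default of 0.6 mm gives 10 ppw in water and
  20 ppw in bone, well beyond pseudospectral convergence needs. The time
  step is derived from a CFL target of 0.2 at the fastest sound speed
  (54 ns in water, 26.7 ns with bone on the 0.4 mm grid); CFL above 0.3
  is refused.
- **Staggered density** uses harmonic averaging, which preserves the
  effective impedance of sharp interfaces (arithmetic averaging biased
  layer transmission by ~7% at normal incidence).
- **Absorption** is narrowband: the dB/cm map at the reference frequency
  is scaled by (f₀/f_ref)² and applied as a per-step exponential decay on
  both velocity and density, which leaves the impedance untouched and
  realizes the nominal dB/cm (damping only the mass equation would halve
  it). Full fractional-Laplacian power-law dispersion is out of scope
  for a 15-cycle narrowband burst.
- **Source.** The bowl is voxelized as the set of voxel centers within
  half a voxel of the sphere of radius F about the geometric focus,
  between the inner and outer aperture half-angles (a circular arc in
  2D). It is driven as an additive mass source with a raised-cosine
  ramped tone burst (15 cycles, 2-cycle ramps by default; the pulse
  repetition frequency is irrelevant to linear single-burst amplitudes
  and is ignored). With mass-source amplitude s per voxel, the
  free-field response of one voxel is the free-space Green's function
  with strength s·dV, which is what makes the solver directly comparable
  to the Rayleigh-integral oracle without calibration constants.
- **Recording.** The per-voxel maximum |p| is recorded only from each
  voxel's earliest possible wavefront arrival (distance transform to the
  source over max c), discarding the start-up transient. Optional probe
  voxels record full time series; narrowband amplitudes are extracted by
  quadrature demodulation over integer periods, which is how the solver
  is compared against single-frequency analytic solutions.
- **Boundary layer.** Default 10 voxels with strength 2 Np/voxel
  (quartic ramp) reflects ~5% in the worst case, comparable to common
  pseudospectral practice at that thickness; validation runs that need a
  quieter boundary (layer transmission, the sweep) use 20–30 voxels at
  1 Np/voxel, measured at ≤1% and ≤0.2% reflection respectively.
- **Duration.** By default a run simulates two crossings of the grid
  diagonal at the slowest speed, so the focus fully forms; `t_end`
  overrides this for plane-wave measurements.

### Validation oracles

Three independent analytic results validate the solver: the
Rayleigh–Sommerfeld bowl integral (numerical quadrature at ≥20 nodes per
wavelength, checked against the closed-form on-axis cap solution to 1%);
the free-space Green's-function superposition over the solver's own
source voxels (2D Hankel kernel / 3D spherical kernel), which isolates
propagation physics from source-quadrature differences; and the
three-medium transfer-matrix transmission coefficient, valid through the
evanescent (beyond-critical-angle) regime with a complex layer angle.

A note on "focal location": for this bowl geometry the *analytic* field
itself is flat to <1% over several millimetres along the axis, with its
maximum a few millimetres proximal of the curvature center (both the 2D
arc oracle and the closed-form 3D on-axis solution show this). The
simulated focus is therefore checked to land on that analytic plateau
and on the beam axis to within one voxel; demanding the argmax voxel
coincide with the geometric focus would be ill-posed on such a plateau.

## Beam metrics and the angle sweep

Focal position is the ROI argmax refined per axis by a 3-point parabolic
fit; the ROI is a ±15 mm box around the free-field focus with bone
voxels excluded (the measurement emulates a hydrophone scan *below* the
skull). Attenuation (insertion loss) is `100·(1 − p_skull/p_free)` using
ROI maxima, robust to focal shift. Focal shift is decomposed into a
signed axial component (positive toward the transducer) and an unsigned
lateral magnitude; FWHM is linearly interpolated at 50% of the profile
peak along lines through the focus.

The sweep experiment tilts a 5 mm shell about the axis perpendicular to
the simulated plane through eight nominal incidence angles spanning
45–90°, with the proximal surface 30 mm above the geometric focus. The
tilt axis choice makes the geometry exactly planar, so the simulation is
2D (272×240 at 0.6 mm) while incidence estimation still runs on the 3D
voxelized phantom — and the regression's x-axis uses those
pipeline-estimated angles, not the nominal tilts, mirroring how angles
are obtained from B-mode data in practice. One free-field reference
serves all tilts. Attenuation decreases as incidence approaches 90°
(Spearman ρ = −0.79, OLS R² = 0.74, slope ≈ −0.4 %/deg under the default
conditions). Two caveats: a flat, uniform, weakly absorbing slab
preserves coherent thin-layer interference and aperture-edge
critical-angle effects that real (curved, rough, diploic) skulls smear
out, so the relationship plateaus slightly between ~75° and 90°; and 2D
cylindrical focusing has lower gain than the real 3D bowl, so absolute
attenuation percentages are not comparable to hydrophone numbers — the
monotone trend and its strength are the reproducible content.

## Known limitations

- Fluid-only bone model: no shear conversion, which matters at steep
  incidence on real skulls; no nonlinearity or heating.
- The B-mode emulator's simplifications listed above; automatic
  segmentation is validated only against that emulator.
- Plane-patch incidence estimation carries the curvature bias quantified
  above; no refraction-aware ray tracing.
- CT/B-mode slice matching for thickness comparison is left to explicit
  user-provided slice indices, as feature-based matching is inherently
  manual.
- 3D simulation is supported (and smoke-tested) but the validation suite
  exercises the desk-scale 2D configuration.
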