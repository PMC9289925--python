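# Methods

## Scope and model of the measurement

`acrpet` automates quantitative quality assurance of PET systems with the
ACR-approved Jaszczak phantom (Esser PET faceplate, spheres removed).  The
phantom is modelled parametrically: a stack of 2D transaxial sectional
profiles, each an ordered (painter's) list of circular/annular primitives
carrying a material.  Materials combine a 511 keV linear attenuation
coefficient with a relative activity concentration:

| material | mu [1/cm] | relative activity |
|---|---|---|
| air | 0 | 0 |
| water (background / cold water) | 0.096 | 1 / 0 |
| hot solution | 0.096 | insert:background ratio (2.5 default) |
| nylon (screws) | 0.1036 | — (mu-map only) |
| acrylic (shell, walls, rods) | 0.117 | 0 |
| Teflon (bone surrogate) | 0.148 | 0 |

Printed phantom dimensions are built in: 210 mm internal diameter, 190 mm
interior height, hot insert diameters 25/16/12/8 mm, 25 mm cold air, cold
water and Teflon cylinders, 1.5 mm acrylic walls on all fillable inserts,
and six pie-sector sets of resolution rods with diameters
12.7/11.1/9.5/7.9/6.4/4.8 mm.  Quantities the phantom's drawings do not
publish were fixed once at nominal values and exposed as configuration: the
axial section boundaries (faceplate inserts spanning z = 47–95 mm, rods
z = −80 to −25 mm between two 6 mm acrylic support discs, with the axial
origin at the interior midpoint), the seven insert positions (evenly spaced
on a 65 mm radius), a rod centre-to-centre pitch of twice the rod diameter
(the standard Jaszczak layout), 3.2 mm side-wall thickness, and placeholder
nylon-screw positions.  The largest rod is 12.7 mm by default; 12.97 mm can
be configured (both values circulate for this insert).

Voxelization assigns each voxel the material of the primitive containing
its centre, painter's order, with no anti-aliasing; partial volume enters
only through downstream mean-pool resampling.  Because sections are
z-invariant, each distinct section combination is rasterized once in 2D.
The rod insert is a separate component with its own rigid transform — it
can be mounted at any rotation.

## Ring-VOI sampling and the knife-edge model

Every insert and rod is sampled with concentric rings (tubes in 3D, 10 mm
axial slab) on a 0.5 mm design grid: a 4 mm central circle then 2 mm rings
for inserts (10 rings hot, 11 cold), with the ring straddling each fillable
wall widened to 2.5 mm so a ring boundary coincides with the wall; a
2.52 mm central circle then 2 mm rings for rods, one identical pattern per
rod pooled over the set (ring counts 11/10/9/7/6/4, largest set first);
18 background rings of 6 mm radial width spanning the full interior with
exclusion holes of insert radius + 6 mm around every insert.  Rod samples
falling inside any other rod, or outside a 103 mm radius, are excluded.
The per-ring abscissa is the area-weighted effective radius
r_eff = (2/3)(r_out³ − r_in³)/(r_out² − r_in²).

Sampling never rasterizes templates into the image grid: template-space
points are mapped through the rigid transform and the image is interpolated
trilinearly at the mapped points, which is equivalent to upsampling the PET
image to the 0.5 mm analysis grid.

The radial profile across a cylindrical boundary is fitted with

    K(x) = A·erf(k(x − mu)) + b,

whose derivative is the Gaussian effective PSF with amplitude 2Ak/√π,
sigma = (k√2)⁻¹ and FWHM = 2·sigma·√(2 ln 2).  Three refinements matter in
practice:

- **Annulus-averaged forward model.**  A ring mean is an area-weighted
  average of K over the annulus, not a point sample; fitting point values
  at r_eff inflates the apparent width by roughly w²/12 in variance (≈10%
  in FWHM for 2 mm rings against a 3 mm PSF).  When ring bounds are known
  the model therefore predicts annulus averages (8-point Gauss–Legendre on
  the area measure).  Profiles supplied as bare (x, y) points fall back to
  the literal point-evaluated model, which recovers noise-free model data
  exactly.
- **Wall-aware model for hot inserts.**  A fillable hot insert presents
  hot → cold wall (1.5 mm) → warm background, not a single step.  The fit
  uses a two-edge compound with shared sharpness k and known wall width,
  still four free parameters; the reported (A, k, mu, b) are the
  equivalent single-edge parameters of the insert-to-background
  transition.  For the cold fillable compartments the wall itself is cold,
  so the physical knife edge sits at R + 1.5 mm; solid Teflon has no wall.
- **Sign convention.**  With radius as abscissa, A < 0 where concentration
  falls outward (hot inserts) and A > 0 where it rises (cold inserts,
  rods).  Reported resolution metrics use |2Ak/√π|.

FWHM is reported as valid only when the sampled profile extends at least
two FWHM beyond the boundary; narrow rod sets fail this rule by design and
are summarized by the maximum transition rate instead.  The residual
cylindrical-curvature bias of the planar-edge model is accepted (≈1–2% at
the 25 mm insert for 3–6 mm PSFs, measured on noise-free simulations) and
covered by the stated tolerances.  k is constrained to [0.05, 5] mm⁻¹ and
flagged when pinned; fits are weighted by pooled per-ring voxel counts
(the weighting choice is a package decision).

## Registration

STAGE I aligns a non-attenuation-corrected (NAC) appearance template to the
NAC image; STAGE II isolates the rod insert and aligns the rod template.
The NAC template multiplies the activity map by exp(−L(x, y)/2), where
L is the attenuation line integral through the uniform mid-section mu-map
averaged over 16 in-plane directions (evaluated on a 2 mm transaxial grid
and interpolated) — a deliberately simple surrogate for the peripheral
brightening of NAC reconstructions.  The rod insert's axial extent is
detected from the summed per-slice profile: the two support discs displace
all activity and appear as deep minima (below half the interior median)
flanking an intermediate-intensity rod region; detection is scale
invariant.  The rod template is started from a user-supplied approximate
rotation angle, since the insert can be mounted at any rotation that a
local optimizer cannot discover.

Similarity is Mattes mutual information (32 bins, linear interpolation),
maximized through a Gaussian pyramid with smoothing sigmas 3/1/0 mm and
per-level iteration caps 10000/1000/100 (shrink factors 4/2/1).  Coarse
levels use regular-step gradient descent with scales from physical shift;
the final level uses a gradient-free Powell polish on a regular 25% sample
grid, because the full-resolution MI landscape is flat along the phantom
axis and rippled by interpolation, where gradient descent stalls ~0.5 mm
off.  All sampling is deterministic; rotations act about the template
centroid so rotation and translation estimates stay decoupled.  The MI bin
count and optimizer are package decisions, not protocol constants.

## Synthetic reconstruction and bootstrap

The simulator stands in for list-mode OSEM reconstruction: voxelize
activity (default 1 mm render grid) → optional NAC modulation → rigid
misplacement (trilinear resampling) → isotropic Gaussian PSF (default
4 mm FWHM) → mean-pool to the 2 mm reconstruction grid → scale to an
expected total count → independent per-voxel Poisson noise → calibrate to
Bq/mL via the background concentration (default 3281 Bq/mL, i.e. 18.7 MBq
in 5.7 L; hot inserts 2.5:1).  The counts-per-activity calibration is fixed
before the blur so that losses at crop boundaries cannot bias it.  Decay,
scatter, randoms and attenuation-corrected reconstruction are not
modelled; out-of-FOV contamination is available only as a configurable
additive low-frequency ramp for qualitative studies.

Bootstrap realizations are voxel-wise Poisson redraws of the expected-count
image, each reproducible from (seed, index).  This preserves the count
statistics that drive VOI precision, but unlike list-mode bootstrap it
carries no correlated reconstruction noise between voxels and no
iteration-dependent noise structure — conclusions about absolute SEs of a
real scanner do not transfer, while scaling behaviour (SE ∝ 1/√counts,
volume-driven ring SEs, registration-robustness logic) does.

The registration-robustness check computes every ring statistic twice per
realization — under one fixed transform and under a fresh registration —
and compares dispersions ring-by-ring with the Fligner–Killeen scale test
under Holm control at alpha = 0.01 (the protocol names no test; this is a
robust default).  Verdict "robust" requires no significant ring and a
registration failure rate ≤ 20%.  Default 50 realizations, with a reduced
n = 10 mode for quick studies.

## Problem sizes and numerical choices

Analyses run at the native design grids (0.2 mm mu-map, 0.5 mm templates,
0.4 mm registration templates); validation studies choose sizes where each
effect is measurable rather than maximal, as a design decision: resolution
studies render at 0.5 mm and reconstruct at 0.5–1 mm so grid blur stays
negligible against the PSF under test; registration and bootstrap studies
use the 2 mm reconstruction grid with 2 mm registration templates, 10–30
bootstrap realizations, and count levels of 1–2×10⁸ expected events
(sub-volumes are simulated at the equivalent count density via the axial
activity fraction).  Degenerate inputs fail loudly: constant images refuse
to register, profiles need ≥ 4 rings, empty rings and missing disc
signatures raise dedicated errors, and extractor failures in bootstrap
summaries are counted and excluded rather than silently dropped.

## Known limitations

- The PSF is estimated in the transaxial plane only (cylindrical edges).
- The NAC template is an appearance heuristic, not a physical NAC
  reconstruction; it exists solely to make STAGE I robust.
- Phantom filling and physical positioning variability are outside the
  bootstrap's scope.
- Synthetic images share none of a real scanner's correlated noise, Gibbs
  ringing, scatter or randoms; passing tests validate the measurement
  chain, not scanner physics.
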