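# Methods

This note documents the models, parameter choices and design decisions
behind `drteval`, and states explicitly what the synthetic phantom does and
does not show about real data.

## Coordinate and format conventions

All streamline and point coordinates are world millimetres in the frame of
the volume's NIfTI affine (RAS expected, not enforced). Voxel indices are
0-based; a voxel is the half-open cube centred on its index point. TRK files
store voxel-order coordinates on disk and are converted to world mm on read;
TCK passes through unchanged. Gradient tables follow the FSL `.bval`/`.bvec`
convention (3 rows × N columns accepted, as is N × 3); gradient vectors with
b > 0 are normalised on read, and a zero vector paired with b > 0 is an
error rather than a silent fix. Mask readers reject non-binary volumes
instead of thresholding them.

## Tensor model

The fit is plain log-linear least squares, solved in one batched `lstsq`
over the volume for `[ln S0, Dxx, Dyy, Dzz, Dxy, Dxz, Dyz]`. A weighted or
iterative fit was deliberately not used: at the noise levels the phantom
targets (SNR ≥ 20 relative to S0 = 100) the LLS estimate of the principal
direction is accurate well below the tracker's angular tolerance, and the
fit is deterministic and fast. Voxels with non-positive signal, a
non-positive fitted S0 or a non-finite solution are marked invalid; negative
eigenvalues are clamped to zero before FA. Principal eigenvectors get a
fixed sign (first non-zero of x, y, z made positive) so serialized fields
are reproducible; the tracker re-aligns the sign per step regardless.

## Tracker

`fact` mode is classic FACT: nearest-neighbour lookup of the per-voxel
principal axis, bidirectional from each seed-voxel centre, stopping on
FA < `fa_stop`, inter-step angle > `max_angle_deg` (evaluated against the
previous step direction, not cumulatively), volume exit, or length. `tend`
mode trilinearly interpolates the tensor and blends its principal axis with
the deflected incoming direction `D·v_in` by `tend_blend`.

Defaults sit at the lower ends of the clinically quoted ranges: FA cutoff
0.15 (range 0.15–0.2), minimum length 50 mm (range 50–80 mm), angulation
20°. The step defaults to half the smallest voxel dimension (1 mm on the
default phantom). Each propagation half is capped at `max_length_mm / 2`, so
a merged streamline can never exceed the length bound; the cost is that a
seed near one bundle end cannot reach further than half the cap in one
direction, which is irrelevant for tracts much shorter than 300 mm. A
termination point is never placed inside an inadmissible voxel: the step is
refused, so retained streamlines visit only voxels at or above the FA
cutoff and never contain a bend above the angular limit.

## Selection

"Visit" means any point of the streamline, resampled at half the smallest
voxel dimension, falls inside a mask voxel — resampling prevents a coarse
point spacing from jumping a thin mask. Visit order is not enforced, and by
default termination inside PG is not required (a strict mode exists). RN
dilation is Euclidean in world mm on voxel centres (via a distance
transform), which handles anisotropic voxels; 2 mm is the protocol default.

The laterality of RN/PG relative to DN is genuinely ambiguous in clinical
usage, so it is a switch. The default (`drtx_crosses`) follows the anatomy
of the decussation: the *crossed* variant connects DN to the contralateral
RN/PG, the uncrossed variant stays ipsilateral. The opposite convention
(`drtu_crosses`) is available and flips both variants.

Manual elimination of erroneous fibers cannot be reproduced faithfully;
it is modelled as deterministic, recorded exclusion masks (any streamline
visiting any exclusion mask is removed).

## Density, warp and congruence metrics

Densities count *distinct streamlines per voxel* (not step visits), because
the Dice threshold is phrased in streamlines per voxel; a streamline
re-entering a voxel contributes once. Warping applies a template-grid
displacement field by trilinear pull-back (no Jacobian modulation — counts
are compared, not integrated densities), and binarisation at the threshold
happens *after* warping on interpolated values, matching a workflow in
which maps are normalised first and thresholded second.

The z profile evaluates one level per integer template millimetre from −27
to 16 (44 levels), each mapped to the nearest slice; the spacing is a
package choice since only the range is standard. Slices where either map
carries no mass (COG) or both suprathreshold sets are empty (Dice) are
*undefined* and excluded from aggregates rather than scored zero — absence
of signal is not disagreement — and the number of defined levels is always
reported alongside. Both median and mean aggregates are computed. COG is
computed on continuous world coordinates of voxel centres, not on index
units, so anisotropic template grids are handled.

Validity at a level reports the in-plane distance from the density COG to
the nearest reference-mask voxel centre on that slice (0 when the COG's own
voxel is inside the mask).

## The phantom

The generator emulates a single-shell clinical acquisition: 64³ voxels at
2 mm isotropic, 60 gradient directions (deterministic golden-spiral
hemisphere scheme) at b = 1000 s/mm², one b = 0, S0 = 100. Bundle voxels
carry a prolate tensor with eigenvalues (1.7, 0.3, 0.3)·10⁻³ mm²/s
(FA ≈ 0.80, typical of coherent white matter) whose principal axis follows
the local centerline tangent; background voxels are isotropic at
0.8·10⁻³ mm²/s (FA = 0, below any cutoff). Noise is Rician,
`√((v+n₁)² + n₂²)` with `σ = S0/snr`; "high/low quality" acquisitions are
emulated purely through this one number, as no quantitative SNR is standard.
Repeat sessions share the noiseless signal and differ only in the noise
seed (seed, seed+1).

Bundle geometry is a pair of cubic-spline tubes (radius 4 mm) through
hand-placed control points mirroring the schematic DRT course: the
uncrossed bundle runs DN → SCP corridor → RN-adjacent corridor → Vim → PG
within the left hemisphere; the crossed bundle leaves the same dentate
region, decussates across the midline below the RN level and ascends the
right hemisphere. Waypoint masks are axis-aligned boxes placed on the
centerlines so that ground truth is self-consistent with the selection
protocol (the generated centerlines pass their own DN, dilated RN and PG) —
a property the test suite asserts. The Vim, RN and SCP boxes sit at
template z = 6, −8 and −22 so the validity levels are meaningful.

Crossing-fiber voxels are created where the crossed bundle meets the
decussation segment of its own mirror image (the contralateral crossed
tract, present in any real decussation). Those voxels average the two
tensor signals 50/50. For congruent prolate tensors at a crossing angle of
~65°, the mixture's principal axis is the bisector, ~32° away from either
fiber — beyond the 20° angulation limit — so a deterministic single-tensor
tracker terminates there by construction. The mirror population is
restricted to centerline samples within 6 mm of the midline precisely so
that it cannot graze the uncrossed bundle: the uncrossed tract's course is
mixture-free and tracks cleanly. This is the minimal geometry that
reproduces the qualitative crossing-failure phenomenon while keeping the
uncrossed recovery clean; a 50/50 mix of *both named bundles* in one voxel
would provably degrade both, since the mixture axis is the bisector either
way.

The template warp is a synthetic stand-in for a diffeomorphic registration:
a three-component low-frequency cosine displacement field rescaled to a
3 mm maximum magnitude (configurable, ≤ 6 mm), smooth by construction. The
same warp is shared by both sessions of a subject, as a subject-level
registration would be.

### What the phantom does not emulate

EPI/susceptibility distortion, eddy currents, motion, partial volume with
grey matter or CSF, multi-shell acquisitions, axonal dispersion, and any
anatomical variability across subjects. Passing tests therefore demonstrate
the *correctness of the pipeline's computations and contracts* and the
qualitative crossing-failure mechanism — not clinical accuracy figures for
real acquisitions. Numbers obtained on the phantom (e.g. sub-millimetre
retest COG distances) are upper bounds on pipeline-intrinsic error, not
predictions for in-vivo data.

## Problem sizes and numerical tolerances

The default study runs one 64³ phantom subject with whole-WM seeding
(≈ 2 600 seeds), which tracks in seconds; the full three-arm study including
a two-session SNR-20 retest completes in well under a minute on one core.
Metric implementations are vectorised but verified exactly (Dice) or to
1e-9 mm (COG) against independent brute-force loop implementations on
randomised small grids. Affine comparisons use 1e-4 tolerances on
round-trips; streamline round-trips are exact to 1e-4 mm (TCK/TRK store
float32). Degenerate inputs are first-class: empty seed masks warn and
return empty tractograms, empty selections propagate as "reconstruction
failed" results, all-zero slices are undefined rather than zero.

## Known limitations

* The commercial two-tensor deflection tracker this pipeline approximates
  is proprietary; fidelity to its exact stepping, interpolation and seeding
  cannot be verified. The `tend` mode is a generic tensor-deflection
  variant, not a reverse engineering.
* Only TCK/TRK ingestion is supported for externally produced tractograms.
* Slice metrics require axis-aligned affines; oblique template grids are
  not supported.
* The warp is applied, never estimated; registration error is out of scope.
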