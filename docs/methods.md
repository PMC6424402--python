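# Methods

This note records the models behind each pipeline stage, the conventions
and defaults that matter, and what the synthetic-data generators do and do
not emulate.

## Spatial statistics of pole patterns

**Model.** Structures (flagellar motors and relics) on one cell pole are
treated as a planar point pattern; motors and relics are pooled for
nearest-neighbour and Clark–Evans analysis because the biological question
is whether both occupy a single placement grid. Per-label histograms are
available for the group comparison.

**Pole-area convention.** The published procedure derives each pole's
ellipse by adding one C-ring diameter (45 nm, the steric footprint of a
motor) to the maximum X and Y coordinates of any structure. The coordinate
origin is unstated in that procedure, so this package fixes it: coordinates
are re-centred on the point centroid, and each semi-axis is the maximum
*absolute* centred coordinate plus the C-ring diameter. The centre is
recorded in the output and overridable. Consequences worth knowing:

* The convention is translation- and quarter-turn-invariant but **not**
  invariant under arbitrary rotations (the maxima are axis-aligned).
  Property tests assert exactly the invariances that hold: translation,
  90° rotation, and uniform scaling with the C-ring diameter scaled along.
* A single structure claims a 45 nm-semi-axis ellipse — its own footprint.

**Clark–Evans ratio.** R = mean NN distance / (0.5·√(A/n)), computed only
for poles with at least `min_structures_per_pole` structures (default 5,
"more than four"; configurable because published cohort sizes vary).
Excluded poles are reported with a reason, never silently dropped. No edge
correction is applied. The null model is therefore *procedural*: ≥500
synthetic poles, each copying an observed pole's count and derived ellipse
and refilled uniformly at random, are re-measured with the geometry
**recomputed from the synthesized points**. At the spatial scale of real
pole data — grid-like patterns at ~64 nm spacing, 5–10 structures, derived
semi-axes ~110–150 nm — the upward small-n/no-edge-correction bias of the
raw ratio and the downward bias from the 45 nm area margin nearly cancel,
and the null cohort mean sits within ~0.05 of 1. At much larger pole
ellipses (semi-axes ≳200 nm) the margin no longer compensates and the null
mean drifts to ~1.2; the calibration is therefore always run at the data's
own scale, which is what the constrained-null construction guarantees.

**Hard-core expectation.** The steric reference (what mean NN spacing mere
C-ring exclusion would produce) is estimated by Monte-Carlo: random
sequential adsorption (RSA) packings with a 45 nm exclusion diameter,
capped at 10⁴ placement attempts per point; saturation raises an error
reporting the achieved count.

## Synthetic pole patterns

Four generators cover the hypotheses the analysis discriminates:

* `uniform` — uniform in the ellipse (area-preserving polar sampling).
* `hardcore` — RSA with a 45 nm default exclusion, the steric null.
* `grid` — hexagonal lattice (the lattice that attains the CE maximum
  2.1491), compact about the centre, clipped to the ellipse, with optional
  isotropic Gaussian jitter (points resampled to stay inside).
* `cluster` — Thomas process (uniform parents, Gaussian offspring,
  clipped); any CE < 1 generator would do, this one is standard.

Labels are assigned motor/relic by independent Bernoulli draws with
`motor_fraction` (default 0.8, roughly the published motor:relic ratio of
424:114). All generators are deterministic given (parameters, seed).

## Population flagellation model

A continuous-time birth–death model per tracked cell lineage, simulated
exactly (event-driven; the deterministic trigger-crossing time is handled
by advancing to it and redrawing, so rates are piecewise-correct):

* Culture OD600 follows a logistic curve (default growth rate 2.2 h⁻¹,
  matching a ~19 min early doubling time; carrying OD 1.4); CFU/ml is OD ×
  8×10⁸.
* Each cell assembles flagella at `assembly_rate` (default 5 h⁻¹, chosen so
  the pre-trigger steady state is ~5 flagella per cell, the observed
  early-growth flagellation) and divides at the logistic per-capita rate.
* `polar_ejection` mode: once OD reaches `trigger_od` (default 0.8, where
  motility collapses), assembly halts and each flagellum is ejected
  independently at `ejection_rate_post_trigger` (default 6 h⁻¹ — no
  quantitative rate is published; the default is illustrative and surfaced
  in `RunConfig`). At division the polar bundle passes intact to the
  old-pole daughter, so a tracked lineage keeps all or none.
* `peritrichous_dilution` mode: no ejection ever; counts halve binomially
  at division (flagella distributed over the whole surface).

This reproduces the qualitative signatures: per-cell means stable near 5
until the trigger then collapsing, absolute population flagella (mean ×
CFU) rising with growth and declining after the trigger in polar mode,
monotonically rising in peritrichous mode. Statistics downstream: the mean
per-cell count carries a Student-t 95% CI (pooled across replicates by
default; per-replicate averaging supported); CFU is treated as exact (no
published uncertainty), noted in output metadata.

## Hook-end statistics

A shed flagellum has two ends; ejection at the base of the hook leaves the
hook on exactly one of them, while mid-filament shearing leaves hooks on
neither. Exhaustive enumeration of all 2n ends therefore yields exactly
0.5 for a purely ejected population and 0 for pure shearing; subsampling
converges to these by the law of large numbers. The generator enforces the
one-hook invariant at construction.

## Swim tracks

Tracks are straight runs with per-frame Gaussian heading noise and a
constant ground-truth speed (normal draw truncated at 0). The default
estimator divides total path length by elapsed time — for short (~10 s)
tracks this is the natural "swimming speed"; net-displacement speed is also
available since path-length speed overestimates for strongly curved
tracks. Cohort summaries report the mean and SE over motile tracks, the
motile fraction (threshold 5 μm/s — not published, configurable, reported
in output), and speed relative to an early-growth baseline.

## Periplasmic distances

Inputs are scalar inner-membrane-to-outer-disk distances per structure
(contour drawing is upstream and out of scope). Summaries use linear
interpolation quartiles (numpy default) so results are bit-reproducible;
the range (max − min) is the published comparison statistic, and the
comparison reports difference and ordering only — no inferential claim.
The generator draws either uniform (spread = full range, the natural match
to a published range) or normal (spread = SD) distances, truncated
positive.

## Density phantoms and map operations

**Phantom.** Cylindrical geometry on the z axis: a Gaussian outer-membrane
slab (σ 2 nm) at +13 nm with a soft-edged aperture (tanh edge of one voxel;
the stated diameter is the half-rise diameter), an optional plug density
(0.8 amplitude) filling the aperture, and a Gaussian torus T-ring (radius
22 nm, σ 2 nm) offset 19 nm below the membrane, azimuthally modulated by
`1 + 0.5·cos(nθ)` for n ≥ 2 subunits (n = 1 is a smooth ring). Defaults
encode the measured motor geometry (44 nm ring, 19 nm offset, 15 nm
aperture, 13 subunits) in a 64³ box at 1 nm voxels. SNR is quoted as ring
amplitude (1.0) / noise SD, so SNR 2 means noise SD 0.5. The phantom does
**not** emulate tomographic artifacts (missing wedge, CTF) — deliberately,
since the operations under test are geometric.

**Symmetrization** averages n in-plane rotations about z. Rotation uses
cubic-spline interpolation (order 3, configurable): measured relative RMS
self-consistency error ~6×10⁻⁴ on a smooth 64³ phantom, versus ~9×10⁻³ for
trilinear, which would be the limiting error of every downstream tolerance.
Total density is conserved to ~10⁻⁶ relative.

**Symmetry detection** samples the density on an annulus (trilinear), radii
every half-voxel, averages an azimuthal profile, and picks the candidate
order with maximal rotational power. Two guards prevent arbitrary answers:
a modulation-depth floor (best-order depth ≥ 2% of the profile mean —
voxelization ripple on a smooth ring sits at ~10⁻⁵) and a power-dominance
check (best ≥ 3× the median power of the other candidates).

**FSC** uses shells one Fourier voxel thick and normalized real
cross-correlation per shell; resolution is the reciprocal of the linearly
interpolated first crossing below the threshold (default 0.5). A curve
that never crosses reports the Nyquist-limited value. FSC is symmetric and
scale-invariant by construction; the noise behaviour is validated against
the closed-form per-shell expectation S/(S+N).

**Composite merge** is the voxel-wise weighted average of two partial maps
under soft masks in [0,1]; zero-weight voxels are set to the solvent value
and counted. Complementary masks (binary or cosine-edged halves built by
`axial_soft_mask`) reconstruct a common input exactly. Mask design for
real data is the user's: only the merge contract is implemented.

**Ring measurement** works on azimuthally averaged ρ(z, r): membrane plane
by maximal in-plane mean, ring plane by maximal off-axis radial peak
outside a 5 nm membrane guard, ring radius by 3-point parabolic refinement,
aperture by the half-rise radius of the membrane-plane profile, and
occlusion flagged when the axis density exceeds half the membrane plateau
(the plugged-relic signature). With an even box the grid centre falls
between voxels, so the innermost non-empty radial bin stands in for r = 0.

## I/O and reproducibility

Lengths are nm everywhere inside the package; MRC files store Å and are
converted exactly once at the boundary (2.713 Å voxels become 0.2713 nm).
MRC2014 I/O goes through gemmi; anisotropic voxels are accepted with a
warning on read but rejected by the symmetry operations (resample first).
Point tables are TSV/CSV with a fixed five-column header, validated with
errors naming the column, row, or offending label. Every stochastic CLI
stage takes `--seed` and logs the seed, a stable config hash, and input
checksums; two runs with the same config and inputs produce identical
outputs.

## Problem sizes

The test suite and the acceptance script use desk-scale sizes chosen to
keep every estimate comfortably inside its tolerance: 500-pole null
cohorts, 100-replicate property checks, 64³ phantoms, 150-cell population
samples, 1000-track speed cohorts. These match the scale of the study's
own data (e.g. ~70 analysed poles, 150 counted cells, >1000 traces).

## Known limitations

* The CE analysis is strictly planar; real poles are curved caps, and no
  3D statistic is implemented.
* The pole-area convention is not rotation-invariant at arbitrary angles
  (inherited from the published definition of the maxima).
* The population model tracks lineages, not the full branching population;
  CFU and OD are deterministic.
* Phantoms are noise-plus-geometry only; no projection artifacts.
* The ejection rate, motility threshold, and cluster-process parameters
  are package choices where no published value exists; all are
  configurable and surfaced in `RunConfig` or the model dataclasses.
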