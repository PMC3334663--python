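# Methods

## Scope and data model

The package quantifies subchondral bone architecture in 8-bit micro-CT
stacks with isotropic voxel spacing (default 8.7 μm) and analyses
paired-limb longitudinal cohorts. Arrays are `(z, y, x)`, 0-based and
voxel-centered, with z increasing distally (articular surface at low z).
Physical spacing travels in a JSON sidecar next to every TIFF
(`spacing_um`), because plain TIFF does not carry it reliably; a spacing
passed at call time overrides the sidecar. All internal lengths are μm,
volumes mm³, BV/TV and porosity %.

## Segmentation

A single global threshold binarizes every volume of a study (bone iff
intensity ≥ t), preserving longitudinal comparability. The threshold is
user-fixed or suggested once by Otsu's between-class-variance criterion on
a designated calibration volume; since the bone rule is ≥, the suggestion
is Otsu's split plus one grey level. Conventions are fixed for bit-exact
reproducibility: ≥ at the threshold, 26-connectivity for bone,
6-connectivity for background. An optional despeckle pass (off by default)
removes bone islands and background cavities below a voxel-count cutoff.

## VOI construction

Per-slice medial and lateral polygons (0-based pixel coordinates of vertex
centers) are rasterized with a center-inclusion rule: a voxel is inside
iff its center is inside or on the polygon boundary (evaluated with
Shapely's `covers`). Medial and lateral must be disjoint; total is their
union. The axial window (e.g. 52 slices ≈ 0.45 mm) and its starting slice
are user inputs — the anatomical placement below the plate is a manual
step in the protocol being modeled, so the package does not guess it.

## Direct-3D local thickness

Local thickness at a voxel is the diameter of the largest sphere fully
contained in the phase that covers the voxel (maximal-sphere fitting). It
is computed from the Euclidean distance transform by sphere propagation:
distinct distance values are visited in descending order and every voxel
reachable by a sphere of that radius inherits its diameter unless already
claimed by a larger sphere. Radii equal distances between voxel centers
(the standard voxel-based convention): a slab k voxel layers thick reads
exactly k·spacing, and an isolated voxel reads 2 voxels. The volume border
is background for every domain — spheres may not leave the image — so
thickness means must be taken over a VOI kept away from the lateral
borders (the maps are computed on the full field and averaged inside the
VOI; the examples use a 35-voxel margin for 15-voxel marrow radii).
Tb.Th averages the bone map over bone ∩ VOI (volume-weighted); Tb.Sp runs
the identical machinery on VOI ∖ bone; by construction Tb.Sp of a mask
equals Tb.Th of its complement. Tb.N = (BV/TV)/Tb.Th, reported per mm.

Accuracy on analytic phantoms at 8.7 μm: slab thickness and separation are
exact for voxel-multiple geometry; voxel-centered rods land within one
voxel of 2·radius (discrete circles of radius 5 voxels carry a ~0.1-voxel
overshoot from the nearest-background-center convention); BV/TV is exact
for slabs and Gaussian-random-field phantoms and within 0.3 points for
rods. Errors shrink monotonically with resolution.

## Subchondral plate

Within a small analysis rectangle (default 1.5 mm × 2.5 mm, anchored at
the posterior edge of the compartment ROI) the plate normal is assumed
parallel to z. Separation is a deterministic column scan: per in-plane
column, plate = bone from the first bone voxel down to the first marrow
gap strictly longer than `gap_bridge` (default 52.2 μm = 6 voxels, a
declared assumption); all bone below is trabecular. The rule is monotone
in `gap_bridge` and partitions the bone. Its known limitation: a
through-pore column assigns the first bone it meets *below* the pore to
the plate, so porosity oracles are evaluated on plates whose pores are
enclosed by the footprint, and end-to-end runs are validated on pore-free
plates.

Pl.Th is the mean direct-3D thickness over plate voxels (pores excluded
from the domain, so a punctured plate legitimately reads thinner). Pl.Por
is pore volume over plate-envelope volume: per column, the z-span from
plate top to plate bottom; columns with no plate bone are included only
when the plate footprint encloses them in-plane (a through-pore, span
interpolated from the nearest plate column) and excluded when they fall
outside the plate. Total-compartment values are the arithmetic mean of
medial and lateral.

## Phantoms

* **Slabs** — parallel plates normal to z, period thickness+gap, z-extent
  trimmed to whole periods so voxel counting equals the analytic BV/TV.
* **Rods** — z-aligned cylinders on a square lattice, axes on voxel
  centers, in-plane extent trimmed to whole cells so no rod is truncated.
  Truth: thickness 2·radius, BV/TV π·r²/pitch².
* **Gaussian random field** — white noise smoothed with σ = correlation
  length, thresholded by a deterministic top-k selection so the achieved
  bone fraction is exact to one voxel regardless of kernel normalization.
* **Subchondral plate** — solid plate with through-pores drilled as
  radius-2-voxel canals on a jittered grid (localized blobs cannot
  encircle plate, keeping the footprint connected) plus one partial blob,
  hitting the requested pore count exactly; below it a marrow gap
  (default 174 μm) and a rod compartment. The grayscale companion renders
  bone 200 / marrow 50 with Gaussian blur (σ 0.6 voxel) and noise
  (σ 10 grey levels) for segmentation tests.

What the phantoms do not emulate: scanner physics (beam hardening, ring
artifacts, partial-volume blur beyond the stated Gaussian), anatomical
curvature of the plate, and irregular trabecular topology. Passing the
phantom suite therefore shows the *measurement* pipeline is correct, not
that segmentation of real tissue is unbiased.

## Cohort simulation

A cohort draws, per parameter × compartment,
`value = μ(limb, week) + SD(limb, week)·(√ρ·A + √(1−ρ)·ε)` with a
per-animal standard normal `A` shared across limbs and weeks and i.i.d.
`ε`. Each cell hits its designed mean and SD; the inter-limb (and
inter-week) correlation is ρ, compound-symmetric, so the repeated-measures
F tests are calibrated without sphericity correction. The default design
copies the published 12-animal group summaries; ρ defaults to 0.7, a
stated assumption — published summaries do not constrain it — chosen as a
typical within-animal correlation for paired skeletal sites. Growth is
encoded as different means per timepoint, not a parametric curve, because
only per-timepoint summaries exist to match.

## Inference

Normality is screened with Shapiro–Wilk (3 ≤ n ≤ 5000). The two-way
within-subject ANOVA computes sums of squares from cell and marginal means
of the balanced complete design and tests each effect against its own
subject-by-effect interaction mean square; exactly-null effects report
F = 0, p = 1 instead of a 0/0 artifact (the implementation is verified
against statsmodels' `AnovaRM` on non-degenerate data). Sphericity
correction is omitted by default; a Greenhouse–Geisser epsilon is
available. Paired t-tests per timepoint run only when the ANOVA shows a
significant limb or time-by-limb effect (the gate can be disabled for
calibration studies). The Holm family is the set of timepoint comparisons
within one parameter × compartment — matching the repeated-over-time
structure — and is the package's declared choice; between-timepoint
within-limb comparisons form their own family. Holm's stepdown is
`adj_(i) = max_{j≤i} (m−j+1)·p_(j)` capped at 1, returned in input order;
it dominates raw p and is dominated by Bonferroni.

## Reporting

Reports keep full precision; the companion table view applies the
published rounding (integers for μm/mm³ columns, one decimal for %, Tb.N,
and percent differences). Percent difference is 100·(MIA − control)/control.
Note the published BV magnitudes are inconsistent with mm³ for a
0.45-mm-high VOI; the pipeline reports true mm³ and the reference tables
record the published scale as-is. Published Tb.N cells are treated as
per-animal ratios summarized per group, so ratios of printed group means
need not reproduce every printed Tb.N cell; the derived-column checks use
cells where they do.

## Problem sizes and numerical choices

The test suite runs phantom recovery at 128-voxel in-plane scale
(slab 130×128×128, rod 64×120×120, GRF 128³, plate 96×128×128), chosen so
every structure is large against its own inscribed spheres while the full
suite stays interactive. Statistical calibration uses 500 simulated null
cohorts (n = 12) for paired-t and ANOVA type-I error (expected 0.05 ±
0.02) and 500 replicates for the power check on the published 2-week
Tb.Sp effect (271 vs 250 μm, SDs 13/14, ρ = 0.7; power > 0.8). The Holm
stepdown is verified against an independent closed-testing oracle
exhaustively for all grid-0.01 p-vectors of length ≤ 3 and on 50,000
random grid vectors of length 4. Floating-point ties in the thickness
propagation are rounded at 10⁻⁶ voxel; GRF thresholding breaks ties by
stable sort order, making every generator bit-reproducible under its seed.

## Known limitations

* The column-scan plate separation is a deterministic stand-in for
  connectivity-based cortical segmentation; it misassigns bone beneath
  uncovered through-pores (see above).
* Thickness means inside VOIs closer than one maximal sphere radius to
  the image border are biased low by the hard-wall rule; keep a margin.
* The cohort model is Gaussian and compound-symmetric; it does not model
  dropout, heteroscedastic growth, or measurement error correlated across
  parameters.
* Scores (macroscopic grading, OARSI) are arithmetic only; no image-based
  grading is attempted.
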