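# Methods

This note documents the models, conventions, and numerical choices behind
each stage of the pipeline, what the synthetic generator does and does not
emulate, and the known limitations.

## Synthetic data model

The generator renders an idealized operated ovine tibia: a hollow-cylinder
diaphysis (outer radius 10 mm, cortical thickness 3 mm by default) with a
transverse mid-shaft gap of 3 mm or 17 mm, and a mineralizing callus with
analytic ground truth. The callus has two monotone-from-empty components:

- an **interior component** (endosteal plug plus gap fill), the set of
  voxels within a radius fraction *t* of the local cap — the full gap
  cylinder inside the defect, the medullary canal within 10 mm beyond it;
- a **periosteal sleeve**, a fusiform shell outside the cortex whose
  thickness follows a raised-cosine axial profile over the gap ± 20 mm.

The interior fraction *t* is bisected on the actual voxel grid to hit
`(1 − periosteal_fraction) × target_volume`, then the sleeve thickness is
bisected for the remainder; the rendered truth-mask volume is required to
land within 2% of the requested volume, otherwise a capacity error is
raised (the requested callus cannot fit the field of view — enlarge
`fov_margin` or `bone_length`). Callus voxel densities are the target mean
plus re-centred Gaussian heterogeneity (SD 50 mg HA/cm³ by default), so
the truth-mask mean equals the set-point exactly in expectation-free
fashion. HU is linear in density with additive Gaussian noise; beam
hardening and metal artifacts are not simulated (fixation hardware is
removed before post-mortem scanning in the emulated workflow).

Default voxel spacing is 0.2 mm — coarser than a real peripheral-QCT scan
(~61 µm) — so full pipelines run in minutes at desk scale; all results are
computed per-spacing and the virtual torsion stage resamples to 0.4 mm
regardless. Two-arm studies are sampled from per-arm (mean, SD) set-points
whose defaults are the published group summaries of the emulated study
(e.g., 17-mm model callus volume 7.3 ± 1.3 vs 12.0 ± 2.3 cm³); the
treatment exists only as this distributional shift. Strictly positive
quantities use truncated-normal redraws (logged). Every generator is a
pure function of its parameters and seed.

What passing tests on these data do **not** show: robustness to irregular
callus geometry, scanner artifacts, registration error between post-mortem
scan and day-0 geometry, or real biological covariance between endpoints
(the sampler draws endpoints independently within a subject).

## Calibration

Unweighted OLS of rod-mean HU against known rod densities; the phantom's
rod densities are a required user input (they are scanner/phantom
specific). Negative densities after conversion are retained, not clipped,
so noise statistics survive into density averaging; thresholds are applied
downstream.

## Morphometry

The published segmentation procedure this stage stands in for is a
commercial-software workflow; here it is a transparent replacement: the
old-bone mask is an explicit input (day-0 geometry; the generator's truth
mask in synthetic studies), new callus is `ρ ≥ threshold` inside a
defect-centred axial slab, minus old bone, with connected components below
50 voxels removed. The mineralization threshold defaults to
450 mg HA/cm³ and is deliberately configurable: the soft-tissue cutoff of
the FE material model (665) is documented, but the morphometric cutoff is
a declared stand-in. Empty segmentations report volume 0 and density NaN
(undefined, never 0).

## Virtual torsion

- **Discretization**: one trilinear hexahedral element per retained voxel.
  The emulated study used quadratic tetrahedra from a commercial mesher;
  the contract here is convergence to the analytic Saint-Venant oracle,
  not mesh identity, and a tetrahedral backend could sit behind the same
  `FEModel` interface.
- **Material model**: dual-zone. Below 665 mg HA/cm³ → 50 MPa; at or above
  (threshold is exclusive-below) → E = E_ref (ρ/ρ_ref)^γ clamped between
  the soft modulus and the law at ρ_max. The published ovine scaling law's
  coefficients are not printed in the source literature, so the default
  power law (E_ref = 20 GPa at ρ_ref = 1200 mg HA/cm³, γ = 1.5, in the
  range of trabecular/cortical density-modulus laws) is a declared,
  fully configurable stand-in; all validation is law-independent
  (oracle, linearity, monotonicity, recovery). Poisson's ratio 0.3.
- **Soft tissue vs air**: 50 MPa elements exist only inside the body mask;
  background air is excluded entirely.
- **Boundary conditions**: distal end plane fully fixed; proximal plane
  given the linearized rigid in-plane rotation about the section centroid
  with axial motion free (a torsion rig with axial float under pre-load).
  A fully-welded driven face would stiffen short specimens; for circular
  sections the difference vanishes (no warping).
- **Gauge length** = axial distance between the constrained planes.
- **Connectivity**: only the component bridging both end planes carries
  load; absence of such a component raises `DiscontinuousStructureError`
  rather than reporting VTR ≈ 0, because a nonunion is a categorical
  outcome, not a small number.
- **Solver**: assembled sparse stiffness (element matrices are one cached
  24×24 matrix scaled by each element's modulus, exact for axis-aligned
  cubes under 2×2×2 Gauss quadrature). Systems ≤ 20 000 free dofs go to
  SuperLU; larger ones use Jacobi-preconditioned CG started from the
  analytic twist field (relative residual ≤ 1e-8), which keeps iteration
  counts near 200 even at ~400 000 dofs because the start vector already
  solves the circular-section problem exactly.
- **Benchmark sizes**: the oracle cylinder is r_o = 8 mm, r_i = 5 mm,
  L = 8 mm at 0.4 mm spacing (20 voxels per outer radius, ~15 000
  elements), halved to 0.2 mm (~122 000 elements) for the convergence
  check; measured errors are ≈3% vs the closed form and ≈1.6% change on
  halving. Short cylinders are legitimate here because circular sections
  do not warp, so there is no Saint-Venant end-effect length.
- **Down-sampling** to the FE grid is block-mean pooling (zero-padded to
  a full multiple, conserving total mineral mass to round-off; audited at
  0.5%); non-integer ratios fall back to trilinear resampling with the
  audit relaxed to 2%.

## Biomechanics

Only the loading ramp (samples up to the torque maximum) enters the
regression; stiffness is the OLS slope of torque on rotation for samples
with 6 Nm ≤ τ ≤ 10 Nm. The lower bound skips the toe/settling region —
the synthetic trace generator includes a 0.5° toe precisely so this
window choice is consequential and testable. A trace that never reaches
(or barely clips) 6 Nm raises a window-unreachable error carrying the
trace's maximum torque; the pipeline records such limbs as missing rather
than extrapolating, and a fallback window remains a deliberate, off-by-
default caller decision.

The stiffness (Nm/deg) to rigidity (Nm²/deg) conversion necessarily
involves a length that the emulated study never printed; here
`rigidity = stiffness × gauge_length`, with gauge length an explicit
per-study setting (default 100 mm in synthetic studies) so the unit
system is auditable. The 5 N axial pre-load is metadata only.

## Histomorphometry

Hard-label inputs by contract: each pixel already carries one tissue
class. Global percentages are relative to non-background pixels; sector
percentages (cis cortex / endosteal / trans cortex) are relative to total
callus pixels and require the supplied sector masks to be disjoint and to
cover the callus. An optional ignore label handles slide artifacts. No
colour-based segmentation of raw photomicrographs is attempted.

## Statistics

- **Student's t**: pooled-variance (the classical test; Welch is not the
  default because the battery gates on Levene). Zero-pooled-variance
  conventions: equal means → p = 1, unequal → p = 0.
- **Normality**: the Kolmogorov–Smirnov screen uses the sample's own
  mean/SD, i.e. the Lilliefors variant, with table p-values; constant
  samples are non-normal by convention (p = 0).
- **Levene**: mean-centred variant; two identical multisets give W = 0,
  p = 1.
- **Mann–Whitney U**: for n_a + n_b ≤ 14 the two-tailed p is exact —
  every C(n_a+n_b, n_a) labeling of the pooled midranks is enumerated
  (vectorized, cached), so ties are handled exactly; the two-tailed p is
  the probability of a |U − n_a n_b/2| deviation at least as large as
  observed. Larger samples use the normal approximation with tie
  correction. At 6 + 6 and α = 0.05 the exact test's achievable size is
  38/924 ≈ 0.041 — discreteness, not an implementation artifact.
- **Selection rule**: t only when both samples pass normality and the
  pair passes homogeneity at α; otherwise Mann–Whitney. The group-table
  builder additionally honours per-parameter overrides (morphometry, VTR
  and histomorphometry endpoints parametric; biomechanics and ordinal
  scores nonparametric), matching how such batteries are conventionally
  pre-specified.
- **Cohen's d** uses the pooled SD and is computed for every parameter
  (callers can restrict reporting to significant rows); raw-sample and
  summary forms agree to 1e-12 by construction.
- **Multiplicity**: none — per-parameter α = 0.05 reporting, as is
  conventional for these exploratory batteries.

## Pipeline

Single-process, stage-sequential; per-subject seeds are spawned from the
study seed so subjects are independent and reruns bit-identical. In full
mode the intact contralateral FE model is computed once and shared across
subjects (the generator renders identical intact anatomy; per-subject
intact geometry would invalidate the cache). The manifest records package
version, seed, config hash and per-stage failures. Stage failures that
represent real study outcomes (nonunion, under-stiff limbs never reaching
the regression window) are recorded per subject and excluded pairwise in
the group table; anything else aborts the run with the stage and subject
named.

## Problem sizes in the shipped checks

Unit and acceptance checks run at desk scale by design: the oracle
cylinder sizes above; parameter recovery on the default 0.2-mm,
(180, 180, 300)-voxel scan with a 12 cm³ callus; 10 000 simulated 6 + 6
studies for null calibration; 200 replicate studies for power/direction;
500 traces for stiffness recovery. The full-image pipeline test uses two
subjects per arm at 0.4 mm generation / 0.8 mm FE spacing on a shortened
shaft.

## Known limitations

- Voxel (staircase) boundaries under-stiffen torsion models by a few
  percent at 20 voxels per radius; first-order convergent, and shared by
  all voxel-FE pipelines.
- The power-law modulus stand-in means absolute VTR values are not
  comparable to studies using the unpublished ovine law; comparisons and
  ratios within a study are.
- The generator's calluses are rotationally symmetric; segmentation
  performance on irregular real calluses is untested by construction.
- Whether the emulated study's simulated torsion drove rotation or torque,
  and its gauge length, are unstated in the source; both are explicit
  settings here (rotation-driven, gauge = constrained-plane distance by
  default).
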