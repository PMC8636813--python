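# Methods

This note records the models, conventions and numerical choices behind
`ventmorph`, and what the synthetic data can and cannot demonstrate.

## Canonical frame and alignment

All morphometry is defined in an RAS-like ACPC frame: the anterior
commissure (AC) at the origin, the AC→PC direction along −y (so PC sits at
`(0, −d, 0)` with `d` the AC–PC distance), the midsagittal plane at `x = 0`
and +z superior.  Axial slices are perpendicular to z, coronal slices to y.

Alignment is landmark-driven.  From AC, PC and one midsagittal point the
rigid transform is constructed directly: `e_y = (AC − PC)/|AC − PC|`, `e_z`
the component of (midsagittal − AC) orthogonal to `e_y`, `e_x = e_y × e_z`.
Collinear landmarks are rejected.  Automatic AC/PC detection is out of
scope; clinical practice places these landmarks manually.

Label volumes are resampled with nearest-neighbour interpolation (labels
must stay integer), intensity images trilinearly.  The output grid covers
the transformed head bounding box plus a one-voxel margin, and is snapped so
voxel centres sit on integer multiples of the spacing in the canonical
frame.  Two consequences: the AC always lands on a voxel centre, and
resampling a volume that is already lattice-aligned (identity transform, or
an exact quarter-turn without translation) reproduces it exactly.  The
output spacing defaults to the source spacing and is a free parameter.

## Measurement conventions

* Extents are distances between extreme voxel *centres* times the spacing —
  a convention that systematically underestimates a face-to-face extent by
  up to one voxel per end.  Every recovery tolerance below accounts for it.
* Ties in "maximal" searches break toward the slice or column closest to
  the AC, making all searches deterministic.
* The cranium interior (EI and z-Evans denominators) is recovered by
  hole-filling the head mask and removing the shell label; if no shell label
  exists the brain+ventricle mask is used and the measurement is tagged
  `brain-fallback`.
* The intercaudate line for the BCI is approximated as the line (within the
  axial ACPC plane, between PC and AC) maximising the ventricular width —
  caudate segmentations are not assumed to exist.  An explicit `y` override
  is unnecessary because the search reports the chosen line.
* The callosal angle uses least-squares lines fitted to the per-column roof
  (topmost ventricle voxel) of each lateral ventricle on the PC coronal
  slice, rather than a three-point vertex construction; fitted slopes are
  reported for audit.  Two flat roofs (|slope| < 1e-6) are a degenerate
  error, as is a side with fewer than three roof columns.
* Roof/top readings are robustified against nearest-neighbour aliasing:
  a column counts only with ≥ 3 voxels of support, tops are median-filtered
  over a 3-column window per hemisphere (the two sides are filtered
  independently so a partial medial column cannot validate its mirror
  image), and a boundary column is kept only when its top and voxel count
  are consistent with its inner neighbour.  On a genuine sloped roof the
  filter distorts the top surface by at most one column's drop
  (`slope × spacing`).

### Error model

For a roof of slope `s` sampled at spacing `Δ`, the centre-to-centre /
nearest-neighbour conventions carry intrinsic error of order `(1 + s)·Δ` in
the roof-dependent quantities (BVR numerator, CA roof line) and `≤ 2Δ` in
simple extents.  The recovery tolerances used throughout the tests are
`2Δ/denominator` for ratio indices, 2° for the callosal angle and 5% for
volumes; they are attainable when `s ≲ 1` on the native grid.  Two
measurements of the *same* geometry on different grids (e.g. posed vs
unposed phantoms) each carry an independent error, so their difference is
only bounded by the *sum* of the two bands; pose-invariance checks therefore
anchor to the analytic truth at the single band and to the companion
measurement at twice the band.  When a posed scan is re-aligned, label
aliasing on oblique walls adds noise comparable to the band at 1:1
resampling, so pose-invariance measurements resample at 0.7 mm (the resample
spacing being a free parameter) and use moderate roof slopes (s = 0.5);
steeper roofs (the hydrocephalic regime reaches s ≈ 1.8, i.e. CA ≈ 58°) are
exercised through ordering comparisons rather than absolute recovery.

## Phantoms

The phantom is a deliberately minimal head: a box or ellipsoidal cranium
interior wrapped in a shell of finite thickness, an axis-aligned brain box
strictly inside it, and a bilaterally symmetric ventricle pair strictly
inside the brain.  Three ventricle shapes are supported:

* `box` — prisms extruded along y, with separate frontal (anterior) and
  body widths switching at a small `frontal_onset_mm` (default 2 mm)
  anterior of the AC, so the width discontinuity never sits on the AC
  measurement plane;
* `wedge_roof` — the same prisms with roofs of slope `|dz/dx| = s`, giving
  a closed-form callosal angle `180° − 2·atan(s)`;
* `ellipsoid` — a mirrored pair of true 3D ellipsoids (closed-form volume
  `2·(4/3)πabc`).

Every index value is derived in closed form from the generative parameters
*before* voxelization; the derivations are straightforward slice geometry
(e.g. the z-Evans denominator under an ellipsoidal cranium is
`2Cz·sqrt(1 − (d/2Cy)²)` because the AC coronal plane sits `d/2` anterior of
the cranium centre).  Two shape-specific caveats are handled explicitly:

* for `wedge_roof`, the BVR numerator's maximum is attained at the lateral
  roof edge, so its truth is `brain_above + s·w_body`; validity constraints
  keep the wedge above the ACPC plane at body level;
* for `ellipsoid`, the BVR numerator's supremum (`brain_above + c`) is
  approached with unbounded surface slope and is *not* attainable on a voxel
  grid — the voxel measurement undershoots by `O(c·sqrt(Δ/a))`.  Ellipsoid
  phantoms are therefore validated against a quadric-roof bound
  `(c'·sqrt(2Δ/a') + 2Δ)/V` for BVR and the standard bands for everything
  else.

A rigid pose (Euler rotation + translation) models the scanner acquisition:
the voxel grid is axis-aligned in the world frame and the head sits in it at
the pose, exactly as a tilted acquisition would; landmarks are exported in
world coordinates.  Intensity images use fixed levels (background 0,
CSF 100, shell 300, brain 600) — an arbitrary T1-like ordering (CSF dark,
brain bright) sufficient for the threshold segmenter.

Randomized generators provide three regimes: a *recovery* regime (moderate
slopes s ∈ [0.5, 0.9], wedge bodies ≥ 18 mm wide, all truths attainable at
1 mm), and *hydrocephalic* / *healthy* regimes whose parameters mirror the
published group contrast (wide ventricles, tall horns, steep roofs vs the
reverse) for ordering properties.  A lattice caveat: because grids are
snapped to integer multiples of the spacing, specs whose extents are whole
millimetres place faces exactly on the worst-case sampling phase; test
fixtures use fractional-mm extents.

Anatomical realism — curved horn trajectories, DESH-type sulcal morphology,
partial-volume effects, noise and bias fields — is deliberately absent.
Passing phantom tests demonstrates that the geometry pipeline measures what
it claims on known shapes; it does not demonstrate segmentation quality on
real MRI, which is out of scope (masks are inputs).

## Volumetry and segmentation

Ventricular volume is exact voxel counting (`count × voxel volume / 1000`
cm³); an absent label yields a zero-volume warning rather than an error.
The bundled threshold segmenter (voxels below a threshold, 26-connected to a
seed) exists to exercise the intensity → mask → volume path on phantoms; it
is not a clinical segmenter.  Note the two lateral ventricles are separate
components, so full recovery takes one seed per side.

## Cohort simulation

The data registry (`ventmorph/data/paper_params.json`) carries the published
per-group means and SDs for all six indices (NPH, AD, HC, and the
Classic/Complex NPH subtypes), pre/post-drainage moments for responder and
non-responder groups (including the BVR-at-PC brain and ventricle components
in mm and 3D ventricular volume in cm³), comorbidity counts out of n = 21,
and the group sizes (9 responders / 12 non-responders; 6 Classic /
15 Complex).  One registry value is internally inconsistent — the responder
pre-drainage ventricle component SD of 0.490 mm against neighbouring SDs of
~5 mm — and is kept verbatim but flagged in the registry notes.

Subjects are drawn from a truncated multivariate normal whose marginals are
the registry moments.  Correlation is exchangeable across measures
(ρ_m = 0.5) and, for paired designs, Kronecker-structured across timepoints
(ρ_t = 0.9); neither correlation is published, so both are configuration
knobs with those defaults.  Truncation (ratios to (0,1), angles to (0,180)°,
positive quantities to (0,∞)) resamples invalid rows; at the published
moments the bounds sit ≥ 3 SD from every mean, so the moment bias is
negligible (the bias grows with the coefficient of variation; a marginal
rejection rate above 50% is treated as a parameter error).  Comorbidities
are independent Bernoulli draws at the published prevalences — no covariance
is published.  Outcome improvements for longitudinal designs are drawn in
open intervals excluding the exact 10% / 20% MCID boundaries so that the
responder label is recoverable without boundary ambiguity; this is a
modelling convenience, not a clinical claim.

## Clinical scoring

The mFI-11 score is the count of 11 binary comorbidity items; missing items
raise rather than impute.  The published comorbidity table lists a combined
cerebrovascular row, which maps onto the TIA/CVA item with "CVA with
neurological deficit" defaulting to absent, preserving the validated 11-item
instrument.  The frailty strata split at a score of 3 (0–2 vs ≥ 3).  The
responder rule is a conjunction with inclusive thresholds: best inpatient
domain improvement ≥ 10% AND reported functional improvement ≥ 20%.

## Statistics

Fisher's exact test sums hypergeometric probabilities of all tables (fixed
margins) no more likely than the observed one; the arithmetic is exact
integer arithmetic, with a 1e-12 relative tolerance on likelihood ties.
Mann-Whitney uses the exact permutation null (computed via the
Gaussian-binomial recurrence) for combined n ≤ 20 without ties, and
otherwise a normal approximation with tie and continuity corrections;
Wilcoxon drops zero differences (the Pratt variant is available behind a
flag), uses the exact subset-sum null for n ≤ 25 tie-free differences, and
the corrected normal approximation beyond.  The 20/25 crossovers are
configurable per call.  All tests are two-sided; exact two-sided p-values
double the smaller tail and cap at 1.  ICCs come from the two-way ANOVA
mean squares; both the absolute-agreement ICC(2,1) and the consistency
ICC(3,1) are provided because published repeatability figures rarely state
the model.  Comparison tables apply no multiple-testing correction (matching
the source analyses) but expose the number of comparisons so users can.

## Pipeline

`run_pipeline` chains cohort generation → phantom export → alignment →
measurement → scoring → tables.  Default problem sizes keep a full 21-subject
two-timepoint run desk-sized: phantoms at 0.6 linear scale, 1.5 mm
isotropic voxels, poses within ±10° / ±15 mm (chosen so every wedge roof
spans enough columns for the angle fit at that spacing).  Non-responders
shrink ventricular extents by 3% post-drainage, emulating the published
direction of change; responders are left unchanged.  Outputs carry a SHA-256
config hash, and deterministic stages are byte-identical across reruns of
the same config.

## Known limitations

* Phantom geometry is piecewise-quadric and bilaterally symmetric; no
  attempt is made at anatomical fidelity, and the callosal angle is only
  analytically defined for wedge roofs.
* The centre-to-centre extent convention biases absolute extents low by up
  to one voxel per end; ratios partially cancel the bias but inherit the
  `2Δ/denominator` uncertainty.
* Simulated cohorts reproduce first and second moments and a chosen
  correlation structure, not the joint distribution of real morphometry.
* The threshold segmenter has no partial-volume or noise handling and no
  rule for excluding falsely-included CSF-intensity voxels, for which no
  reproducible published rule exists.
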