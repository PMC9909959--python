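# Methods

This note records the models, conventions and numerical choices behind
`ctoam`, in the spirit of a methods appendix: what is computed, under which
assumptions, and what the synthetic validation does and does not show.

## Density scheme

Subchondral bone is partitioned into 12 closed integer HU intervals,
100–200, 201–300, …, 1101–1200 and 1201–maximum, grouped into low (1–4),
medium (5–8) and high (9–12) classes.  Two conventions follow from the
integer interval labels:

* **Float HU are rounded to the nearest integer before binning**, making bin
  membership exact and the partition gapless over the integers: every HU
  ≥ 100 belongs to exactly one bin (property-tested by sweep).
* **Voxels below 100 HU are outside the bone tissue of interest** — they
  enter neither a bin nor the %BTV denominator.  This preserves
  Σ %BTV_i = 100 exactly (to 1e-9 in floating point) and treats sub-100 HU
  material as marrow/soft tissue rather than mineralised bone.  Whether any
  sub-100 HU material should count toward the denominator is a genuine
  modelling choice; this package excludes it and flags the choice here.

HU are stored as int16 with the CT air floor clamped at −1024.

## BTOI extraction

The bone tissue of interest spans the articular surface to the epiphyseal
line.  Extraction is a deterministic equivalent of interactive mask editing:
threshold at 100 HU (aligning the ROI with the lowest density interval),
keep the largest 26-connected component, clip at the epiphyseal plane
(femur: keep inferior voxels, z ≤ plane; tibia: keep superior voxels), and
re-reduce to the largest component.  26-connectivity is used for all 3D
component operations; it is the conventional choice for blob extraction and
is fixed so results are reproducible.

The epiphyseal line is modelled as a **flat plane** perpendicular to the
inferior–superior axis.  Real epiphyseal lines are curved; a plane keeps the
ROI contract exact and testable, and the plane index is always overridable.
Auto-detection picks the z slice of minimum in-mask mean HU (the
growth-plate remnant is less dense than surrounding bone); it is best-effort
and should be reviewed.  How far the BTOI extends below the surface is
governed entirely by the plane; no fixed-depth shell is imposed by default.

## Surface mapping and regions

The density map is a **maximum-intensity projection along z**: each (x, y)
column that intersects the BTOI contributes its maximal HU.  MIP (rather
than mean) is the densitogram convention — maxima carry the high-density
areas the method counts.  Projection along true surface normals is out of
scope; for the near-axial articular surfaces analysed here the z-column
approximation is standard.

The nine anatomical regions are an **equal-thirds grid over the footprint
bounding box**: rows anterior→posterior, columns medial→lateral, region
= (row−1)·3 + column, region 5 central.  The medial column maps to low x
for a right knee and high x for a left knee, so numbering is anatomically
mirrored between sides.  This grid is an explicit convention (published
region drawings cannot be reduced to text); all cohort arithmetic and
pattern rules are defined on top of it and are mirror-invariant by
construction.

High-density areas are 8-connected pixel components with projected HU
≥ 901 (the lower edge of the high-density class — studies rarely print
their cutoff, so the class boundary is the default) and area ≥ 25 mm²;
both are configurable.  Cohort frequency = number of knees in which ≥ 1
area touches a region; percentages are integers, nearest-integer rounding
with halves away from zero (verified against every published count→percent
pair available: 24/30→80%, 28/30→93%, 17/30→57%, 19/30→63%, …).

## Pattern taxonomy

The label names and their bone-applicability come from clinical CTOAM
reporting; the decision rules are this package's operationalisation, fixed
for determinism (precedence resolves overlaps; classification is a total
function):

* femur — Blank (no area) ≻ Center Connections (one component touches both
  region 4 and region 6, i.e. bridges the central row) ≻ Anterior-Lateral
  (every component centroid in the anterior-lateral quadrant of the
  footprint) ≻ Dual Center (all remaining multi-/off-centre
  configurations).
* tibia — Blank ≻ Multi-Center Connections (one component spans ≥ 2 of the
  three columns) ≻ Multi-Center (≥ 2 components each ≥ 100 mm²) ≻ Scatter.

The 100 mm² "center" threshold and the quadrant definition are parameters.
Whether "Dual Center" demands exactly two centres is not defined in the
source taxonomy; here it is the fall-back for every non-blank femoral
configuration that is neither a central bridge nor purely anterior-lateral.

## Statistics

Per density bin, the two groups are compared after a one-sample
Kolmogorov–Smirnov screen against a normal law with the sample's own mean
and SD.  KS with estimated parameters (no Lilliefors correction) is known to
be conservative — it under-rejects normality — which matches the procedure
as conventionally described; the consequence is that the pooled-variance
Student t carries most comparisons, with Mann–Whitney U as the non-normal
branch.  Degenerate comparisons (both samples constant and equal, e.g. an
empty bin in both groups) are reported as P = 1 with a flag rather than
tested.  No multiple-testing correction is applied by default, matching the
per-bin reporting convention; Holm/Benjamini–Hochberg and Welch variants are
available as options.  Left–right contrasts within a group are two-sample by
default (cohort tables are reported without pairing detail); a paired mode
(paired t / Wilcoxon) exists.

Calibration, measured by the acceptance suite on the scaled-down phantom
(below): with two control-like cohorts of n = 15 over 1000 replicates, the
per-bin rejection rate at α = 0.05 stays within 0.05 ± 0.02 for every bin
that is testable in ≥ 95% of replicates; bins the control profile leaves
empty are degenerate and cannot reject.  Power is monotone in effect size,
and the default judo-like shift is flagged "higher in judo" in every medium
bin in ≥ 90% of seeds.

## Phantom generator

The generator exists to make every stage testable with exact ground truth;
it emulates topology and contrast, not anatomy.

* **Geometry** — distal femur: two condylar ellipsoids joined by an anterior
  trochlear bridge and a shaft; tibial plateau: two compartment cylinders
  joined by a central block with a flat plateau.  Default grid 48×48×40
  voxels at 0.625 mm isotropic (thin-slice knee CT), subchondral shell
  10 mm, epiphyseal plane derived from the surface extremum plus the shell
  thickness.
* **Control-like field** — laminar: HU = baseline + A·exp(−depth/τ) with
  baseline 160 HU, A = 300 HU (subchondral plate ≈ 460 HU), τ = 3 mm.
  The profile concentrates %BTV in the low bins with a small medium tail,
  the shape seen in untrained knees.
* **Judo-like field** — the same laminar background plus concentric Gaussian
  foci on the articular surface at anatomical regions 4, 5, 6 (amplitude
  600 HU, σ = 4 mm).  Defaults were chosen so that (a) the direction of the
  group contrast matches the published finding — athlete-like knees higher
  in the medium and high bins, control-like higher in 100–300 — and (b) the
  foci project to countable high-density areas (≥ 25 mm² above 901 HU) over
  the central regions.  Magnitudes of published group means are *not*
  targeted; they depend on the authors' scanners and subjects.
* **Noise** — additive Gaussian HU noise (default SD 30), truncated at the
  −1024 air floor.
* **Ground truth** — the BTOI mask is derived from the emitted volume by the
  same contract the extraction stage implements (threshold, largest
  component, plane clip), so recovery is exact even when boundary noise
  moves single voxels across 100 HU; per-bin voxel counts are a direct
  closed-interval scan of the emitted voxels, independent of the analysis
  path's binning code.
* **Cohorts** — per-subject seeds derive from a master seed via
  `SeedSequence(seed, group, subject)`; inter-subject variability is
  multiplicative log-normal jitter on the laminar and focus amplitudes
  (σ_log = 0.15) and the baseline (σ_log = 0.05).  Default group size 15.

**What phantom tests do not show.**  The phantoms have no trabecular
texture, beam hardening, partial-volume blur, cartilage, or anatomical
shape variation; the epiphyseal boundary is a plane and the articular
surfaces are smooth quadrics.  Passing tests demonstrate the correctness of
the measurement pipeline (segmentation, binning, projection, counting,
statistics) under known ground truth — not that the pipeline's anatomical
conventions (region borders, pattern rules) coincide with any particular
published atlas.

## Numerical choices and problem sizes

* Integer percentage rounding is computed in exact integer arithmetic
  (`(200·c + n) // (2·n)`), never through floats.
* Binning uses `searchsorted` on the interval lower edges; ties at interval
  boundaries are impossible after integer rounding.
* Largest-component ties break toward the lowest label index (deterministic).
* Writers embed no timestamps (gzip members use `mtime=0`, empty filename),
  so pipeline reruns are byte-identical and the manifest hashes stable.
* Replicated statistical studies (null calibration: 1000 replicates × two
  n=15 cohorts; power: 100 seeds) run on a 28×28×24-voxel phantom with an
  8 mm shell — the same fields and jitter at a smaller geometry, chosen to
  keep thousands of cohort draws tractable on a desktop.  Direction and
  calibration results were spot-checked against the full-size geometry.
* Noise SD 30 against 100-HU-wide bins implies a one-sided leak of up to
  ~4.6% across a bin boundary, so a noisy volume's composition can differ
  from its noiseless counterpart by several %BTV points; this is a property
  of the binning grid, not an estimator error.  Recovery is therefore
  validated against the emitted volume's exact ground truth (where the
  pipeline is voxel-exact), and the noisy-vs-noiseless shift is
  characterised separately.

## Known limitations

* The epiphyseal plane is flat; strongly oblique growth-plate remnants
  would need a curved boundary.
* MIP along z under-represents density on steep surface flanks.
* The nine-region grid is bounding-box based; footprint outliers stretch
  the bands.
* The KS gate inherits the conservatism of estimated-parameter KS; users
  wanting a calibrated normality screen should apply a Lilliefors table
  externally.
* DICOM support covers single uncompressed CT series (read-only).
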