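# Methods

This note documents the models, numerical choices and limitations behind
`atlasquant`. It is written for someone who wants to trust (or break) the
pipeline, not just run it.

## Image model

All volumes live on axis-aligned 3-D grids: `shape` voxels, `spacing` mm,
`origin` mm at voxel (0,0,0). Physical coordinates are
`origin + index·spacing`; no rotation is supported because nothing in the
pipeline requires oblique geometry. NIfTI-1 is the on-disk format; PET
frame timing travels in a CSV sidecar (`mid_time_min,duration_min`) since
NIfTI has no standard PET timing extension. Label maps round-trip as
int32, bit-exactly.

## Synthetic phantom

The phantom emulates the study conditions the analysis was designed for:
one reference subject and a cohort of deformed subjects with known
ground truth for every quantity the pipeline reports.

**Anatomy.** Tissues are geometric primitives (ellipsoids, elliptic
tubes/annuli) in normalized [0,1]³ coordinates, so one anatomy definition
serves any grid: a head with a brain; a torso with two low-signal lungs,
a heart, a liver, a deliberately tiny pancreas, an aorta tube, three VAT
blobs and a subcutaneous fat ring; two legs with bone cores and muscle
annuli; a bright bone scaffold (spine + leg bones); and soft-tissue
filler inside the body envelope. Primitives must be pairwise disjoint
(checked; violations name the colliding pair). The default grid is
(64, 48, 160) voxels at 4 mm — large enough for distinct organs, small
enough for minute-scale test runs; the cohort/registration tests use a
reduced (40, 32, 96) grid for the same reason.

**MR signal.** Per tissue, water `= (1−FF)·S` and fat `= FF·S` with total
signal `S` (bone brightest at 2.0, lungs 0.15, everything else 1.0), plus
Gaussian noise (σ = 0.02 signal units, ~2 % of soft tissue) and a
magnitude floor at zero. Fat fractions range from 0.02 (aorta blood) to
0.92 (SAT).

**Kinetics.** Each tissue follows the irreversible two-tissue-compartment
model `dC1/dt = K1·Cp − (k2+k3)·C1`, `dC2/dt = k3·C1`,
`C_t = C1 + C2 + Vb·C_wb`. Parameters were chosen once to give influx
rates in the range clamped FDG studies report (×10⁻² /min): brain 2.06,
heart 3.0, muscle 1.04, liver 0.60, VAT 0.46, SAT 0.25, lungs 0.14,
pancreas 0.37; the aorta is a pure blood pool (Vb = 1, K1 = 0). The
arterial input is the conventional Feng model
`Cp(t) = (A1·t − A2 − A3)e^{λ1 t} + A2 e^{λ2 t} + A3 e^{λ3 t}` with the
standard constants (A = 851.12, 21.88, 20.81; λ = −4.134, −0.119,
−0.0104 min⁻¹). The aorta carries *whole blood*
`C_wb = Cp·(1 − Hct·(1−r))` (Hct 0.45, r 0.8), so the pipeline's
blood-cell correction is exercised, not bypassed. The compartment ODE is
integrated with an exact exponential-integrator recursion on the dense
plasma grid (piecewise-linear Cp), and frame values are time-averages
over each acquisition window. PET noise is Gaussian with
σ = scale·√(C/duration) (scale 0.3 kBq/ml·min^½) — a
reconstruction-domain approximation of count statistics, not a
projection-domain Poisson model.

**Frame schedule.** 16 early frames over 0–10 min (8×15 s, 8×1 min)
followed by five contiguous 12-min whole-body passes, mids 16–64 min —
a one-hour examination with no sampling gap, so the trapezoidal plasma
integral stays accurate. `n_body_frames` marks the whole-body passes; the
default Patlak start time t\* is the first of them.

**Deformed subjects.** A subject field is
`T(x) = c + S(x−c) + t + u(x)`: anisotropic scaling about the grid
centre, translation, and a band-limited random displacement (white noise
smoothed with a 24 mm Gaussian, rescaled to a 4 mm peak). Cohort defaults
draw scales from (0.93, 1.07) and translations up to ±6 mm. On top of
the global field, the pancreas analogue receives an *independent*
Gaussian-windowed shift per subject (up to ±8 mm, 20 mm window): small
abdominal organs move between subjects independently of body habitus,
and — because the pancreas has almost no water/fat contrast against the
surrounding soft tissue — the registration cannot see or recover that
shift. This one mechanism reproduces the characteristic failure of
single-atlas segmentation on small mobile organs (cohort Dice ≈ 0.9 for
large tissues vs ≈ 0.1–0.3 for the pancreas analogue) without touching
the large-tissue behaviour. Fields with
non-positive Jacobian are rejected. Subject images are the reference
pulled through the numerically inverted field (fixed-point iteration;
the affine part makes it a contraction); labels use nearest-neighbour.
The subject's PET is re-simulated from its deformed label map with fresh
seeded noise rather than interpolated from the reference series — an
interpolated 4-D series would double-blur boundaries and contaminate the
aorta IDIF with partial-volume signal that no real acquisition has.
Identity parameters return a voxel-identical copy.

## Registration

A dependency-light multi-resolution demons scheme on the joint
(water, fat) channels, intensity-normalised by their 99th percentiles,
with SSD similarity. Three stages honour the anatomy prior — bone, then
lean (FF < 0.5), then adipose (FF ≥ 0.5) — via similarity weight masks
computed from the *reference* FF and water intensity (the bright bone
scaffold stands in for the skeleton; no CT exists in the phantom), with
a floor of 0.05 outside the stage mask so the field stays driven
everywhere. Elastic regularisation is a Gaussian on the displacement
field with σ = 4 / 2 / 1 voxels for bone / lean / adipose — strictly
decreasing, "gradually allowing more elasticity" (enforced at
configuration time). Each stage runs a 3-level pyramid (factors 4/2/1,
iteration caps 80/40/15); updates are the classic
`−(M∘T − F)·∇F/(|∇F|² + diff²)` force, fluid-smoothed (σ = 1 voxel),
step-capped at 0.4 of the level spacing, and rejected (with temporarily
increased smoothing) if they would fold the field. A stage that fails to
improve its weighted SSD reverts to its starting field, so the per-stage
similarity is non-increasing by construction. The estimated field maps
reference voxels to subject physical coordinates (pull-back), which makes
reference-space readout, label propagation and Jacobian volumetry each a
single-interpolation operation.

Registering identical images yields exactly the identity field (zero
force everywhere), which is what makes the pipeline's self-consistency
check exact rather than approximate.

## Quantification

Lean VOIs keep FF < 0.5, adipose keep FF ≥ 0.5 — lean strict, adipose
inclusive, so the two rules partition FF space and no voxel is orphaned
at the threshold; class "other" is unfiltered. Volumes use `Σ|J|·v_voxel`
(the fields are constrained orientation-preserving, so `|J| = J` in
practice). FF and Ki readouts (mean and median) are taken in reference
space from the subject's warped images, as single-atlas protocols do;
this choice changes partial-volume behaviour and is deliberate.
`TTUR = Ki_mean × volume`, reported in Ki-unit × L (the definition
consistent with combining an uptake column and a volume column).

**Partial-volume behaviour.** A warped voxel near a tissue boundary
blends the tissue's Ki with its neighbour's. The *median* readout is
robust to this (interior voxels dominate: ≤ 2.6 % error for well-resolved
tissues, noiseless, true field); the *mean* is not when the contrast to
the neighbourhood is large — the phantom's lungs (Ki 0.14×10⁻² beside
soft tissue at 0.69×10⁻²) show mean-readout inflation of tens of
percent, the same qualitative failure clinical whole-body studies report for
lungs and heart. At desk-scale grids this effect is exaggerated relative
to clinical resolution because surface-to-volume ratios are a few times
larger; passing tests on the phantom therefore demonstrate machinery
correctness and error *structure*, not clinical-scale error magnitudes.

## Kinetic analysis

The IDIF is the per-frame mean over the aorta VOI; plasma correction
divides by `1 − Hct·(1−r)` (defaults 0.45 / 0.8, configurable — the
standard form, since the protocol itself only states that a correction
was applied). `∫₀ᵗCp` is a trapezoid on the plasma sampling grid with
`Cp(0) = 0`; Patlak is ordinary least squares on frames with mid-time
≥ t\*. The voxel-wise fit shares its regressors across voxels and
reduces to a closed-form covariance ratio. With a multi-exponential
input the apparent Patlak intercept drifts slowly, biasing the slope by
−2…−4 % when fitting from the first whole-body frame (16 min) and
≤ 1.3 % from 40 min; the oracle checks therefore fit from 40 min while
the pipeline default remains the first whole-body frame, matching the
acquisition. Decay correction is assumed already applied (reconstruction
convention). The M-value helper implements
`M = GIR(steady state 60–120 min) / lean body mass`.

## Validation statistics

Dice `2|A∩B|/(|A|+|B|)` (two empty masks ⇒ 1.0 with a warning); paired
two-tailed t on automated−reference differences (exactly equal vectors ⇒
t = 0, p = 1; zero-variance non-zero differences ⇒ p = 0 with a flag);
R² as squared Pearson correlation (equal to OLS R² for a simple
regression, so regression direction is immaterial; exactly equal vectors
⇒ 1.0 by convention, a constant prediction ⇒ 0.0). Associations are
computed subject-wise per tissue. The report footer includes the mean
absolute volume difference over significantly different tissues. The
phantom's "reference arm" reads each subject's own true label map in
subject space with the identical tissue-class FF filter — the
manual-segmentation analogue that makes the self-consistency run exact.

## Numerical and design notes

* Label propagation is nearest-neighbour (as in the protocol). Its
  irreducible error is surface-voxel quantisation: flips occur at a rate
  proportional to the per-axis shrink of the field, so the
  ground-truth-recovery oracle uses a gentle family (scales 0.99–1.07,
  3 mm jiggle) where quantisation stays below the oracle tolerance, while
  the registration benchmark uses the full cohort range. Sub-voxel-thin
  tissues (the pancreas analogue, ~1.4 voxel half-thickness) are exempt
  from near-perfect-overlap assertions by design — they exist to probe
  the small-tissue failure mode.
* Volume/Ki ground-truth-recovery checks cover the measured-VOI set
  (brain, lungs, liver, VAT, SAT, muscles). The bone scaffold and the
  aorta are analysis infrastructure — registration driver and IDIF site —
  not quantified tissues, and as thin tubes their voxel-count *truth*
  itself jumps by whole surface rings under scaling (±10 % at desk
  resolution), which is quantisation of the reference standard rather
  than pipeline error.
* Patlak preconditions (≥ 2 frames past t\*, positive plasma) raise
  explicit errors; voxels with non-finite input are zeroed and flagged.
* All generators are deterministic under a fixed seed; the pipeline
  draws every per-subject seed up front so `--resume` cannot change
  results (resumed CSVs are re-read with round-trip float precision and
  are byte-identical to a fresh run).

## Known limitations

* No MR acquisition physics: no bias fields, no T1/noise bias in FF, no
  multi-echo fat–water decomposition with T2* — the FF substrate is the
  idealised 2-point-Dixon ratio.
* No PET reconstruction modelling (attenuation, scatter, projection-space
  Poisson noise, motion); noise enters in image space.
* The demons scheme is a documented, dependency-light stand-in for
  production whole-body registration; it is not inverse-consistent or
  diffeomorphic-by-construction, and recovers large global scalings only
  approximately (mean Jacobian ~7 % low on a ×1.1 scaling test).
* Phantom anatomy is schematic (no organ-shape realism, no respiratory
  motion), so absolute accuracy numbers do not transfer to clinical data;
  orderings and failure modes do.
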