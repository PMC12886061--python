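# Methods

This note documents the models, conventions and design choices behind
`reirrad`: what the synthetic benchmark simulates, how each quantity is
defined, and where the implementation had to pick one of several defensible
dialects.

## Coordinate and transform conventions

All spatial quantities live in one fixed patient-based world frame in mm.
Voxel indices are 0-based; index `i` maps to `origin + axes · (spacing ∘ i)`
with an orthonormal direction-cosine matrix `axes`. Every transform is a
pull-back: it maps a point on the current (reirradiation) CT to its source
location on the previous CT, because structures and doses are always
materialised on the current anatomy. Push-forward fields are out of scope.

Masks are resampled by trilinear interpolation of the binary array followed
by a 0.5 threshold (smoother surfaces than nearest-neighbour at coarse
spacing); doses by trilinear interpolation with out-of-volume samples set to
0 Gy and the in-volume fraction reported as a coverage figure, so silent
extrapolation cannot corrupt a DVH unnoticed. Doses are stored as 32-bit
floats, masks as 8-bit integers.

## The phantom and what it does (not) emulate

A case is a 192 mm cube of thorax, by default 96 × 96 × 64 voxels at
(2, 2, 3) mm. The current-course anatomy is analytic: two lung ellipsoids, a
heart ellipsoid, tubular spinal cord / oesophagus / trachea / aorta, and two
bronchial tubes (the only allowed organ overlap is bronchi inside lungs).
The ground-truth deformation is a Gaussian-filtered random 3-vector field
(default maximum displacement 10 mm, kernel scale 30 mm) plus a small affine
part (≤1°, ≤2 mm); the previous-course anatomy is the current one carried
through the (fixed-point-iterated) inverse of this field. The deformation
amplitude/smoothness defaults were chosen so the field is clearly non-rigid
over the evaluated region — anatomies separated by months to years of
interval change — while staying invertible: case generation rejects any
field with more than 1% non-positive Jacobian determinants.

Doses are spherical sigmoid-falloff targets: the 50% isodose radius follows
the case's PTV volume, the peak equals prescription × escalation (150% for
the 3-fraction stereotactic schemes, 1.3 for the 50 Gy/24 fx scheme with
mean-GTV escalation to 65 Gy, 1.0 for homogeneous normofractionation), and
the previous-course target is offset ~9 mm so the two 50% isodoses overlap.
The seven default cases take their fractionation schemes, PTV volumes and
inter-course intervals from the embedded case table (medians 53 cm³, 54 cm³
and 46 months); the seventh case is the stress scenario: the current-course
left lung is collapsed (shifted medially/superiorly by 30 mm and shrunk), a
change no smooth field explains, emulating an atelectasis appearing between
courses.

Simulated centres model *workflow* variability, not algorithm internals:
each centre's DIR is the ground-truth field composed with a smooth random
residual field (default 1 mm RMS, 25 mm smoothness); its RIR is the
least-squares proper rigid (Procrustes) fit to the ground-truth field over a
60 mm sphere around a per-centre jittered anchor near the current target
(10 mm jitter), composed with a small random rigid residual of 3 mm RMS
displacement. The rigid residual splits its variance between a translation
and a rotation about the anchor, so RIR submissions keep an exactly rigid
transform. The σ_DIR < σ_RIR default encodes the working hypothesis that
deformable workflows align OARs more consistently; both amplitudes are
calibration choices, not measured quantities.

The phantom deliberately omits: CT intensity texture and intensity-driven
registration, 4DCT breathing phases, auto-contouring error, and multiple
vendor engines. Passing tests therefore demonstrate that the *evaluation
machinery* is correct and that the pipeline detects known, controlled
differences; they do not validate any clinical registration algorithm.

## Consensus (STAPLE)

Binary STAPLE EM: E-step posterior of foreground per voxel given rater
sensitivities/specificities and a global prior; M-step re-estimates the
rater parameters; convergence when all |Δp|, |Δq| < 1e-6 (max 100
iterations), parameters clamped to [1e-6, 1−1e-6]. The prior is spatially
uniform, equal to the mean rater foreground fraction inside a bounding box
dilated 10 voxels around the union of raters — the classic full-volume prior
is biased by the large empty background. The consensus is posterior ≥ 0.5,
ties included. Multi-label and spatially varying-prior variants are out of
scope.

## Geometric metrics

Before any metric, both masks are restricted cranio-caudally to the axial
slices between the lowest and highest slice whose current-plan EQD2 maximum
reaches 2 Gy (full transversal extent kept). The restriction dose is a
single EQD2 conversion of the current plan at α/β = 3 Gy; this is a
geometric gate only, and the 1 Gy-scale difference a cord-specific
conversion would make at the 2 Gy level moves the gate by at most a slice.

Surfaces are the centres of boundary voxels (foreground with ≥1
face-adjacent background neighbour); directed distances come from the exact
Euclidean distance transform on the anisotropic grid, and MSD / HD-98% pool
the two directed samples into one set (mean, and 98th percentile by linear
interpolation between order statistics). These are deliberate, oracle-
checkable dialect choices — mesh-based surfaces or per-direction averaging
would give slightly different numbers — and are printed as dialect flags in
every manifest. The unit tests verify all three surface metrics against an
O(n²) all-pairs brute-force oracle to 1e-9 mm.

## Dose accumulation

Order of operations is fixed: map the previous-course *physical* dose, then
convert to EQD2 (`EQD2 = D·(D/n + α/β)/(2 + α/β)`, per-fraction dose taken
voxelwise as D/n, so escalated subvolumes deliver more per fraction).
Conversion is per organ with that organ's α/β (cord 2 Gy, others 3 Gy), so
the artificial step a mixed-tissue conversion would create never enters a
DVH; no tissue-recovery discounting is applied. The suite asserts the
guard-rail that physical-dose summation is *not* equieffective summation.

## DVH statistics

Cumulative DVHs use the ≥ convention on a uniform 0.1 Gy axis (V(0) = 100%,
non-increasing), computed on the organs as delineated on the current course;
absolute (cm³) and relative (%) axes are both emitted. D_0.3cm³ is read from
the absolute curve by linear interpolation; organs smaller than 0.3 cm³ are
flagged and report their maximum dose. Bands across centres are pointwise
order statistics (percentiles by linear interpolation; shorter curves padded
with 0%); the band area is Σ_d IQR(d) · 0.1 Gy in Gy·%. Constraint
distributions are symmetrised by subtracting the (min+max)/2 midpoint of
each case/organ/method group — a display convention that puts the extreme
centres at ±range/2.

## Mixed-effects models

For each organ and metric (and pooled across organs), a linear mixed model
with the DIR-vs-RIR indicator as fixed effect and crossed random intercepts
for patient and centre, fitted by REML (statsmodels MixedLM with variance
components on a single all-encompassing group); the method effect is tested
with a two-sided Wald z-test at 5%. No multiple-testing correction is
applied across organs/metrics. Because a model on raw constraint doses
would test dose *level*, variability enters as explicit responses: (a) each
centre's absolute deviation of D_0.3cm³ from the patient-wise median within
method (default), and (b) the per-patient DVH band IQR area (one value per
patient × method, patient intercept only). Singular fits (a variance
component at the boundary) are reported with a flag, never silently
dropped. Monte-Carlo calibration on records with known variance components
shows the estimator unbiased (within 10% at δ=2) and the Wald test's type-I
error close to nominal over 200 null replicates.

## Exclusion gate

A case is excluded from all dose analyses when some organ's MSD against the
delineated reference exceeds 10 mm for *every* centre under *both* methods —
a numeric stand-in for the clinical judgement that no acceptable transfer
exists, which the stress case triggers by construction. Excluded cases keep
their geometric records; exclusions are listed in the manifest and summary.

## Problem sizes and determinism

The default phantom grid is 96 × 96 × 64 at (2, 2, 3) mm. The test suite and
the acceptance script run the same anatomy on coarser lattices covering the
identical 192 mm cube — 48 × 48 × 32 at (4, 4, 6) mm for single-run checks
and 32 × 32 × 24 at (6, 6, 8) mm for the 20-replicate method-effect power
study — sizes chosen as the coarsest grids at which thin tubular organs
remain resolved. One-voxel resampling tolerances in the tests scale with the
voxel diagonal accordingly. Every run derives all randomness from a single
seed (per-case generator and centre-error seeds are spawned from it and
recorded in the manifest), and identical seeds reproduce byte-identical CSV
outputs.

## Known limitations

- Contour-based evaluation only; no landmark or image-similarity QA, no
  Jacobian or inverse-consistency maps of the simulated fields beyond the
  invertibility gate.
- Analytic anatomy and dose; no CT intensities, so intensity-based DIR
  cannot be run on the phantom — centre behaviour is simulated, not
  executed.
- The rigid residual model perturbs the fitted transform; it does not model
  systematic vendor-specific rigid strategies.
- DICOM import (CT/RTSTRUCT/RTDOSE) is a documented future path; the on-disk
  format is NIfTI + JSON sidecar.
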