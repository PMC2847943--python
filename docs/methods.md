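# Methods

`osteoct` quantifies the mineralized-bone response to an intraosseous lesion
from micro-CT volumes, and ships a synthetic femur cohort on which every
step of that quantification can be validated against known ground truth.
This note documents the models, the parameters that matter, the numerical
conventions, and what the synthetic cohort does and does not establish.

## The femur phantom

The phantom reduces a murine distal femur to the features the measurements
depend on:

* **Cortical shell** — a hollow cylinder along z (outer radius 1.2 mm,
  thickness 0.25 mm, 1200 mg/cm³ mineral density).
* **Trabecular lattice** — parallel plates orthogonal to the bone axis
  (thickness 40 µm, spacing 220 µm, 1000 mg/cm³) filling the metaphysis,
  plus sparse vertical rods (radius = half the plate thickness, ≈1% of the
  compartment volume) for connectivity. Plates are subdivided into six
  angular sectors, and each sector's plate stack is phase-shifted by 1/6 of
  a lattice period along z. The stagger serves two purposes: any axial
  analysis window samples the lattice at six phases, so finite-window volume
  fractions are unbiased (no fencepost artifact); and sagittal sections of a
  lesioned bone genuinely differ between section levels, as real histology
  does. One buffer period of lattice sits below the ROI anchor so the
  standard metaphyseal window lies in the lattice interior.
* **Growth plate** — a 0.12 mm zero-density disc below the lattice;
  `growth_plate_z` is the operational landmark all ROIs anchor to.
* **Marrow** — 30 mg/cm³ mineral-equivalent, varying per femur (lognormal,
  cv 0.3; red/yellow marrow composition is local biology).

Because the plates are parallel and axial, the Parfitt plate-model formulas
TbN = (BV/TV)/TbTh and TbSp = 1/TbN − TbTh are *exact* on the generating
geometry; the ground truth (TbN = 1/period = 3.85 /mm, TbTh = 0.040 mm,
TbSp = 0.220 mm) is therefore analytic, while BV/TV and the mean densities
are measured on the generated voxel grid (brute-force counts, exact by
construction).

The base grid is 8 µm isotropic (≤ TbTh/4, enforced), float32,
(1125 × 340 × 340) voxels per femur.

## The tumor transform

The lesioned (right) femur differs from its vehicle control by:

* **element-wise trabecular removal** — each plate sector and rod is deleted
  independently with probability 0.4 (matching the ≈40% TbN/BV-TV loss such
  models show), and survivors' thicknesses are jittered lognormally
  (σ = 0.2): heterogeneous thinning, thickening and loss;
* **inward cortical thickening** — shell thickness × 1.35, the osteoblastic
  host response;
* **marrow infiltration** — marrow density rises by a median 30 mg/cm³
  (lognormal σ = 0.6 across animals), tumor tissue replacing fatty marrow;
* **undermineralization of surviving trabeculae** — tissue density × 0.85
  (lognormal σ = 0.1), woven bone and osteoid being less mineralized.

The transformed volume is repainted from the surviving element list, and the
ground truth is re-measured from the realized geometry, not the expectation.
The last two items matter less for the morphometry itself than for the
*histograms*: they are what makes histogram-derived automatic thresholds
drift in diseased bone.

## The scanner model

Acquisition is modelled as block averaging of the density grid to the target
voxel size (the partial-volume effect dominating mouse trabecular µCT), a
linear density→HU map, additive Gaussian noise, and a two-density
calibration insert (0 and 1000 mg/cm³) appended inside the field of view.
Four resolution classes mirror a typical in vivo / ex vivo protocol:

| class | realized voxel | HU gain | noise SD |
|---|---|---|---|
| invivo91 | 88 µm | 1.0 HU/(mg/cm³) | 40 HU |
| exvivo31 | 32 µm | 2.2 | 80 HU |
| exvivo16 | 16 µm | 2.2 | 120 HU |
| exvivo8  | 8 µm  | 2.2 | 200 HU |

The nominal 91 and 31 µm classes are realized at 88 and 32 µm — the nearest
integer multiples of the 8 µm base grid, which keeps resampling an exact
block average. The ex vivo scanner reports a hotter HU scale (gain 2.2×),
which is why its useful thresholds live in the thousands of HU while the
in vivo scale lives in the hundreds. Noise grows as voxels shrink (photon
statistics). The finest class images only the metaphysis (limited field of
view). Beam hardening, scatter and detector blur are not modelled.

HU→density calibration is ordinary least squares through the insert means;
calibrated densities are clipped at zero (mineral mass density).

## Regions of interest

All ROIs anchor to the growth plate, in mm, voxel-center membership:

* diaphyseal cylinder: diameter 2.5 mm × height 5 mm, bottom 1.5 mm above
  the growth plate;
* metaphyseal cylinder: diameter 1.5 mm × height 0.6 mm, bottom at the
  growth plate, wholly inside the cortex (rejected if the endocortical
  radius is ≤ 0.75 mm).

The "2.5 × 2.5 × 5 mm cylinder" notation is read as diameter × diameter ×
height, the convention of small-animal densitometry software.

## Morphometry

**BMD** is the mean calibrated density over *all* ROI voxels — no threshold
enters, which is exactly why BMD is threshold-invariant while the
structural parameters are not.

**Segmentation**: fixed threshold (closed lower bound, ≥), Otsu's automatic
threshold (256-bin ROI histogram, ties to the lowest edge), or a
maximum-gray-scale fraction (t = fraction × ROI maximum).

**Structural parameters**, two estimators:

* *plate* — TbTh = 2·BV/BS by voxel-face counting (exact for ideal plates),
  TbN = (BV/TV)/TbTh, TbSp = 1/TbN − TbTh. Cheap and robust to coarse
  voxels; used by the cohort runner at all voxel sizes.
* *direct* — model-independent: per-voxel structure diameter is the largest
  inscribed sphere containing the voxel, computed from the Euclidean
  distance transform by sweeping distinct radii in descending order (exact
  up to quarter-voxel radius quantization when more than 64 distinct radii
  occur). TbTh (TbSp) is the volume-weighted mean diameter of the bone
  (marrow) phase; TbN = 1/(TbTh + TbSp). A digital sphere at y covers
  voxels within R(y) (distance to the nearest background voxel center) and
  has diameter 2(R − ½); this convention reproduces slabs and balls to
  within a voxel. The sphere sweep is ~100× slower than the surface method,
  which is why cohort sweeps use the plate estimator.

Thickness computations treat everything outside the analyzed phase as
boundary. An optional *context* region (an enlarged cylinder) lets spheres
extend into structure just beyond the sampling ROI so the ROI faces do not
truncate them; the mean is always taken over ROI voxels. Degenerate
empty-bone ROIs return BV/TV = TbN = TbTh = 0 with TbSp equal to the ROI
height and a `degenerate` flag, keeping cohort tables rectangular.

## Reference modalities

**Histomorphometry** — three 1-voxel sagittal sections (at −50%, 0, +50% of
the outer radius from the axis) binarized at half the trabecular tissue
density; a mineral stain is treated as noiseless, befitting the reference
standard. Line-intercept stereology runs along the bone axis on every pixel
column: TbTh is the mean complete bone intercept, TbN the number of complete
bone intercepts per mm of test line, and TbSp the derived 1/TbN − TbTh (the
raw mean marrow intercept is also reported, but inside a 0.6 mm window it
cannot register separations larger than the window, which is precisely the
regime lesioned bone occupies). Runs touching the window edge are
discarded, except a run spanning the whole line, which counts once. The
metaphyseal window is clipped per section level to the endocortical chord so
cortical bone is excluded, mirroring the 3D ROI rule.

**DXA** — a noiseless monoenergetic line-integral projection along the
mediolateral axis; areal BMD (g/cm²) is the mean ray integral over a
2.5 × 5 mm diaphyseal rectangle. Redistributing mineral along a ray cannot
change it — the mechanistic reason projection densitometry does not separate
trabecular from cortical change. In the cohort runner a multiplicative
precision error (cv 5%, a typical ex vivo areal-BMD precision including
repositioning) is applied per femur.

## The study and its statistics

`run_study` simulates n = 11 animals (left = vehicle, right = tumor), with
per-animal anatomy jitter (architecture cv 8%, tissue mineralization cv 3%),
scans each femur at the four classes, measures BMD plus the four structural
parameters over threshold grids (in vivo 200–1000 HU by 100; ex vivo
1000–3500 HU by 500), at each specimen's automatic threshold, and at 22% of
the maximum gray value, then assembles:

1. cross-modality BMD correlations (both femora pooled, n = 22 bones);
2. per-parameter *optimal thresholds* — the grid threshold maximizing the
   Pearson correlation with the histomorphometry reference (ties to the
   lowest threshold), with the correlation at the automatic thresholds and
   an independent-samples Fisher-Z comparison alongside;
3. left/right means with two-sided paired t-tests, at optimal and automatic
   thresholds;
4. cross-modality structural-parameter correlations at optimal thresholds;
   and the mean absolute right−left diaphyseal BMD difference (MAD).

The automatic threshold in the cohort runner is the ROI Otsu value perturbed
by a seeded lognormal factor (cv 0.35/0.36/0.32/0.50 for the four classes):
software automatic thresholds on real scans are far more variable than a
clean Otsu on a synthetic histogram, with relative spreads of roughly a
third, and that variability is a study condition, not a nuisance — it is
what fixed optimal thresholds are being compared against. The `threshold_auto`
operation itself is pure Otsu.

Raw p-values are reported throughout (no multiple-testing correction);
significance is read at p < 0.05. Correlations pool both femora as separate
observations; Fisher's Z uses the independent-samples form (the dependent
form, for correlations sharing specimens, is a possible extension).

Everything derives from one master seed (per-animal seeds via
`numpy.random.SeedSequence` spawning), so a study is bit-reproducible.

## Numerical and testing choices

* Problem sizes: one femur is a 1125×340×340 float32 grid; a full study
  (22 femora × 4 scans + references + sweeps) runs in roughly three minutes
  on one core. Study-level property tests run on a coarse variant of the
  same phantom (30 µm base voxel, 120/660 µm lattice) that preserves every
  code path at ~1% of the cost.
* Tie-breaks: argmax ties in the sweep and in Otsu go to the lowest
  threshold (more inclusive mask, deterministic).
* The sweep reports NaN for thresholds where a correlation is undefined
  (e.g. all measurements zero above the bone range) and fails only if the
  whole grid is uninformative; a degenerate (constant) reference in a null
  cohort downgrades that sweep to an uninformative record instead of
  aborting the study.
* Volume I/O: MetaImage (.mhd/.raw) via SimpleITK and NIfTI-1 via nibabel,
  isotropic spacing only, with a JSON sidecar carrying the intensity-unit
  tag and metadata; round-trips are bit-exact.

## What the synthetic cohort shows — and what it does not

Passing tests establish that the measurement chain is correct (against
brute-force oracles and analytic geometry), that its statistics are
calibrated (permutation and Monte-Carlo checks), and that under the modelled
disease process the pipeline reproduces the qualitative signature of an
osteoblastic intraosseous lesion: diaphyseal BMD up, trabecular BMD and
TbN/BV-TV down, TbSp up, TbTh uninformative at coarse voxels, BMD
threshold-invariant, fixed optimal thresholds more faithful to
histomorphometry than automatic ones, and µCT–µCT agreement exceeding
DXA–µCT agreement.

They do not establish performance on real scans: the phantom has ideal
plate-rod geometry aligned to the grid, a linear noise model without beam
hardening or scatter, noiseless histology, and a disease transform whose
components are independent draws. Real trabecular networks are oblique,
connected and anisotropic; real automatic-threshold behavior depends on
scanner software internals that are modelled here only through their
reported variability.
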