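# Methods

This document describes the models and procedures implemented in
`ciliascreen`, the default parameter values and why they were chosen, and
the known limits of the synthetic data generator. Everything stated here is
either a definition, a design choice, or a quantity the test suite and
`scripts/acceptance.py` actually compute.

## 1. Assay model

The package models a rescue assay for PRPF31 missense variants in a
*PRPF31*-mutant retinal cell line. Constructs (wild-type, validation
controls of known classification, and test variants) are delivered to wells
of a 96-well plate; the phenotypic readout per field of view is the
**percentage of whole cells bearing exactly one cilium**, measured by
two-channel high-content imaging (a nuclear stain and a cilium marker).

Plate geometry (`ciliascreen.plate`):

- 8 x 12 plate; the 36 outer-perimeter wells hold media only (edge-effect
  guard) and are never imaged or scored.
- Each construct occupies 3 inner wells (technical replicates); each well is
  imaged at 6 fields of view. Ten constructs therefore occupy 30 inner
  wells / 180 fields; unassigned inner wells are media-only.
- Every plate carries exactly one mock-transfected construct (the negative
  control the normalization is anchored to).

## 2. Synthetic data generator (`synthgen`)

Each field is drawn by a single seeded `numpy` `Generator`. **All random
draws happen before any pixel is rasterized**, so the truth-only path
(`simulate_plate_truth`) consumes the identical random stream as full
rendering and produces bit-identical ground truth — verified by a unit test.

Per cell:

- Nucleus: an ellipse with major radius ~ Normal(12, 2) px (clipped to
  [0.5, 1.8] x mean), aspect ratio U(0.7, 1.0), random orientation,
  placed by rejection sampling so nuclei never overlap (2 px clearance);
  a field that cannot host the requested count raises `PlacementError`
  rather than silently crowding.
- Cilium count: one with probability `ciliation_prob`, two with probability
  `multi_cilium_prob` (default 0.05), else zero — so the expected
  single-cilium fraction equals `ciliation_prob` exactly.
- Cilium geometry: an anti-aliased rod of length U(5, 15) px anchored just
  outside the nucleus. The default minimum length is 5 px (not smaller)
  so that a rendered rod always survives the detector's own area and
  eccentricity filters; shorter rods would be invisible by construction.
  Two placement constraints keep the ground truth recoverable:
  - the rod midpoint must lie in its own cell's territory (nearest nucleus,
    with a 3 px margin; bounded resampling, 20 attempts), otherwise a rod
    could legitimately be assigned to a neighboring cell;
  - multiple rods on one cell emerge at angular separation > 1 rad so they
    do not merge into a single detected object.
- Micronuclei: Poisson(0.1)/cell small disks just outside the nucleus.
- Border flag: a cell whose nucleus sits within `cell_expansion_px` (25 px)
  of the field edge is marked border-touching in the truth, mirroring the
  analysis-side "whole cell" definition.

Rendering: objects are drawn into float images, modulated by a radial
vignette (10% edge falloff), given additive Gaussian noise (SD 12 on a
background of 180), clipped at zero, and written as 16-bit TIFFs.

Seeding: each field's seed is
`sha256(f"{root_seed}/{plate_id}/{well_id}/{field_index}") mod 2^31`,
so any single well is reproducible in isolation and all derived seeds stay
below 2^31. Per-field cell counts are Poisson(`n_cells_mean`, default 100).

### Generator realism limits

The generator is a test harness, not a microscope. Known simplifications:
nuclei are perfect ellipses with no texture or clustering beyond
non-overlap; cilia are straight rods of uniform intensity; noise is
Gaussian and spatially white; illumination falloff is a fixed radial
vignette; there is no focus drift, debris, staining failure, or
well-to-well biological drift; cells are independent (no colonies or local
density effects). Conclusions about the *analysis code* transfer to real
images only to the extent these effects are secondary.

## 3. Image analysis (`hci`)

Per field, in order:

1. **Nuclei**: Otsu global threshold -> hole filling -> watershed declumping
   seeded from peaks of the smoothed distance transform (smoothing sigma
   2 px; peak separation 10 px, about one nucleus radius) -> area filter
   40–2500 px². A guard rejects the segmentation outright when the Otsu
   foreground mean exceeds the background mean by fewer than
   `min_foreground_snr` = 4 background SDs, because Otsu always splits a
   histogram and would otherwise shatter a stain-free field into noise
   specks.
2. **Micronuclei**: connected components of 3–35 px² within 25 px of a
   nucleus boundary, counted per nearest nucleus.
3. **Cells**: distance-limited nearest-nucleus expansion
   (`expand_labels`, 25 px), a cheap stand-in for a cytoplasmic stain.
   Cells touching the field border are excluded from scoring ("whole
   cells"), because their cilium may lie outside the field.
4. **Cilia**: threshold at background median + 6 x MAD (robust to the
   bright-object tail), area 3–200 px², eccentricity >= 0.80 (rods, not
   blobs).
5. **Assignment**: each cilium goes to the cell containing its centroid,
   with a rescue step assigning orphans to the nearest cell within 10 px.
6. **Field statistic**: `100 * (whole cells with exactly one assigned
   cilium) / (whole cells)`; a field with no whole cells is flagged
   unusable and excluded downstream.

Defaults were set from the generator's geometry (nucleus radius ~12 px,
rod length 5–15 px) before any acceptance-style evaluation was run, and
were not tuned afterward.

## 4. Plate statistics (`platestats`)

- **Robust z**: `z = (x - median(mock)) / MAD(mock)` with the *unscaled*
  MAD (`median(|v - median|)`, no 1.4826 consistency factor). Median/MAD
  rather than mean/SD because a single failed control field should not
  move every score on the plate; a unit test demonstrates the robust z
  moves less than a classical z under a 10x corruption of one mock field.
- **Population**: by default the mock population is all usable mock *field*
  values (18 per plate), maximizing the sample behind the MAD;
  `mock_population="well_medians"` switches to the 3 mock well medians.
- **Construct value** `x`: median over the construct's 3 wells of each
  well's median over its usable fields.
- **Replicates**: biological replicates (plates) aggregate as mean ± SEM
  (SD with `ddof=1` over plate z values, divided by sqrt(n)); SEM is
  reported as undefined (`None`) for a single plate rather than 0.
- A plate whose mock MAD is zero is declared non-scorable (`NonScorableError`)
  instead of dividing by zero.

### Per-well percentage: median vs pooled

Two defensible per-well summaries exist: the **median of the six field
percentages** (robust to one bad field) and the **pooled count ratio**
(sum of single-cilium whole cells over sum of whole cells, the minimum-
variance estimate under the generating binomial model). The scoring path
uses the median, keeping the robustness rationale consistent across
levels. The simulation-recovery checks compare each well against its known
generating probability and use the pooled ratio, because the comparison is
against truth (no outliers to guard against) and the pooled estimator's
sampling SD, `100 * sqrt(p(1-p)/N)` for N pooled whole cells, is what the
±5-point recovery tolerance is budgeted against (≈ 2.4 points at p = 0.5,
N ≈ 430).

## 5. Functional-evidence calls (`rescuecall`)

Cutoffs come from the validation controls scored on the same plates: the
lower cutoff is the mean z of the pathogenic controls, the upper cutoff the
mean z of the benign controls (optionally pooled with the wild-type
control via `pool_wt=True`). Calls are strict: `z < lower` -> PS3,
`z > upper` -> BS3, anything else — including equality with a cutoff — is
indeterminate, so a boundary value never becomes clinical evidence. If the
pathogenic mean is not below the benign mean the assay cannot discriminate
and threshold derivation refuses (`NonDiscriminatingAssayError`).

Evidence strength is capped by the number of validation controls in the
class matching the call direction: 0 -> not applicable, 1–10 ->
supporting, >= 11 -> moderate. This is a deliberately simple, configurable
stand-in for full calibrated odds-of-pathogenicity tables; with the
panel's 3 + 3 controls it yields "supporting".

## 6. ACMG/AMP assembly and combining (`acmg`)

- **Frequency cutoff**: `prevalence x prop_inheritance x gene_fraction /
  allelic_divisor x penetrance_factor`. Defaults encode autosomal dominant
  RP from PRPF31: prevalence 1/3000, a quarter of RP dominant, 5.5% of
  that attributable to the gene, one causal allele (divide by 2), and a
  tenfold allowance for incomplete penetrance — 2.3e-5 at two significant
  figures.
- **Frequency evidence** is exactly one of PM2 (absent or below the
  cutoff), BA1 (>= 5%), or BS1 (in between).
- **Computed criteria**: PP3 when >= 2 of the three protein predictors say
  damaging and no splice change is predicted; BP4 when every available
  predictor says tolerated; PS3/BS3 at the strength delivered by the assay.
  Evidence the package cannot compute (segregation, de novo status, case
  counts) enters as explicit overrides.
- **Combining rules**: criteria are counted at their possibly modified
  strengths (e.g. PS3 at supporting counts as one supporting), then the
  published combination table maps counts to one of five tiers; meeting
  both a pathogenic-side and a benign-side combination is a conflict and
  yields VUS. The implementation is verified exhaustively against a
  literal transcription of the rule table for every criteria set of up to
  four codes at default strengths.

## 7. Clone QC (`editqc`)

- Insertion percentage = `100 * n_ins / (n_ref + n_ins)` over
  junction-spanning reads, rounded **half-up** to one decimal via
  `decimal.Decimal` (binary-float `round()` is banker's rounding and
  half-up is the convention the reported percentages follow).
- Dosage ratio = mutant/wild-type transcript abundance, flagged
  haploinsufficiency-consistent inside [0.35, 0.65] (inclusive), a
  deliberately wide band around the idealized 0.5.
- When the insertion allele is under-represented (< 25%) in both nuclear
  and cytoplasmic RNA, a note records that this pattern fits preferential
  expression from the wild-type allele rather than cytoplasm-restricted
  decay of the mutant transcript.

## 8. Numerical choices

- Unscaled MAD everywhere (no 1.4826 factor); cutoff values quoted in z
  units are on this scale.
- SEM uses `ddof=1`; undefined (not zero) for n = 1.
- Rounding for reporting: significant-figure rounding via
  `round_sig` (MAF cutoff), half-up decimal rounding for read
  percentages; internal computation is never rounded.
- All seeds derived by SHA-256 hashing of structured keys, reduced mod
  2^31; no global RNG state is used anywhere.

## 9. Limitations

- The strength lookup in §5 is a placeholder shape, not a calibrated
  evidence model; real use requires assay calibration against many more
  controls.
- Criteria the package cannot compute must be supplied by the analyst;
  the bundled variant table deliberately marks predictor verdicts as
  unavailable rather than inventing them.
- The segmentation stack is tuned to the generator's geometry; applying it
  to real micrographs would at minimum require revisiting the area,
  eccentricity, and SNR defaults in `HCIConfig`.
- Recovery results quoted in the README come from the synthetic generator
  and certify the pipeline's internal consistency, not clinical
  performance.
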