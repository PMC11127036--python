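# Methods

## Scope and model

`plexiquant` implements two image-based counting assays used to study the
interaction between T lymphocytes and enteric glial cells, the cohort
statistics applied to their outputs, and the single-cell quantities used to
describe ICAM-1 expression in glia. Because the original micrographs and
patient material are not distributable, the package also ships a synthetic
generator that produces micrographs, cohorts and count matrices with known
per-object ground truth, so that every stage of the pipeline is testable
end to end.

### Co-culture adhesion assay

A T cell is a DAPI+CFSE+ object: an 8-connected component of the CFSE
segmentation whose pixels lie at least 50 % inside the DAPI mask, with an
area of at least 50 µm². A T cell is **adherent** when at least 5 % of its
area overlaps the S100β (glial) mask. Both thresholds are inclusive,
matching the "at least" phrasing of the counting rule. The overlap
denominator is the T-cell object's own area: adherence is treated as a
property of the T cell. (Alternative denominators would change calls only
for cells much larger than their glial contact patch.)

Counts are pooled over all fields of a well and expressed as adherent
cells per mm² of S100β surface; per condition, the **median** of the well
densities is reported as a percentage of the control condition's median.
The acquisition design this mirrors images 81 fields (36 mm²) per well and
uses 3 wells per condition; any field/well count is accepted and recorded.

### Plexitis assay (sections and whole-mounts)

**Apposition** is overlap or strict contact between T-cell and neural
staining: no background pixel between the two, i.e. a minimum Chebyshev
pixel distance of at most 1 (8-adjacency). Ganglia are S100β+ components
above a minimum area (default 200 µm², a de-speckling choice — the assay
definition does not specify a ganglion detector). A T cell is counted for
a ganglion when its centroid lies inside the ganglion dilated by 1 px
("inside or at the border", the smallest extension consistent with the
apposition gap rule) *and* it is apposed to that ganglion's mask. A cell
straddling two candidate ganglia goes to the one with the larger pixel
overlap, ties to the lower ganglion id — a deterministic rule, exercised
by a constructed test case.

Per patient the summary is the mean apposed count per ganglion, the
percentage of ganglia with at least one apposed T cell, and — when a Hu
channel is present — apposed T cells per Hu+ neuron. Whole-mount analyses
sample 12 ganglia per animal uniformly without replacement (seeded); when
fewer are available all are used and a warning is emitted.

Marker intensities (GFAP, S100β) are reported as background-subtracted
ganglion means, with background estimated as the median intensity outside
all ganglia; background handling is not specified by the assay and this
choice is the simplest robust one.

## Synthetic data generator

The generator is deliberately the simplest model that exercises
threshold-based segmentation: hard-disk cells and elliptical ganglia of
unit amplitude on a constant background, convolved with a Gaussian PSF
(default σ = 0.5 µm) and corrupted by additive Gaussian read noise,
clipped at zero. Pixel size defaults to 0.413 µm. Ground truth (adherence
and apposition flags, ganglion membership) lives in separate noiseless
label images, so detector validation never depends on renderer internals.

Key parameter choices:

- **T-cell radius**: 5 µm (≈79 µm², above the 50 µm² filter) in
  co-cultures, where the cells are activated and spread; 3.5 µm in tissue
  sections, the size of a resting lymphocyte. Nuclei are rendered at 0.8 ×
  the cell radius so the 50 % DAPI co-positivity rule holds for every
  rendered cell.
- **Placement margins**: non-adherent cells keep ≥3 px clearance from the
  glial sheet (truth overlap exactly 0); truth-adherent cells overlap the
  sheet by ≥20 % (well above the 5 % rule); non-apposed cells keep a
  Chebyshev gap ≥4 px from neural labels (the rule needs 2). The extra
  slack guarantees that segmentation-mask growth under the PSF cannot flip
  a truth label, which is what makes exact noiseless recovery a meaningful
  requirement rather than a fragile coincidence. Any two cells keep a
  ≥4 px background gap so components never merge.
- **Counts per ganglion**: negative binomial. The reference cohort means
  are 0.36 (controls and non-recurrent) and 2.42 (recurrent) apposed
  T cells per ganglion. The within-patient dispersion is not reported
  anywhere, only patient-level means ± SEM; the cohort generator defaults
  to size θ = 1 (strong overdispersion typical of infiltrate counts) and
  exposes the Poisson limit (θ → ∞). The image renderer uses θ = 3 so
  that the per-ganglion tail stays within the geometric packing capacity
  of a rendered ganglion.
- **Glial sheet**: a Gaussian-smoothed random field thresholded at the
  coverage quantile — coverage is exact by construction.
- **Imaging noise**: the reference imaging setup's noise and exposure are
  unreported; `noise_sd` is a free knob. The noisy-recovery tests use
  `noise_sd = 0.2` against unit-amplitude objects, i.e. SNR ≈ 5.

The single-cell generator produces a sparse genes × cells matrix with
Poisson background counts (lognormal gene rates) and one designated gene
whose per-stratum expressing fraction is controlled: Bernoulli per cell by
default, or exactly `round(fraction × n)` cells when `exact_fractions` is
set (used to pin realized fractions in validation). The truth table
records the realized fraction as an exact nonzero count over cells.

What the generator does **not** emulate: tissue autofluorescence and
texture, uneven illumination, 3D structure and optical sectioning,
photobleaching, cell-shape variability, segmentation ambiguity from
touching cells. Passing the recovery tests therefore shows that the
counting rules and their implementation are correct and noise-tolerant
under the stated imaging model — not that segmentation would be equally
accurate on real tissue.

## Cohort statistics

The unit of analysis is the patient (or animal): group tests take
patient-level means, matching the one-dot-per-patient convention and
avoiding pseudo-replication of ganglia. All tests are two-sided, α = 0.05.

- **Mann-Whitney U** from midranks; for pooled n ≤ 12 the two-sided p is
  exact by enumeration of all group assignments (ties handled via
  midranks, so identical samples give p = 1); larger samples use the
  tie-corrected normal approximation with continuity correction.
- **Kruskal-Wallis** (tie-corrected, χ² reference) with **Dunn** post hoc
  z statistics on pooled midranks. The multiplicity correction used by the
  original analyses is unreported; the default here is Bonferroni over all
  pairs, with Holm and no-adjustment available.
- **Spearman** rho as Pearson correlation of midranks; exact permutation
  p for n ≤ 8, t-approximation otherwise.
- **ANOVA**: one-way with Tukey HSD pairwise comparisons; two-way
  factorial (condition × size-bin) via OLS with type-II sums of squares.

Inclusion and recurrence rules: subjects with fewer than 10 ganglia are
excluded; a Crohn subject is recurrent iff the Rutgeerts score is ≥ i1
**or** clinical recurrence at 18 months is recorded; subjects with neither
assessment are labeled lost-to-follow-up and excluded from recurrence
splits.

Calibration and power are checked by simulation: under a shared NB null
(mean 2, θ = 1, the paper-sized groups) the empirical type-I error of both
rank tests is ≈0.046 over 2000 replicates; on cohorts generated at the
reference means (0.36/0.36/2.42, n = 9/6/11, 20 ganglia per patient), the
control-vs-recurrent Dunn comparison rejects in ≈100 % of 500 simulated
cohorts and the equal-means control-vs-non-recurrent comparison in ≈0 %.

## Single-cell quantities

"Expressing" means raw count > 0 (configurable minimum count); the
expressing fraction is the percentage of cells of a metadata-defined
subset with a nonzero count for the gene. Pseudo-bulk aggregation sums raw
counts over (sample × cell type) strata and conserves the total count by
construction (validated per gene and globally). Differential testing on
the pseudo-bulk table is deliberately delegated to standard DE tooling;
the package only produces the table such tooling consumes.

The accession export this ingests (MTX triplet plus a cell-metadata table)
is not shipped; validation runs the identical load → subset → fraction →
aggregate path on synthetic accession-shaped datasets, including one
constructed at the published per-stratum glia counts and ICAM-1
percentages (colon 1211/934/72 cells at 2.8/2.9/13.9 %; terminal ileum
502/1636/479 cells at 1.2/4.0/5.6 %).

## Numerical choices and degenerate inputs

- Otsu thresholding on a 256-bin histogram after 1-px Gaussian smoothing;
  masks are true at intensity ≥ threshold; a constant channel raises an
  explicit "no threshold" error (pipelines treat an empty stained channel
  as an empty mask; a fully empty S100β surface is an error for density).
- 8-connectivity everywhere; object ids in raster order of first pixel;
  0-based (row, col) coordinates; pixel area = pixel size squared.
- All-identical Kruskal-Wallis input returns H = 0, p = 1 rather than
  erroring; an empty group is an error.
- Zero Hu+ cells leaves the per-neuron metric undefined (omitted), not 0.
- Every stochastic routine takes an explicit integer seed; one
  `numpy.random.Generator` per call; identical parameters and seed give
  bit-identical outputs, including the OME-TIFF bytes on disk.

## Problem sizes used in validation

Recovery tests use 20 co-culture fields (384², 20 cells each) and 20
sections (512², 4 ganglia each) per noise regime; rate calibration uses
500 ganglia (25 sections of 20); statistical calibration uses 2000
replicates and pattern recovery 500 simulated cohorts. These sizes put the
binomial/NB sampling error well below the tested tolerances while keeping
the full suite fast.

## Known limitations

- The renderer's simplicity means detector performance on real tissue is
  not established here; the pipeline's configuration surface (thresholds,
  channel maps, minimum areas) exists precisely so it can be recalibrated
  on real data.
- `is_apposed` ignores the physical pixel size: the 1-px contact rule is
  resolution-dependent by definition (it was stated at 0.413 µm/px).
  Images at other resolutions should be resampled before counting.
- The exact Mann-Whitney enumeration is O(C(n, n_A)) and intentionally
  capped at pooled n = 12.
- Two-way ANOVA requires a complete factorial (no empty cells) and does
  not implement repeated-measures structure.
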