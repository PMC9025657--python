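# Methods

## Problem and model

In drug-resistant focal epilepsy, single-photon emission computed tomography
(SPECT) of cerebral blood flow is acquired in two states per subject: ictal
(tracer injected at electrographic seizure onset) and interictal (seizure-free
baseline). The analysis implemented here quantifies each acquisition as a set
of **perfusion indexes** (PI), one per atlas region:

    PI_r = mean activity of region r / mean activity of the remaining gray matter

The reference is leave-one-out and voxel-weighted: the denominator for region
r is the total gray-matter activity minus r's own contribution, divided by the
corresponding voxel count. PI = 1 means parity with the rest of gray matter.
The voxel-weighted reading of "mean activity of the remaining gray matter" is
a design choice (the alternative, an unweighted mean of region means, is not
used); it makes the bookkeeping identity
`sum_r w_r * mean_r = global GM mean` hold exactly, which the tests check.

A per-subject PI cut-off then discriminates the two states, and the
"epileptogenic network" of a subject is the set of structures with PI at or
**below** the cut-off interictally (hypoperfusion) and at or **above** it
ictally (hyperperfusion); both comparisons are inclusive. Group-level networks
are consensus sets: structures flagged in at least `min_subjects` subjects of
a group (default `ceil(n_group / 2)` — the aggregation rule is an explicit
parameter because only a qualitative description of it exists).

## Partial-volume correction

The scanner's point-spread function (PSF) mixes signal between adjacent
regions. The multi-region correction is realized as the regional geometric
transfer matrix (GTM) formulation: with a shift-invariant symmetric PSF and
region-homogeneous activity, observed regional means obey `m = omega @ t`,
where `omega[i, j]` is the mean over region i's voxels of the PSF-blurred
indicator of region j. Unlabeled voxels form one extra background compartment
solved jointly and then discarded, so spill-in from non-gray tissue is not
attributed to gray regions. The correction is a dense linear solve with
explicit condition-number reporting (matrices are at most ~80 x 80; an
iterative solver would add nothing). Negative corrected means are flagged in
diagnostics but never clipped — clipping would bias the ratio indexes.
Whether the correction applies to one or both states is configurable; the
default applies it to both, for a consistent compartment model.

Numerical conventions: the PSF is a separable sampled Gaussian, truncated at
`ceil(4 sigma)` voxels per axis and renormalized, convolved with reflective
boundaries (avoids background bleed-in at grid edges). `fwhm = 0` is the
exact identity. The solve refuses matrices with condition number above 1e6
(configurable).

## Threshold discrimination

Two per-subject discrimination methods are provided:

* **tree** — the single split of a depth-one classification tree (CART):
  the cut-off minimizing total Gini impurity of the two children over all
  midpoints between adjacent distinct pooled ictal+interictal values. Ties
  are broken toward the midpoint closest to the pooled median, then toward
  the smaller value; both conventions are fixed for determinism. The split
  needs both states, and both states of a subject share it.
* **traditional** — `mean - k*sd` of the state's own PI distribution for the
  interictal gate and `mean + k*sd` for the ictal gate (k default 1). The
  method this name refers to in the source clinical workflow is not defined
  anywhere we could verify, so this implementation is an explicit,
  documented convention.

The first-level ictal-vs-interictal comparison is a two-sample pooled-variance
Student t (positive t = ictal mean higher); two zero-variance identical
samples return t = 0, p = 1 rather than NaN.

Second-level summaries use the sample standard deviation with the n-1
denominator throughout — this choice reproduces five independently printed
dispersion values from the packaged tables (7.07 with n=2, 3.19 with n=5,
2.12 with n=2, 6.71 and 0.111 with n=15) — and percentiles by linear
interpolation between order statistics, with "max quartile" = 75th
percentile. When outputs are compared against printed values, rounding is
half-away-from-zero to the printed number of decimals.

## Packaged tables

The per-patient clinical tables (15 subjects: 4 temporal-lobe, 8 frontal-lobe,
3 posterior-quadrant epilepsy) are shipped as TSV fixtures: demographics and
seizure counts, interictal and ictal PI tables listing only the structures
that passed each subject's published threshold, the per-subject thresholds
themselves (15 interictal; 7 ictal — two frontal-lobe subjects with post-ictal
tracer uptake and six subjects without usable ictal acquisitions are excluded
from ictal analyses), and the semiology glossary. Missing table cells are
absent rows, never zeros: the tables list only threshold-passing structures,
so absence carries no perfusion value. Accented region codes are normalized
to ASCII. Brainstem structures (midbrain, pons, medulla oblongata) are
represented as lateralized halves because the tables print them with
ipsilateral/contralateral suffixes.

Because the PI tables are truncated at the threshold, per-subject *maxima*
statistics of the full PI distribution are not recomputable from them; only
the interictal minima summary is reproduced. The ictal extremes suffer the
same truncation (and one ictal-valid subject has an empty column), so they
are reported by the pipeline but not used for verification.

## Synthetic data

Two generators, both driven by explicit integer seeds with no global state:

* **Voxel phantoms** place each atlas name code as a disjoint axis-aligned
  box in one hemisphere, mirrored about the x midplane (hemisphere = sign of
  the x offset from the grid midplane; default grid 48^3 voxels at 3 mm
  isotropic). Activity is piecewise constant at the specified regional means,
  with designated epileptogenic-zone (EZ) regions multiplied by `ez_effect`.
  Degradation applies the Gaussian PSF (default FWHM 9 mm — a stated
  implementer convention, since no scanner PSF is available to us) and then
  per-voxel Poisson noise at `count_scale` expected counts per voxel
  (default 100); noise after blur is the standard emission-imaging forward
  model. The phantoms are geometrically unrealistic on purpose: PVC and PI
  depend only on geometry/PSF overlap.

* **Cohort tables** skip the image level and draw PI values directly:
  non-EZ regions from a positive-truncated Normal(1.0, sigma = 0.07), the
  group's ipsilateral EZ regions shifted by -0.15 interictally and +0.25
  ictally (defaults). These effect sizes place the simulated per-subject
  interictal cut-offs in the ~0.85-0.99 band and PI values essentially
  within the observed 0.28-1.85 envelope of the clinical tables. EZ region
  sets per group are fixed: mesial/lateral temporal codes for TLE, frontal
  codes for FLE, occipital codes for PQE.

What the cohort generator does **not** emulate: spatial correlation between
neighboring regions, subject-level global perfusion offsets, asymmetric
left/right baselines, and heavy-tailed outliers (e.g. the 0.287 printed
minimum). Passing recovery tests therefore show that the thresholding and
consensus machinery recovers a known signal under idealized independence —
not that it would perform identically on real scans.

## Recovery protocol

Network-recovery checks run the package end to end on simulated cohorts
(n = 5 per group, 20 seeds): per-subject per-state thresholds, inclusive
network extraction, per-group consensus at `min_subjects = ceil(n/2)`, then
sensitivity/specificity of consensus membership against the known EZ sets.
Recovery uses the **traditional** per-state thresholds: the tree method
yields a single boundary between the two pooled state distributions, which
is the right object for state discrimination but gates both states with one
number, flooding the ictal network when used as that state's cut-off in a
mostly-at-parity cohort. Under the default effects, sensitivity and
specificity both exceed 0.9; with the effect removed, the flag rate on
designated regions is statistically indistinguishable from the rate on the
rest (paired per-seed comparison — decisions within a seed are correlated
through the shared thresholds, so naive binomial tests overstate
significance).

## Degenerate inputs and tie-breaks

* All pooled values identical → the tree split is a degenerate error.
* Single threshold value → sd reported as 0 with an explicit degenerate flag.
* Subjects with no rows in a state are excluded from extremes with a warning
  rather than erroring the batch.
* Consensus with `min_subjects = 1` is the union; above the number of
  networks, empty.
* Semiology consensus orders codes by median of per-subject first onsets;
  median ties break lexicographically by code so rendered flowcharts are
  deterministic.

## Problem sizes

Default test and verification sizes: 48^3 voxel phantoms (74 regions plus
background), cohorts of 15 simulated subjects (5 per group) with 74 regions
x 2 states, 20 simulation seeds per recovery condition, and 50 random sample
pairs for the split-threshold oracle comparison. These sizes were chosen so
the full verification cycle stays lightweight while keeping Monte-Carlo
error well below the decision margins involved.

## Known limitations

* The atlas is exactly the vocabulary of the packaged tables (37 bilateral
  name codes); no claim is made about the original anatomical atlas' full
  region count.
* MRI segmentation, atlas co-registration, and scanner calibration are out
  of scope; phantom-native labels stand in for the registration chain.
* Tissue-probability maps are binary in the phantoms (gm = 1 on gray
  labels), so tissue-fraction-weighted PVC variants are not exercised.
* The semiology sequence fixture is synthetic: per-patient event times are
  only available as narrative onset windows, and the fixture encodes those
  windows, not measurements.
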