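# Methods

This note documents the models, conventions and design choices behind
`periprog`, and what the synthetic-data generator does and does not emulate.

## The 24-2 grid

`periprog.grid` builds the standard 24-2 lattice: rows at y ∈ {±3, ±9, ±15,
±21}°, 6° spacing, a nasal extension to 27°, 54 points in total, with the
blind-spot pair at (15°, ±3°) in right-eye format. All analysis runs in
right-eye format (temporal field positive x); left-eye fields are mirrored
on input, which makes hemifield, sector and cluster logic laterality-free.
The two blind-spot points carry data but never enter any analysis, leaving
52 analyzed locations.

**Adjacency** is the 8-neighborhood on the 6° lattice (|Δx| ≤ 6 and
|Δy| ≤ 6), the weakest common reading of "adjacent" in the pointwise-
regression cluster literature. Blind-spot points are adjacent to nothing.
When a cluster criterion demands one hemifield, the adjacency relation is
restricted to same-hemifield pairs before connected components are taken;
since no 24-2 point lies on y = 0, this also confines every component to one
hemifield.

**Edge locations.** There is no universal definition of the 24-2 "edge";
we use: a non-blind-spot point is edge iff at least one of its four axial
neighbors (N/S/E/W at 6°) is missing from the grid, with blind-spot points
counting as present. This yields the 20-point outer rim. Because published
analyses differ here, the edge set is overridable by explicit index list in
`build_grid`, and results that depend on it (the ±10 %/yr cut-off) should be
read with that sensitivity in mind.

**ST/IT sectors.** The supero-temporal and infero-temporal sectors are
hard-coded 15-point arcuate regions sweeping from the paracentral field into
the temporal field, mirror images of each other about the horizontal
midline, in the spirit of structure–function maps that tie these field
regions to the optic-disc sectors most vulnerable in glaucoma. They are
explicit index lists and overridable; no result in this package depends on
their exact membership beyond the sectoral summaries.

## Scales and percent of mean normal

Perimetric decibels are attenuation units: `dB = k · log10(CS)` with k = 10
for the Humphrey SAP/SWAP Weber scale and k = 20 for the Matrix FDT
Michelson contrast-amplitude scale. Percent of mean normal is
`100 · CS(observed) / CS(age-matched normal)` = `100 · 10^((dB − dB_normal)/k)`,
which depends only on the dB *difference* — the device luminance constants
cancel exactly, so omitting them is not an approximation. Values below the
0 dB device floor are clamped to the floor before conversion (negative dB
would explode the linear scale asymmetrically); percent of normal is not
capped at 100, since supernormal values carry the information used by
improvement flags.

One consequence worth keeping in mind: equal dB losses are not equal
percent losses across modalities (−10 dB is 10% of normal on SAP/SWAP but
31.6% on FDT), which is the entire motivation for the common scale.

## Normative aging model

For each location and modality, normal sensitivity is modeled as a linear
function of age, fitted by OLS on a cross-sectional healthy cohort (one eye
per subject). Prediction uses the subject's age at each visit, so the
normal reference declines over follow-up and ordinary aging is not counted
as progression. Extrapolation beyond the cohort's age range is allowed with
a logged warning.

Deviation machinery (device-style, reconstructed because devices do not
publish theirs):

* total deviation TD = observed − predicted normal (dB);
* general height GH = 85th percentile of TD over the 52 analyzed locations
  (≈ the 7th-best point), the standard proxy for diffuse shifts;
* pattern deviation PD = TD − GH, invariant to uniform dB shifts;
* PSD = RMS of TD about GH over the 52 analyzed locations (unweighted; the
  per-location variance weights of commercial indices are proprietary).

Abnormality probability limits are *empirical* percentiles (5th/1st of PD
and TD per location, 95th of PSD) taken from the normative cohort itself
rather than parametric limits, because deviation distributions are skewed.
A field is abnormal if PSD exceeds its 95th normative percentile, or an
externally supplied Glaucoma Hemifield Test result is "outside" (the GHT is
proprietary and is accepted as input, never computed), or a cluster of ≥ 3
nonedge points sits below the 5% PD limit with ≥ 1 below the 1% limit.

## Visit pairing

Tests are usable when fixation losses, false negatives and false positives
are all ≤ 33% (inclusive). SAP is the anchor modality: for each reliable
SAP test in date order, the nearest-in-time reliable SWAP and FDT within
±30 days are attached, each test used at most once — a deterministic,
order-independent rule. Visits closer than 3 months to the previously
accepted visit are dropped, and eyes with fewer than 5 complete visits are
excluded; every exclusion is logged. Each modality keeps its own test dates,
and regression time for a modality is measured from that modality's own
baseline (paired tests can differ by up to 30 days).

## Pointwise linear regression and eye criteria

Per location, percent of mean normal is regressed on time (years) by OLS;
two-sided p-values come from the exact t distribution on n − 2 df, because
series have only 5–7 points and the normal approximation is too liberal
there. A perfect fit (zero residual variance) is assigned p = 0 for a
nonzero slope and p = 1 for a zero slope so that noise-free data behave
sensibly; these degenerate fits are logged.

Flags: progression iff slope ≤ −5 %/yr (nonedge) or ≤ −10 %/yr (edge) with
p < 0.05; improvement mirror-image. Slope thresholds are inclusive as
printed; the significance gate is strict. The ±5/±10 figures approximate
the classical 1 dB/yr (nonedge) and 2 dB/yr (edge) SAP criteria after
conversion: a 29 dB location at 48.2% of normal declining 1 dB/yr has an
OLS percent slope of ≈ 5.9–7.2 %/yr depending on whether 5, 6 or 7 annual
visits are sampled (the trajectory is exponential in linear units, so the
OLS slope is schedule-dependent); the edge example (27 dB, 55.0%, 2 dB/yr)
gives ≈ 8.1–11.3 %/yr. The acceptance script reports the 5-visit values.

Eye criteria per direction: conservative — some same-hemifield adjacent
cluster of ≥ 3 flagged locations containing ≥ 1 nonedge location (the
nonedge requirement is evaluated per qualifying cluster, not per eye);
moderate — any 3 flagged with ≥ 1 nonedge; liberal — any 2 flagged with
≥ 1 nonedge. Conservative ⇒ moderate ⇒ liberal by construction. An eye
meeting both directions at a level is *indeterminate* at that level.
Improvement is interpreted as a specificity proxy: under the null,
progression and improvement calls are exchangeable.

A floor effect of the percent scale is worth noting: at a location already
deep in a defect (say 10% of normal), a fixed dB/yr decline corresponds to
an arbitrarily small percent-of-normal slope, so trend criteria on this
scale are insensitive to further deepening of severe loss.

## Mean sensitivity and the mixed model

Mean sensitivity is averaged strictly in linear contrast-sensitivity units
(converting first, averaging after — the dB mean understates damaged
locations) over the 52 analyzed locations (global) or a sector, and divided
by the same-aged normal mean computed identically over the same locations.

The longitudinal model is `MS ~ time × modality` with SAP as reference,
a random intercept and slope at the subject level, a random intercept per
eye nested within subject (bilateral subjects contribute both eyes through
this nesting), REML estimation, and Wald standard errors / 95% confidence
limits / p-values for fixed effects (normal-approximation df, as is
standard for mixed models of this size). With single-eye subjects the eye
variance component is dropped and the model collapses gracefully to
subject-level effects. Non-convergence is recorded on the returned fit and
logged, never silent. Note that with few bilateral subjects the subject and
eye intercept variances are only weakly separated; fixed effects — the
quantities of interest — are unaffected, which is what the parameter-
recovery check in the acceptance suite verifies.

## Agreement battery

The three modalities are treated as three raters of a binary eye label per
criterion and direction (indeterminate eyes are excluded from the tested
direction, with a log entry; counting them as stable is available
downstream). Cochran Q is the omnibus proportion test; pairwise McNemar
follow-ups run only when the omnibus is significant (uncorrected, the
stepwise convention; a multiplicity flag can be added downstream). McNemar
is exact-binomial by default because discordant counts are small at cohort
sizes of ~100 eyes; the chi-square variant is available via flag. Fleiss κ
gets a Monte-Carlo p-value: each rater's labels are permuted independently
across eyes (marginals preserved), with add-one smoothing,
`p = (1 + #{κ* ≥ κ}) / (1 + B)`, B = 10,000 by default, seeded. κ and
ICC(2,1) are reported with their *pairwise* ranges (the range across the
three modality pairs), and the output metadata says so, since "estimate
(range)" reporting is ambiguous between pairwise ranges and CIs. Friedman
(with average-rank ties) compares the 52-location flag-count maps across
modalities, with pairwise Wilcoxon signed-rank follow-ups (exact null when
≤ 25 untied nonzero differences, tie-corrected normal approximation
otherwise).

## Synthetic cohorts

The generator emulates the study conditions the pipeline targets, not any
particular patient data:

* **Normative cohort** (default 207 subjects, one eye each, three
  modalities within 30 days): per-location true sensitivity =
  eccentricity-dependent intercept + negative aging slope × age + subject
  effect (SD 0.5 dB) + test-retest noise (SD 1.0 dB). Default aging slopes:
  SAP −0.07, SWAP −0.09, FDT −0.045 dB/yr — negative everywhere, with SWAP
  aging fastest, as perimetric normative studies report. Intercepts put a
  50-year-old's central SAP normal near 32 dB, consistent with the percent
  conversions above.
* **Patient cohort** (default 113 eyes of 84 patients, so 29 bilateral
  subjects exercising the nesting; ages N(60.2, 9.1); 5–7 visits at
  intervals N(12, 3.3) months, ≥ 3 months apart; SWAP/FDT dates jittered
  ≤ 20 days from the SAP anchor). Every eye receives a baseline arcuate
  defect (connected cluster of 4–8 locations, 5–15 dB deep in SAP terms,
  plus up to 1.5 dB diffuse loss), deep enough to satisfy the baseline
  abnormality gate. Defect depths and progression rates are specified in
  SAP dB and converted to equal *fractional* loss for the other modalities
  (FDT gets twice the dB, being on a 20·log10 scale).
* **Modality noise**: SAP/SWAP test-retest SD = 1.5 + 0.15 × defect depth
  (variability grows with damage); FDT SD constant 2.5 dB (its variability
  does not grow with damage — the property that motivates comparing it).
  SAP/SWAP thresholds step in 1 dB; FDT snaps to 15 evenly spaced levels
  over 0–38 dB (the true Matrix level grid is non-uniform and unpublished;
  the grid is overridable). SWAP's true per-location variability is not
  well characterized publicly; its defaults mirror SAP's and are labeled
  assumptions in the config.
* **Progression**: a configurable fraction of eyes (default 20%) receives a
  linear decline (default 1.5 SAP-dB/yr) at a 3-location adjacent
  same-hemifield cluster grown *outside* the baseline defect — injected
  inside a deep defect the change would be unmeasurable on the percent
  scale by the floor effect above, i.e. absent by construction rather than
  missed by noise. Ground-truth labels are returned for power/specificity
  scoring.
* A separate generator (`simulate_ms_records`) draws mean-sensitivity
  records directly from the mixed model's own structure (defaults: SAP
  baseline 71.10% of normal, −1.69 %/yr; SWAP offset −21.59; FDT × time
  +2.00; subject intercept/slope SD 12/1.2, eye SD 6, residual SD 5) for
  parameter-recovery checks of the LMM fit.

What the generator does **not** emulate: SITA/ZEST staircase dynamics,
fatigue and learning effects, lens/cataract spectral artifacts (a real
concern for SWAP baselines), floor-censoring response errors, or spatially
correlated noise. Passing tests therefore demonstrate the *pipeline's*
correctness and calibration under the stated statistical structure, not
clinical performance on real fields.

## Numerical choices and reproducibility

Cluster output is sorted (size descending, then smallest member) so runs
are deterministic; all simulation flows from one seeded `numpy` Generator,
and identical config + seed gives byte-identical CSV output. FDT
quantization ties round toward the lower level. Degenerate inputs are
defined explicitly: empty flag set → no clusters; Cochran Q on constant
rows → Q = 0, p = 1; κ and ICC undefined (NaN, with a log entry) when there
is no variance to apportion; Bland–Altman requires ≥ 3 pairs.

Problem sizes in the test and acceptance suites — 10,000 null series for
PLR calibration, 1,000 random flag sets for the criterion oracle, 100
replicates of 113 eyes for LMM coverage, a 120-eye power cohort (60
progressing) and a 113-eye null cohort — were chosen to give stable Monte-Carlo estimates (binomial SE
under ~2% on the reported rates) while keeping a full run in the minutes
range on one CPU.
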