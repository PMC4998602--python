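# periprog

Cross-modality visual-field progression analysis for glaucoma follow-up.

Glaucoma care hinges on detecting *progression* — continuing loss of visual
function — from serial perimetric tests. Three test types are in wide use:
standard automated perimetry (SAP, white-on-white), short-wavelength
automated perimetry (SWAP, blue-on-yellow) and frequency-doubling technology
perimetry (FDT Matrix). All three report per-location sensitivities in
decibels, but the decibel means something different on each device (SAP and
SWAP use a Weber-contrast scale with 10 dB per log10 unit; FDT uses a
Michelson contrast-amplitude scale with 20 dB per log10 unit), so raw dB
slopes are not comparable across tests. `periprog` implements the analysis
chain that makes them comparable, for researchers comparing perimetric
modalities on longitudinal cohorts:

1. **Common scale.** Sensitivities are converted from dB to linear contrast
   sensitivity, `CS = 10^(dB/k)` with `k ∈ {10, 20}`, and expressed in
   *percent of mean normal*: `100 · CS(observed) / CS(normal for that age and
   location)`. The age-specific normal comes from a per-location,
   per-modality ordinary-least-squares regression of sensitivity on age in a
   healthy cross-sectional cohort, so normal aging decline is not mistaken
   for progression.
2. **Pointwise linear regression (PLR).** At each of the 52 analyzed 24-2
   locations (the two blind-spot points are excluded), percent-of-normal is
   regressed on follow-up time. A location is flagged as progressing when the
   slope is ≤ −5 %/yr (≤ −10 %/yr at high-variability edge locations) with
   p < 0.05; improvement uses the mirror-image cut-offs and acts as a
   specificity proxy.
3. **Eye-level criteria.** An eye is *progressing* under the conservative
   criterion (≥ 3 adjacent flagged locations in one hemifield, ≥ 1 nonedge),
   the moderate criterion (any 3 flagged, ≥ 1 nonedge) or the liberal
   criterion (any 2 flagged, ≥ 1 nonedge); meeting both directions makes the
   eye *indeterminate*.
4. **Trend and agreement statistics.** Global and sectoral mean sensitivity
   (averaged in linear units) is modeled as `MS ~ time × modality` with a
   random intercept and slope per subject and a random intercept per eye
   nested in subject (REML). Cross-modality agreement of eye classifications
   is quantified with Cochran Q + McNemar, Fleiss κ (Monte-Carlo p),
   ICC(2,1), Friedman + Wilcoxon on per-location flag counts, Bland–Altman
   limits of agreement, and Venn intersection summaries.
5. **Synthetic cohorts.** Because clinical datasets of this kind are not
   public, `periprog.synthetic_data` generates normative and longitudinal
   patient cohorts with the relevant statistical structure (modality-specific
   noise, the 15-level FDT quantization, bilateral subjects, injected
   progression with ground-truth labels), so the whole pipeline is testable
   end to end.

## Worked example

```sh
# simulate a cohort (113 eyes of 84 patients, 5-7 visits) plus a
# 207-subject normative cohort, then run the full analysis
periprog simulate --seed 1 --out patients.csv --normative-out normative.csv --truth truth.csv
periprog run --config run.yaml     # or use the library directly:
```

```python
import periprog as pp
from periprog.synthetic_data import SimulationConfig, \
    simulate_normative_cohort, simulate_patient_cohort

config = SimulationConfig(seed=1)
model = pp.fit_normative(simulate_normative_cohort(config))
series, truth = simulate_patient_cohort(config)
table, counts = pp.cohort_plr(series, model.grid, model)
for criterion in ("conservative", "moderate", "liberal"):
    sap = table[table.modality == "SAP"]
    print(criterion, int((sap[criterion] == "progressing").sum()),
          "of", len(sap), "eyes progressing on SAP")
```

prints

```
conservative 4 of 113 eyes progressing on SAP
moderate 13 of 113 eyes progressing on SAP
liberal 22 of 113 eyes progressing on SAP
```

— the number of eyes called progressing on SAP rises as the criterion is
relaxed, at the cost of specificity (the improvement counts rise in
parallel). `truth` holds the injected ground-truth labels for scoring. The
`periprog run` bundle adds the mean-sensitivity table, mixed-model fits
(`lmm.json`), the agreement battery (`agreement.json`) and per-location flag
maps, all reproducible from the config and seed echoed into `report.json`.

## Data format

Long-format CSV, one row per test location per test:
`subject_id, eye, modality, test_date (ISO-8601), age, loc_index (0-53),
sens_db, fl, fn, fp [, md, psd, ght]`. `loc_index` is row-major in the
eye's native orientation; left-eye fields are mirrored to right-eye format
on read. Reliability fractions `fl`/`fn`/`fp` must be ≤ 0.33 for a test to
be used. See `docs/methods.md` for the model details and design choices.
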