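# nucmorph

Nuclear morphometry for digital pathology: per-nucleus geometric
features from binary segmentation masks, patient-level aggregation, and
survival validation with Cox proportional hazards and the
optimism-corrected concordance index.

## The problem

In diffuse large B-cell lymphoma (DLBCL), whether tumor-nucleus
morphology carries prognostic information has been debated for decades.
Modern segmentation networks make the question quantitative: given one
binary mask per segmented tumor nucleus, compute reproducible geometric
descriptors, summarize them per patient, and test whether they predict
overall survival better than chance — with honest correction for the
optimism of evaluating a model on its own training data.

`nucmorph` implements that pipeline end to end, plus a synthetic-data
generator that emulates every input (masks with known analytic
geometry, ROI annotation tables, clinical tables with Cox-generated
survival, annotated slide rasters), so the whole chain is testable
without any external download.

## The measurements

For each nucleus mask the pipeline traces the outer contour through
foreground pixel centers, then computes the convex hull (area
`hull_area`), the minimum-area enclosing rotated rectangle (rotating
calipers; angle in [−90°, 0), −90° = axis-aligned), a least-squares
fitted ellipse (center, full axis lengths `shortAxis` ≤ `longAxis`,
area πab, Ramanujan-II perimeter), and the maximum and minimum Feret
diameters (distance between parallel supporting tangents) with their
angles. Six dimensionless shape factors follow:

    esf        = shortAxis / longAxis
    csf        = 4π · ellip_area / ellip_perimt²
    sf1        = shortAxis / maxDiameter
    sf2        = minDiameter / maxDiameter
    elongation = maxDiameter / minDiameter
    convexity  = sqrt(ellip_area / hull_area)

For a perfect circle esf = csf = sf1 = sf2 = elongation = 1; csf falls
toward 0 as the nucleus becomes more elliptical.

Per patient, the mean and sample standard deviation of each feature
across all nuclei form the geometric feature vector. Cox proportional
hazards models (hazard = baseline × exp(xᵀβ), Efron tie handling) are
fit on three feature sets — clinical, geometric, both — and scored with
Harrell's C-index. Optimism is estimated by bootstrap: fit on a
resample, evaluate on the resample and on the original data, average
the drop over replicates, subtract it from the apparent C, and report a
95% percentile interval.

## Worked example

The whole pipeline runs from a shell against simulated inputs:

```bash
nucmorph run-all --simulate --out-dir demo --seed 7 \
    --n-bootstrap 200 --n-patients 80 --nuclei-per-patient 25
```

which prints (after per-stage progress logs):

```
both: corrected C = 0.700 (0.662, 0.818)
clinical: corrected C = 0.750 (0.734, 0.775)
geometric: corrected C = 0.675 (0.646, 0.790)
```

Read: on this 80-patient synthetic cohort, nucleus geometry alone
ranks survival times well above the 0.5 chance level (corrected
C = 0.675) because the generator couples nucleus elongation to the true
hazard. The clinical covariates — here the very variables that drive
the simulated hazard — do best on their own; concatenating 26 noisy
geometric columns onto 3 informative clinical ones buys extra apparent
fit that the optimism correction then takes back (apparent 0.800 →
corrected 0.675 for geometric-only). `demo/` now holds
`cell_shapes.csv` (one row per nucleus, dataset-conventional column
names), `patient_features.csv`, `survival_report.json`, and the
resolved config.

The scripted version of the study lives under `analysis/`
(`01_simulate_cohort.py` … `05_survival.py`, each writing its table to
`results/`); `analysis/06_reproduce_real_data.py` reruns the validation
against a real DLBCL-Morph download if you have one.

## Layout

```
src/nucmorph/      library: synthetic, patches, morphometry, aggregate,
                   survival, io, pipeline, cli
analysis/          numbered narrative drivers over the library
tests/             pytest suite (unit, property, acceptance)
scripts/           acceptance.py
docs/methods.md    models, conventions, parameter choices, limitations
```
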