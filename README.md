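# otva

ECG-based localization of outflow-tract ventricular arrhythmia (OTVA)
origin — right (RVOT) versus left (LVOT) ventricular outflow tract — from
standard 12-lead ECG measurements corrected by the anatomical cardiac
long-axis angle, with a complete diagnostic-accuracy evaluation pipeline.

## Who this is for

Electrophysiology researchers and biostatisticians who want to compute,
compare, or re-evaluate ECG localization criteria for OTVAs (premature
ventricular complexes / ventricular tachycardia with LBBB morphology and
precordial transition in V2–V4) ahead of catheter ablation, where the
RVOT-vs-LVOT call directs the mapping strategy.

## The indices

The central index is the **angle-corrected V2S** ("V2S angle"):

    V2S angle = V2S × α   (mV°)

where V2S is the S-wave amplitude in lead V2 during the arrhythmic beat (mV)
and α is the angle between the anatomical cardiac long-axis (mitral-annulus
midpoint → LV apex) and the horizontal plane on a chest radiograph
(degrees). Multiplying by α compensates for cardiac rotation and physique:
a V2S angle ≥ 58.28 mV° predicts an RVOT origin.

The package also implements the comparator criteria — TZ index (transition-
zone score of the arrhythmic beat minus the sinus beat, in 0.5-point
increments V1 = 1 … V6 = 6), V2S/V3R, the combined linear index
Y = −1.15·TZ − 0.494·(V2S/V3R), the V1–V2 S–R difference
(V1S + V2S) − (V1R + V2R), the V3-transition rule, lead-I R amplitude, the
initial R-wave surface-area (ISA) index R-duration × R-amplitude in V1/V2,
and the V1 R/S index — plus the angle-corrected variant of every one
(base index × α).

Evaluation machinery: empirical ROC curves, Mann–Whitney AUC with DeLong or
bootstrap confidence intervals, Youden-optimal cutoffs (midpoint
convention), sensitivity/specificity/PPV/NPV/accuracy with RVOT as the
positive class, reconstruction of confusion matrices from published
sensitivity/specificity and group sizes, and two-group t-tests from summary
statistics. A synthetic cohort generator emulates the published group-wise
marginal distributions (development cohort n = 126 RVOT / 21 LVOT,
validation cohort n = 36 / 12) so the whole pipeline runs without any
patient-level data.

## Worked example

The package ships the published worked-example beat (V2S = 1.3 mV,
V3R = 1.4 mV, α = 45.1°, arrhythmia transition at V2, sinus transition
between V2 and V3):

```sh
$ otva worked-example
v2s_angle = 58.63 (expected 58.63; call: RVOT)
tz_index = -0.50 (expected -0.5; call: LVOT)
v2s_v3r = 0.93 (expected 0.93; call: LVOT)
combined = 0.116 (expected 0.116; call: LVOT)
```

Reading: 1.3 mV × 45.1° = 58.63 mV° ≥ 58.28, so the V2S angle calls RVOT —
the origin confirmed by ablation — while the three comparator indices all
call LVOT on this beat (TZ index 2 − 2.5 = −0.5 < 0; V2S/V3R
1.3/1.4 = 0.93 ≤ 1.5; Y = −1.15·(−0.5) − 0.494·0.93 = 0.116 ≥ −0.76).

The same from Python:

```python
from otva import compute_all, worked_example_record

for res in compute_all(worked_example_record()):
    if res.value is not None:
        print(res.criterion_name, res.value, res.predicted_origin.value)
```

## Cohort-level pipeline

```sh
otva simulate --cohort retrospective --seed 17 --output synth.csv
otva compute  --input synth.csv --preset published --output calls.csv
otva evaluate --input synth.csv --preset published --report report.md --format markdown
```

`report.md` mirrors the familiar table shape, e.g. (synthetic cohort,
seed 17):

```
| Criterion | n | AUC (95% CI) | Cutoff | Youden cutoff | Sens | Spec | PPV | NPV | Accuracy |
|---|---|---|---|---|---|---|---|---|---|
| v2s_angle | 147 | 0.906 (0.842–0.971) | >=58.28 | 37.68 | 70.6% | 90.5% | 97.8% | 33.9% | 73.5% |
```

Two criterion presets ship: `published` (each rule with its published
cutoff and comparator) and `roc_table2` (the ROC-derived cutoff family).
Per-criterion overrides come from a TOML/JSON config (`--config`).

The CSV schema (one row per patient) is documented in
`otva/cli_reporting.py`; empty cells are missing values and propagate to
INDETERMINATE calls, never to silent zeros.

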