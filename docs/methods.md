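# Methods

## Problem and model

Outflow-tract ventricular arrhythmias (OTVAs) with LBBB morphology and
precordial transition in V2–V4 arise either from the right (RVOT) or left
(LVOT) ventricular outflow tract, and the distinction directs the catheter
ablation approach. Because precordial amplitudes depend on cardiac rotation
and physique, the package's central index corrects the V2 S-wave amplitude
by the anatomical cardiac long-axis angle α measured on a chest radiograph
(mitral-annulus midpoint → LV apex against the horizontal; roughly 25–55°,
larger in taller/thinner subjects):

    V2S angle = V2S × α  (mV°),  ≥ 58.28 mV° ⇒ RVOT.

All criteria are deterministic single-threshold rules on scalar indices
(see `otva.ecg_indices` for each formula). RVOT is the positive class in
every metric. Angle correction of any base index is exact multiplication by
α; this is a modeling statement (the correction rescales, it does not
recalibrate), and it is enforced by metamorphic tests.

## Decision rules and presets

Every criterion is a `CriterionRule` (cutoff, direction, strict/inclusive
comparator). Two presets:

* `published` — each rule with the comparator it was published with:
  V2S angle ≥ 58.28 → RVOT; TZ index ≥ 0 → RVOT; V2S/V3R > 1.5 → RVOT;
  Y ≥ −0.76 → LVOT; V1-2 SRd > 1.625 → RVOT; V3-transition positive → LVOT;
  lead-I R ≥ 0.1 mV → LVOT; ISA ≥ 15 → LVOT; V1R/V1S ≥ 0.3 → LVOT.
* `roc_table2` — the ROC-derived development-cohort cutoff family in its
  RVOT-positive orientation: TZ index ≥ −0.25, V2S/V3R ≥ 1.40,
  lead-I ≥ 2.67, ISA ≥ 250, ISA V1 ≥ 0.36, ISA V2 ≥ 42, V1R/V1S > 0.3 →
  LVOT (i.e. ≤ 0.3 → RVOT).

Criteria published without a decision rule (the six per-lead angle indices,
ISA V1/V2, and the angle-corrected family) carry their development-cohort
ROC cutoffs in both presets. Boundary ties go to the GE side under "≥" and
to the non-GE side under ">" — exactly the printed comparators.

The V3-transition rule needs an "R-wave amplitude index in V1" that its
source does not define; the default is the bounded index v1r/(v1r+v1s)
(well-behaved when S dominates), with a config switch
(`v1_amplitude_index_mode="ratio"`) for the raw v1r/v1s reading. The V1R/V1S
criterion value is the amplitude ratio; the stricter two-condition
aortic-sinus-cusp pattern (duration index ≥ 50 % AND ratio ≥ 30 %) is
available as `v1r_v1s_index(...)[2]` but is not a scalar threshold criterion.

## Missing data and degenerate inputs

A missing measurement is `None` end to end; any criterion that needs it
returns a missing value and an INDETERMINATE call (never a silent zero).
Cohort metrics drop INDETERMINATE calls and report the excluded count.
Ratio indices use a signed-infinity sentinel on division by zero
(V2S/V3R = +∞ when V3R = 0 < V2S still classifies as RVOT under ">");
combined or angle-corrected indices that would consume an infinity are
missing instead. A ratio 0/0 is missing. Records with a sinus transition
but no arrhythmic-beat transition (or vice versa) are INDETERMINATE for all
TZ-based criteria.

## ROC, AUC, cutoffs

* AUC = Mann–Whitney U/(n₁n₀) with midrank ties (scipy), which equals the
  trapezoidal area under the empirical ROC curve; both identities are
  asserted against an exhaustive pair-counting oracle and scikit-learn.
* ROC thresholds are +∞ followed by the descending unique scores, so the
  curve runs from (0, 0) to (1, 1); point i applies "score ≥ tᵢ → RVOT"
  (for criteria whose high side predicts LVOT, scores are negated
  internally and thresholds mapped back, i.e. "value ≤ t → RVOT").
* The Youden-optimal cutoff maximizes J = TPR − FPR; ties break toward
  higher specificity, then lower threshold; the returned cutoff is the
  midpoint between the selected observed value and the next lower one.
  All-equal scores give J ≡ 0; the lowest observed value is returned with a
  `degenerate` flag.
* Confidence intervals: DeLong variance with a normal interval (default),
  or a stratified percentile bootstrap (2000 resamples by default, seeded),
  both clipped to [0, 1]. The two agree within 0.02 on fixture data.

## Reconstruction from summary statistics

`confusion_from_summary` inverts printed sensitivity/specificity at known
group sizes: tp = round(sens·n₊), tn = round(spec·n₋) (round-half-up, so
the reconstruction is monotone), then PPV/NPV/accuracy are recomputed from
integer counts. This reproduces every printed predictive value at 1 dp,
e.g. sens 85.7 % / spec 95.2 % at n = 126/21 → (tp, fp, tn, fn) =
(108, 1, 20, 18) → PPV 99.1 %, NPV 52.6 %; and sens 97.2 % / spec 83.3 % at
36/12 → accuracy 93.75 % ≈ 93.8 %. `two_group_test_from_summary` provides
pooled (Student) and Satterthwaite (Welch) t-tests from mean ± SD + n; the
procedure-time comparison (78.8 ± 31.8 min, n = 48 vs 99.5 ± 40.8 min,
n = 147) gives two-sided p ≈ 0.0016 ≈ 0.002. No multiple-testing correction
is applied anywhere, matching the source analyses; normality-gated test
selection is reduced to the explicit `variant` switch.

## Synthetic cohort generator

No patient-level data are deposited, so `otva.synthetic_cohort` generates
labeled cohorts whose group-wise marginals reproduce the printed tables
(development: n = 126 RVOT / 21 LVOT; validation: 36/12).

**Continuous fields.** Each field is a truncated normal inside physical
bounds (amplitudes ≥ 0; α ∈ (5°, 85°); QRS ∈ (120, 300) ms; R durations
< 120 ms ≤ any sampled QRS; LVEF ≥ 50 % per the enrollment criterion). The
underlying (μ, σ) are solved by a 2-D root find so the *realized* truncated
distribution has exactly the printed mean ± SD — naive truncation would
bias both. Where the printed coefficient of variation is unreachable for a
left-truncated normal (its supremum is ~1; only the LVOT V3S marginal,
CV = 1.08, exceeds the solver's reach) a moment-matched log-normal is
selected automatically; either family can be forced per field. An
unmatchable marginal raises rather than silently distorting.

**Transition sites.** Arrhythmic-beat transition sites live on the
enrollment grid V2…V4 (scores 2–4); sinus sites on V2…V4–V5. Per-group
categorical distributions were calibrated once (offline Nelder–Mead on
softmax weights) so the TZ index mean ± SD matches the printed values to
< 0.001 in all four cohort × group cells, and are frozen as package
constants. The sinus support extends past V4 because the printed LVOT
TZ-index variance is unreachable with sinus transitions confined to V2–V4.

**Fields not printed per group.** Initial R-wave durations
(r_dur_v1/v2, r_defl_v3) are nowhere tabulated; defaults are physiological
choices made once: LVOT-origin beats carry broader initial R waves
(r_defl_v3 90 ± 15 ms puts ~75 % past the 80 ms V3-transition limb;
RVOT 60 ± 20 ms mostly below), RVOT r_dur_v1/v2 20/25 ms vs LVOT 45/55 ms.
The printed ISA group summaries are internally inconsistent (the ISA-max
mean exceeds both per-lead means by an order of magnitude) and are not
targeted; ISA is always recomputed from the sampled primitives.
Validation-cohort fields absent from its table reuse the development-cohort
marginals of the same origin group. Lead-I amplitude is generated at its
printed numbers taken as mV, although their scale is mutually inconsistent
with the printed angle-corrected lead-I summary (28.87 × ~37° ≠ 0.13); the
package does not attempt to resolve the units.

**Joint structure.** Fields are independent by default — nothing in the
printed tables constrains the joint distribution. A Gaussian copula
(Spearman ρ mapped to the latent Pearson scale by 2·sin(πρ/6)) can impose
rank correlation; a preset applies ρ = 0.4 among same-beat amplitudes.
Derived indices are never sampled: the pipeline recomputes them from
primitives, so index-level printed summaries (e.g. V2S angle
68.64 ± 29.85) serve as validation targets only. Note the printed index
means are themselves not the product of the printed factor means
(1.82 × 38.6 = 70.25 ≠ 68.64), as expected for correlated, non-degenerate
factors.

**What passing tests do and do not show.** The generator reproduces
marginals (and, optionally, a stylized rank correlation), not the true
joint distribution, skewness, or measurement error of clinical cohorts.
Consequently cohort-level results on synthetic data are internal
consistency checks: the empirical V2S-angle AUC on a large generated
cohort is compared with the binormal closed form Φ(Δμ/√(σ₁² + σ₂²)) = 0.858
at the printed index moments within ±0.05 (Monte-Carlo error plus the
product-of-truncated-normals vs binormal model mismatch; measured ≈ 0.83)
and against the hard bound AUC > 0.8 — not with the published
patient-level AUC of 0.888, which is unrecoverable without the original
data. The same applies to the published ROC cutoffs and the Fig-style
regression; the multiple linear regression of ECG features on the angle is
out of scope entirely.

## Problem sizes and seeds

Property tests run the generator at 8× the development-cohort sizes
(~1000/group) for 3·SE parameter recovery — the SE of a sample SD uses the
resolved marginal's exact fourth central moment, Var(s) ≈ (μ₄ − σ⁴)/(4σ²n),
since the normal-theory σ/√(2n) understates heavy-tailed (log-normal)
sampling error — and at 20× (~2900 records) for the AUC consistency check.
Metamorphic angle-correction sweeps use 10⁴ random records. All random
tests are seeded (hypothesis derandomized); the CLI and generator are
deterministic given (input, config, seed). Reports serialize with sorted
keys and fixed formatting (amplitudes 2 dp, angles 1 dp, proportions 1 dp
in percent, AUC 3 dp), so identical inputs give byte-identical reports.

## Known limitations

* Single-threshold rules only; no probabilistic origin scores or ensembles
  (an opt-in juxtaposition of calls is the extent of combination).
* The generator cannot reproduce patient-level covariance with
  age/BMI/LVEF, waveform-level features, or inter-observer measurement
  variability.
* DeLong intervals are asymptotic; with 21 LVOT cases they can clip at 1.0
  for strongly separated indices.
* Transition sites earlier than V1 or QS patterns without any transition
  have no defined score; such inputs are INDETERMINATE for TZ-based
  criteria rather than guessed.
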