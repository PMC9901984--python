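# Methods

## The model

The multimorbidity index treats each diagnosis as a likelihood-ratio
update on a patient's 6-month death odds. With `b` indexing the 19 body
systems and `LR_b` the likelihood ratio of the worst (highest-LR)
disease the patient carries in system `b`,

```
score = ∏_b LR_b            (systems without a diagnosis contribute 1)
```

This is a naive-Bayes posterior-odds calculation with two deliberate
departures from the textbook form:

1. **Only the worst disease per system enters the product.** Diseases
   within a body system are strongly dependent (they often describe
   stages of the same process), so multiplying all of them would badly
   overcount. Taking the within-system maximum is a coarse but
   interpretable dependence correction: a patient's score never
   decreases as a system's disease worsens, and progression within a
   system reads directly off the LR scale.
2. **The prior odds factor is omitted by default.** The raw product is a
   relative score; it ranks patients identically to the calibrated
   posterior odds (prior × product), so ROC analysis is unaffected.
   `score_patient(..., calibrated=True)` exposes the calibrated version,
   using the training cohort's death odds as prior.

Scores are reported as both odds and natural-log odds. The log form is
recommended when many systems contribute (products of 19 LRs can be
numerically extreme); the two rank identically and give identical ROC
curves, which the tests assert.

## LR estimation

Labels: a patient is *dead* iff a death date exists and falls 0–183 days
(inclusive) after their index date; a missing death date means alive, as
does later death. A death date before the index date is a data error:
the row is excluded and reported. The 183-day horizon is the Medicare
hospice 6-month convention; it is configurable (`horizon_days`).

Counting is patient-level: a patient with five records of a code is one
carrier. The LR of a code with `n_dead`/`n_alive` carriers among
`N_dead`/`N_alive` labeled patients is
`(n_dead/N_dead) / (n_alive/N_alive)`; the all-die and all-survive cases
use `n + 1` and `1/(n + 1)`. Both smoothing values are deliberate
overstatements of certainty growing with `n` — a disease that kills all
500 of its carriers should score far above one that kills both of its
two. LRs are therefore always finite and strictly positive; an LR
printed as 0 in reports is display rounding of a very small value.

**Rare-code rollup.** Codes with fewer than `min_cases = 100` carriers
inherit the LR of their broader ICD-9 concept. The pool of a broader
code is the union of carriers of all its observed descendants (each
patient once). A 5-digit code ascends to its 4-digit parent pool; if
that pool is still under the threshold, to its 3-digit category pool,
which is used regardless of size — replacement, never deletion. Rollup
does not cross the 3-digit category boundary: the category is the
broadest concept that still names a disease rather than a chapter.
A rare 3-digit code keeps its own smoothed LR (there is no broader
within-category concept to borrow from). Whether "fewer than 100" is
counted in patients (default) or raw records is configurable
(`min_cases_unit`), since either reading of the rule is defensible;
patient counting is consistent with patient-level prevalence.

The threshold comparison is strict: exactly 100 carriers keep their own
LR.

## Body systems and the ICD-9 hierarchy

The 19 systems are the 17 ICD-9-CM numeric chapters (001–139
infectious … 800–999 injury/poisoning) plus E codes (external causes)
and V codes (social determinants / health-service factors), assigned by
the 3-digit category. The ranges partition the category space; an
exhaustive sweep over all 1,000 numeric categories plus E/V is part of
the test suite. A `category,system_name` override file can re-bin
specific categories.

Codes parse from dotted or undotted spellings into a canonical undotted
form; numeric categories are zero-padded ("38.12" → 038.12). Undotted
numeric strings are read with a 3-digit category ("3812" → 381.2), the
ICD-9-CM convention — files mixing undotted spellings with implicit
leading zeros are ambiguous and should be dotted. ICD-10 codes are
rejected with a parse error; conversion is out of scope.

## Deyo–Charlson comparator

The 17 conditions are matched by code-prefix lists transcribed from the
published Deyo ICD-9-CM adaptation and shipped as a versioned data file
(`src/mmindex/data/deyo_charlson.csv`, overridable). Weights are the
original Charlson weights: ten 1s, four 2s, one 3 (moderate/severe liver
disease), two 6s (metastatic solid tumor, AIDS/HIV). Severity pairs
(mild vs moderate/severe liver disease, diabetes without vs with
complications, any malignancy vs metastatic tumor) are mutually
exclusive: the severe member suppresses the mild. Age enters as classic
Charlson age points — 0 below 50, one per decade, capped at 4 — the
standard reading of "the index includes age"; treating age as a
continuous covariate would require a regression model the index itself
does not use.

## Evaluation

The split is a seeded patient-level permutation, 90% training by
default, unstratified (a stratified option exists); a training side with
a single outcome class is rejected. AUC is the Mann–Whitney statistic
with midrank tie handling, computed from ranks; its variance, 95% CI and
the paired two-index test use the DeLong placement estimator, chosen
because it is analytic and deterministic. A seeded percentile bootstrap
(2,000 resamples) is the alternative CI method. The relative improvement
statistic is `(AUC_a − AUC_b) / AUC_b`. ROC curves come from
scikit-learn without intermediate-point dropping, so the trapezoidal
area equals the midrank AUC exactly (asserted to 1e-12 in tests).

## Synthetic cohorts

The generator draws, per patient: independent Bernoulli disease
acquisitions; death from `odds/(1 + odds)` with
`odds = baseline_death_odds × ∏ true_effect` over acquired diseases;
a death date uniform in the 183-day horizon; diagnosis dates uniform in
the year before a shared index date; age uniform on [60, 70). All draws
come from one `numpy` generator seeded by the spec, so cohorts are
byte-reproducible.

Defaults and why:

- `baseline_death_odds = 0.02` — a ~2% 6-month death rate, typical of an
  older general-adult primary-care population.
- Ages are confined to a narrow band because age carries no mortality
  signal in the generative model (it enters only the DCI); a wide age
  distribution would add pure noise to one index and none to the other,
  confounding the comparison of their *diagnosis* information.
- `recovery`: three diseases with odds multipliers {4, 1, 0.25} at 5%
  prevalence, n = 200,000 — large enough that sampling error on each LR
  is a few percent.
- `rare_signal_non_charlson` (n = 100,000): moderate-to-large multipliers
  (2.5–12) on codes outside the Deyo map — respiratory failure,
  pneumonia, acute kidney injury, septicemia, cardiac arrest, septic
  shock, palliative-care encounter, and four rare codes (coma 780.01,
  malignant ascites 789.51, cachexia 799.4, brain death 348.82) whose
  prevalences put them under the 100-carrier rollup threshold — plus
  weak Charlson-visible signal (CHF, uncomplicated diabetes) and
  effect-1 background codes.
- `charlson_only` (n = 100,000): all signal on Deyo-mapped codes
  (metastatic tumor, CHF, MI, ESRD, hepatic encephalopathy, lung cancer,
  dementia, COPD, HIV), with weights and multipliers roughly aligned.
- `null` (n = 20,000): every effect 1.

A note on what recovery can show: the fitted LR estimates the *marginal*
likelihood ratio, which equals the generating odds multiplier only in
the limit of rare outcomes. At baseline odds 0.02 the expected marginal
LR of the effect-4 disease is 3.50 (closed-form enumeration over disease
combinations, used as the oracle in tests), not 4.0 — an attenuation
inherent to the quantity, not an estimator bias. Tests therefore check
convergence to the closed-form value, and the ±15% recovery check on the
nominal multipliers absorbs the attenuation.

What the generator does **not** emulate: correlated comorbidity (a
latent-frailty knob was considered and deferred — the marginal LR only
equals the generating multiplier under independence, so the default
generator stays independent); visit patterns, loss to follow-up and
censoring; coding-era effects; age-dependent mortality. Passing tests on
these cohorts show the estimator and the pipeline are correct under the
model's own assumptions, not that the index attains any particular
accuracy on real claims data.

## Numerical and degenerate-input choices

- Ties for worst-in-system break to the lexicographically smallest
  canonical code, for determinism.
- Codes scored but unseen in training get neutral LR 1 and a logged
  warning — the product stays defined without inventing risk.
- Empty history → score 1 (empty product).
- Cohorts with zero deaths or zero survivors are rejected at fit time
  (all LRs would be one-sided).
- LR tables are written with shortest-round-trip float repr, so
  write → read is bit-exact; reports are JSON with sorted keys; reruns
  with the same seed are byte-identical.
- `compare_auc` of a vector with itself returns Δ = 0, p = 1 (the DeLong
  variance of the difference is 0).

## Problem sizes

The shipped scenario sizes (200k / 100k / 20k patients) keep every LR's
sampling error small relative to the effects being recovered while the
whole pipeline — generation, fit, scoring, evaluation — runs in seconds
on one core; the acceptance script completes in under a minute.

## Known limitations

- ICD-9-CM only; ICD-10 inputs are rejected rather than converted.
- The index is a ranking score; calibrated absolute risks require the
  prior-odds factor and, realistically, recalibration per population.
- No confounding control, covariate adjustment or interaction terms
  anywhere in the method — by design.
- The Deyo prefix lists match on code prefixes only; coding-practice
  quirks (e.g. V-code usage) are not modeled.
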