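# Methods

## The screening model

The score is a linear, additive rule set over coded primary-care events. It
is deliberately not a fitted regression: each component is a binary or count
feature with a hand-assigned integer/half-integer weight, chosen during
development from per-component discrimination (Youden's index) plus clinical
rationale, so that the score stays auditable by a GP. The package treats the
rule set as *data* (`data/default_ruleset.yaml`): the engine itself knows only
the four block semantics.

**Censoring.** Every patient is scored on the record up to a censoring date:
the run date by default, or the earliest *ambiguous* diagnosis (a condition
that can be either a PAD complication or a cause of secondary antibody
deficiency — Hodgkin/non-Hodgkin lymphoma, gastric or colorectal cancer,
post-transplantation state). Events dated exactly on the censoring date are
included; this matters because several ambiguous codes also carry weights, and
an exclusive cut would make those weights unreachable. Exclusion criteria
(leukemia, myeloma, HIV, alcoholism, hard-drug addiction, eating disorders,
coded immunodeficiency, cystic fibrosis) are checked on the **untruncated**
record: they indicate secondary antibody deficiency regardless of when they
were coded, so a patient with both an ambiguous and an exclusion code is
excluded, not censored. Age bounds (12–70) are evaluated at the censoring
date, the moment the algorithm would fire.

**Windows.** All look-back windows use a 365-day year and are half-open at
the far end, inclusive at the censoring date: `(censor − N·365 d, censor]`.
The 365-day year matches the year used by the enrollment-normalization
formula and gives unambiguous leap-year behaviour. Antibiotics: 4 years;
respiratory-tract-infection and gastro-intestinal ICPC categories: 10 years;
other infections, auto-immune, malignancy/lymphoproliferative categories and
laboratory values: lifetime; visits: 365 days.

**Antibiotic normalization.** When a patient is enrolled fewer than 4×365
days before censoring, the weighted prescription sum is multiplied by
`4/(days_enrolled/365)`. The published formula is written in terms of the
prescription *count*; because the score is a weighted sum of counts, scaling
the sum is mathematically identical to scaling each count, and we apply it to
the sum. The multiplier is applied only below 1460 enrolled days (at exactly
1460 it equals 1), is uncapped, and a warning is logged below 90 enrolled
days, where the extrapolation is unstable. Enrollment days run from
enrollment start to min(censoring date, enrollment end); zero or negative
observable enrollment is an error rather than a silent zero.

**Component identity.** The published table lists Hodgkin's disease twice —
parent code B72 and sub-code B72.01, identical description and weight. These
are one component that fires on either code; this reconciles the enumerated
table (107 rows) with the stated total of 106 components. All other
parent/sub-code pairs (e.g. R75/R75.01/R75.02) are independent components
that may each score once, as the table weights them separately. The ambiguous
entry printed as "D74 colon or rectal cancer" collides with "D74 gastric
cancer"; the default config records colorectal cancer as D75, the standard
ICPC code, and notes the substitution in a comment. Lab thresholds are strict
(`value < threshold`); a value exactly at threshold does not score.

## Component-selection statistics

`youden_index` computes, for one component, its presence-sensitivity in the
confirmed-PAD group and in the primary-care coded-immunodeficiency group
(each censored pre-diagnosis), averages the two sensitivities (neither case
group is large enough to anchor the choice alone), takes specificity from the
general-population controls, and reports `J = mean sensitivity + specificity − 1`.
`cutoff_sweep` turns a count feature (GP visits natively; any other count via
a caller-supplied counting function) into the family of binary components
"count ≥ c in the 1-year window", evaluates J for each candidate c, and
selects the maximizer, breaking ties toward the smallest cut-off (cheaper to
trigger, same discrimination). When no candidates are given it sweeps the
integer range [median − 3, median + 3] around the PAD-group median, clipped
below at 1. `group_summary` reproduces the descriptive statistics used in
development: per-year antibiotic prescription means in bins
`(censor − k·365, censor − (k−1)·365]` for k = 10..1 (aligned with the
scoring windows), mean 4-year totals, median 1-year visit counts, and
per-analyte lab means/SDs pooled over the 10 pre-censoring years with n =
patients having at least one result (analytes never requested report n = 0
and no mean — the "–" convention). `concordance` is the percentage of
patients for whom two presence flags agree, reported rounded to the integer
with the raw value alongside.

## Synthetic cohorts

The generator exists so that every pipeline stage is testable without patient
data. It emulates the *marginal* structure of seven patient groups — general
population, upper-RTI, COPD/asthma, IBD, malignancy, primary-care coded
immunodeficiency, and PAD — not the joint distribution of any real database.

* **Event processes.** Prescriptions and visits are homogeneous Poisson
  within each pre-censoring year, independent across years and streams;
  diagnosis-code presence and lab requests are independent Bernoulli. Real
  records correlate (prescriptions cluster around infection diagnoses);
  passing tests therefore demonstrate the engine's arithmetic and the
  generator's calibration, not performance on real data.
* **Calibration anchors.** PAD-profile antibiotics follow a linear per-year
  ramp over years −10..−1 from a 0.3/year baseline with the final-4-year mass
  equal to 5.14 expected prescriptions (escalation concentrated in the last
  4 pre-diagnosis years); the general population is flat at 0.12/year (0.48
  per 4 years). Visit rates are Poisson 6.0/year (PAD, pre-diagnosis) and
  2.0/year (general), whose 1-year count medians are 6 and 2; confounder
  groups interpolate (3.0–4.0). PAD coded-symptom prevalences are anchored to
  the pre-diagnosis coded prevalences observed in the development cohort
  (upper RTI 100%, gastro-intestinal 57%, pneumonia 37%, bronchiectasis 20%,
  meningitis 13%), with auto-immune presence spread over common codes.
  Control-group immunoglobulin request probabilities match the observed
  sparsity (e.g. ~0.9% of general-population patients with an IgA result),
  with Gaussian values truncated at zero; the two case-group profiles
  generate **no** immunoglobulin or calculated-globulin results, since these
  were never requested pre-diagnosis. Confounder antibiotic rates (0.20–0.45
  per year) sit between the anchors and are free parameters exposed in the
  profile config.
* **Case anchoring.** Case-group records carry a synthetic diagnosis date
  drawn 1–8 years (uniform) before the run date; all their simulated history
  precedes it, so pre-diagnosis censoring is exercised by passing the
  diagnosis date as the run date. The coded-immunodeficiency profile does
  *not* inject its defining T99.01 code (an exclusion code): the synthetic
  diagnosis date stands in for the moment that code would be assigned.
* **Demographics.** Ages are uniform within per-group ranges chosen inside
  the 12–70 screening band to match the reported group means (e.g.
  malignancy 35–70, PAD 12–60); sex is Bernoulli at the reported female
  fractions. Enrollment length is Gaussian (mean 18 y, SD 6 y) clipped to
  at least 10 years and at most the patient's age, so default cohorts are
  fully observed over all scoring windows and calibration statistics are
  unconfounded by the enrollment correction.
* **Sizes and reproducibility.** Default group sizes keep the two case
  groups at their study sizes (30 and 26) and scale the control groups to
  desk size (general 2000, upper-RTI 450, COPD/asthma 150, IBD 50,
  malignancy 60); every simulation is a pure function of (profile, run
  date, seed), with per-group seeds `seed + group index` recorded, together
  with the full profile parameters and case diagnosis dates, in a manifest
  sufficient for byte-identical regeneration.

## Numerical and design choices

* Dates are ISO calendar dates; age is whole years by the birthday
  convention. Telephone contacts are folded into the "electronic" visit
  modality at load time (both modalities count identically).
* Calculated globulin is derived automatically at load when total protein
  and albumin share a result date; results are never paired across dates.
  A negative derived globulin is returned with a data-quality warning.
* The age-6 prescription floor is enforced even though, with the default
  age bounds and windows, an eligible patient's 4-year window cannot reach
  before age 6; the rule stays correct if windows are reconfigured.
* Ranking ties are broken by patient id (ascending) for reproducible output;
  no high-risk score threshold is asserted by the package — the flagging
  rule (top-k or threshold) is the caller's choice, pending prospective
  calibration.
* The cut-off sweep's spec'd count features beyond GP visits (lung-function
  and infection-blood-test requests) are not representable in the five
  cohort tables — those request events were examined and dropped during
  development — so the sweep accepts a caller-supplied counting function
  for any non-visit feature.

## Verification

The test suite checks each block against hand-computed examples, enforces
the structural invariants (score decomposition, presence idempotence,
censoring monotonicity, normalization identity at exactly 1460 enrolled
days, strict lab thresholds, visit cut-off boundary, Youden bounds,
concordance symmetry, seed reproducibility), and cross-checks `score_patient`
on 500+ randomized records against a brute-force scorer that re-reads the
shipped YAML with a plain parser and re-derives every rule by explicit date
arithmetic. Calibration recovery is tested at n = 2000 per profile within
3 standard errors for means and exactly for medians; case/control score
separation is tested at n = 500 per group at ≥ 3 standard errors.
`scripts/acceptance.py` recomputes the four calibration statistics from a
fresh seeded simulation.

## Known limitations

* The generator's independence assumptions understate real-world clustering
  of infections, prescriptions and visits; discrimination measured on
  synthetic cohorts is optimistic where a profile's defining codes are also
  scored components.
* Single contiguous enrollment per patient; practice switches and enrollment
  gaps are not modelled.
* The rule set maps only ICPC-1 and ATC level-5 codes; no ICD-10/SNOMED
  cross-walks.
* Whether exclusion codes recorded *after* an ambiguous-diagnosis censoring
  date should still exclude is not derivable from the published description;
  this package excludes (secondary-deficiency causes disqualify regardless
  of timing), and documents the choice here.
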