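# padscreen

**padscreen** is a rule engine over structured primary-care EHR data for the
early detection of **primary antibody deficiency (PAD)** — inherited disorders
of immunoglobulin production (CVID, XLA, IgG-subclass and selective IgA
deficiency) whose heterogeneous presentation drives a median diagnostic delay
of many years. Because patients first present to their GP, and GP records in
gatekeeper health systems hold a comprehensive coded history, a weighted score
over those records can notify GPs when immunoglobulin testing should be
considered.

The package is aimed at clinical-informatics teams who want to run, adapt or
re-derive such a screening score:

* a **scoring engine** over five delimited-text cohort tables (patients,
  ICPC-coded diagnoses, ATC-coded prescriptions, laboratory results, GP
  visits), with censoring at ambiguous diagnoses, exclusion of secondary
  antibody deficiency, and per-category subscores;
* the published **106-component rule set** shipped as a machine-readable YAML
  config (editable, validated on load);
* the **development statistics** used to select components: per-component
  sensitivity/specificity and Youden's index, cut-off sweeps, group summaries
  and coded-vs-free-text concordance;
* a **synthetic cohort generator** for seven calibrated patient-group
  profiles, so every stage is testable without patient data.

## The score

For an eligible patient (age 12–70 at the censoring date, no ICPC code for a
cause of secondary antibody deficiency such as leukemia, myeloma or HIV):

```
S = A + Σ_c I_c + L + V
```

* **Antibiotics** `A = Σ_p w(p)` over prescriptions *p* of 20 listed
  antibiotics in the 4 years before the censoring date (and after the 6th
  birthday), weights w ∈ {0.5, 1, 2} per prescription; when the patient was
  enrolled `d < 4×365` days, `A` is rescaled by `4/(d/365)`.
* **ICPC categories** `I_c`: 77 diagnosis components in five categories
  (respiratory tract infections, gastro-intestinal complaints, other
  infections, auto-immune symptoms, malignancies/lymphoproliferative), each
  scoring its weight (0.5–4) once on presence — within 10 years for the first
  two categories, lifetime for the rest.
* **Laboratory** `L`: 8 components scoring 4–8 points when a result is
  strictly below threshold (e.g. IgG < 7 g/L → 8; calculated globulin =
  total protein − albumin < 18 g/L → 6).
* **Visits** `V = 3` if the patient had ≥ 6 GP contacts (physical or
  electronic) in the past year.

Diagnoses that can be either a PAD complication or a cause of secondary
deficiency (e.g. non-Hodgkin lymphoma) are *ambiguous*: the record is scored
only up to the first such diagnosis date.

## Worked example

```bash
padscreen simulate --seed 42 --run-date 2021-11-18 --out-dir study
padscreen screen study/pad --run-date 2021-11-18 --top-k 5 --out-dir screen_out
```

prints

```
wrote 7 cohorts, manifest study/manifest.json
screened 30 patients (0 ineligible), flagged 5 -> screen_out
```

and the top of `screen_out/results.csv` reads

```
patient_id,censoring_date,eligible,exclusion_reason,antibiotic_score,...,total_score
pad-00019,2021-11-18,true,,8.0,5.0,0.0,0.0,1.0,0.0,0.0,0.0,14.0
pad-00006,2021-11-18,true,,4.0,2.0,2.0,0.0,3.0,0.0,0.0,0.0,11.0
```

Patient `pad-00019` scores 14: 8 points from antibiotic prescriptions in the
last 4 years, 5 from respiratory-infection codes and 1 from an auto-immune
code. `screen_out/explanations.txt` itemizes each fired component, and
`flagged.csv` lists the patients selected for laboratory follow-up.

The development statistics run over simulated case/control cohorts:

```bash
padscreen evaluate --pad-dir study/pad --pcid-dir study/pc_immunodef \
    --control-dir study/general --run-date 2021-11-18 \
    --manifest study/manifest.json --out-dir eval_out
```

which writes one Youden's-index row per component
(`component_diagnostics.csv`), per-group prescription/visit summaries, and a
visit cut-off sweep. At these small simulated group sizes (30 PAD / 26
primary-care immunodeficiency cases) the sweep selected a cut-off of 4
visits; the published cut-off of 6 came from the real cohorts.

## Library use

```python
from datetime import date
import padscreen as ps

rs = ps.default_ruleset()            # the shipped 106-component algorithm
records = ps.load_cohort({...})      # five CSV paths
result = ps.score_patient(records[0], date(2021, 11, 18), rs)
print(result.total_score, result.fired_components)
```

See `docs/methods.md` for the model, parameter and calibration details.
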