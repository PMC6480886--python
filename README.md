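# promsagree

Agreement between patient-reported chronic diseases and diagnoses derived
from linked hospital administrative records.

## What this is for

Pre-operative questionnaires in national patient-reported outcome
programmes ask patients whether a doctor has ever told them they have heart
disease, high blood pressure, stroke, leg pain due to poor circulation,
lung disease, diabetes, kidney disease, diseases of the nervous system,
liver disease, cancer, depression or arthritis. Hospital administrative
data record ICD-10 diagnosis codes for every inpatient admission. This
package implements, as a tested and reusable pipeline, the procedure for
validating the self-reports against the administrative record:

1. **Cohort construction** — deduplicate linked questionnaire/procedure
   records, keep each patient's first procedure, exclude questionnaires
   reporting ≥ 7 conditions, with full flow-chart accounting.
2. **Code mapping** — a condition → ICD-10 map (seeded from Charlson- and
   Elixhauser-style index lists, editable JSON) with *backward coding*:
   screening admissions of patients who reported a condition but carry no
   mapped code, and adding 4-character codes whose prevalence among
   reporters is at least twice that among non-reporters.
3. **Reference-standard flags** — a patient is admin-positive when a mapped
   code appears on the index admission or any admission within a look-back
   window (12 months or 5 years by default).
4. **Agreement statistics** — per condition, the 2×2 table (both /
   administrative only / patient-reported only / neither), sensitivity and
   specificity with 95% CIs (Wald by default, Wilson optional), Cohen's
   kappa with a Fleiss-type asymptotic CI, and the qualitative kappa band
   (poor < 0.40 ≤ moderate ≤ 0.60 < substantial ≤ 0.80 < near perfect).
5. **Subcategory analysis** — sensitivity of each self-report against
   cause / manifestation / consequence subgroupings of the code map, as a
   forest-plot-ready table.

Because real questionnaire–admissions extracts cannot be redistributed, the
package includes a seeded synthetic generator of linked data with known
latent truth (per-condition prevalence, reporting sensitivity/specificity,
per-admission coding rates, duplicate questionnaires, repeat procedures,
high-count responders), so every stage is testable end to end. See
`docs/methods.md` for the model and all numerical conventions.

## Worked example

Statistics straight from published 2×2 cells (no cohort data needed). The
package ships the 1-year look-back contingency cells of a large English
arthroplasty validation cohort (N = 676,428) as its default input:

```sh
$ promsagree from-counts
heart_disease: sensitivity 46.4% (46.2, 46.7); specificity 98.1% (98.0, 98.1); kappa 0.54 (0.54, 0.54) [moderate agreement]
high_blood_pressure: sensitivity 74.3% (74.1, 74.4); specificity 90.3% (90.2, 90.4); kappa 0.65 (0.64, 0.65) [substantial agreement]
stroke: sensitivity 32.2% (31.1, 33.3); specificity 98.7% (98.7, 98.7); kappa 0.25 (0.24, 0.25) [poor agreement]
...
diabetes: sensitivity 87.5% (87.3, 87.7); specificity 98.8% (98.8, 98.8); kappa 0.88 (0.87, 0.88) [near perfect agreement]
```

Reading the diabetes row: of the 78,816 admin-positive patients, 87.5%
also said "yes" on the questionnaire; of the admin-negative patients,
98.8% said "no"; chance-corrected agreement κ = 0.88 falls in the
"near perfect" band. Specificity is high for every condition, while
sensitivity varies widely (18.8% for kidney disease up to 87.5% for
diabetes) — self-report is most reliable for conditions that are precisely
named, familiar, and consequential in daily life.

The same statistics from a synthetic cohort, end to end:

```python
import promsagree as pa

config = pa.SimulationConfig(n_patients=20_000, seed=1)
questionnaire, admissions, truth = pa.generate_cohort(config)
cohort, admissions, report = pa.build_cohort(questionnaire, admissions)
flags = pa.derive_flags(cohort, admissions, pa.load_default_codemap(),
                        pa.LookbackSpec(window_days=365))
for r in pa.agreement_suite(cohort, flags.frame):
    print(pa.format_result(r))
```

Or from the shell, producing agreement and subcategory tables at both
look-backs plus the exclusion report, backward-coding audit and a
re-run manifest:

```sh
promsagree run-all --simulate-n 20000 --seed 1 --backward-coding --out results/
```

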