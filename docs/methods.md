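# Methods

## Problem and model

`promsagree` validates patient-reported chronic disease against diagnoses
derived from linked hospital administrative data, in the setting of a
national pre-operative questionnaire programme for hip and knee replacement.
Each patient contributes (a) a questionnaire with one yes/no answer per
listed chronic condition ("Have you ever been told by a doctor that you
have…", twelve conditions including arthritis) and (b) a stream of inpatient
admission records, each carrying up to 20 ICD-10 diagnosis codes. The
administrative side is taken as the reference standard: a patient is
admin-positive for a condition when a mapped ICD-10 code appears on the
index admission (the admission of the joint replacement itself) or on any
admission within a look-back window before it.

For each condition the package cross-tabulates patient report against the
admin flag and reports, with the admin flag as reference:

- sensitivity  `se = both / (both + admin_only)`
- specificity  `sp = neither / (neither + patient_only)`
- Cohen's kappa  `κ = (p_o − p_e) / (1 − p_e)`, with
  `p_o = (both + neither)/N` and
  `p_e = p_admin·p_patient + (1 − p_admin)(1 − p_patient)`.

Arthritis is excluded from agreement analyses by default (it is the
indication for the operation and reported by the overwhelming majority), but
it is kept on the questionnaire and counts toward the high-count exclusion.

## Cohort construction

Exclusions run in a fixed order, and the counts are reported in that order
(they are order-dependent, so the order is part of the contract):

1. **Duplicates.** A procedure linked to more than one questionnaire, or a
   questionnaire linked to more than one procedure, is ambiguous. The
   default `drop-all` mode removes every row of an ambiguous group — the
   source material says duplicates "were excluded" without a keep rule, so
   the reproducible, conservative reading is used. A `keep-first` mode
   (smallest row id survives) exists for sensitivity checks.
2. **First procedure.** Each patient keeps the earliest index admission
   (ties broken by admission id); questionnaires linked to later procedures
   are counted as subsequent-procedure exclusions.
3. **High-count responders.** Questionnaires with ≥ 7 "yes" answers over the
   twelve listed conditions are dropped; the threshold is inclusive and
   configurable. Arthritis is counted: it is on the questionnaire and the
   exclusion rule is stated without restriction. Counting only the eleven
   analysis conditions is available by passing an explicit condition list.

`ExclusionReport` enforces `n_final = n_input − Σ exclusions` as a type
invariant. A defensive `n_no_index_admission` category (always zero on valid
fixtures) catches questionnaires whose patient has no index admission at
all; they are excluded with a logged warning rather than an error, because
real-world linked extracts can contain them.

## Code map and backward coding

A `CodeMap` stores normalized ICD-10 codes (uppercase, dot-free, 3 or 4
characters) per condition. A 3-character category implicitly covers all its
4-character children (prefix matching). The shipped default map is a
reconstruction assembled from the published ICD-10 lists of the RCS Charlson,
Quan Charlson and Elixhauser comorbidity indices; it is **not** an
authoritative transcription of any validated instrument and every entry
point accepts a user map (JSON: `{condition: {chapters: [...], codes:
[{code, subcategory, provenance}]}}`).

Backward coding augments a condition's set from the data:

1. Among patients who reported the condition but carry no mapped code in the
   look-back window ("unexplained reporters"), observed 3-character
   categories are screened. A category is a candidate when it lies in the
   condition's chapter allowlist, occurs in **strictly more than 1%** of all
   condition reporters, and is not already mapped at the 3-character level.
   The chapter allowlist is the package's reproducible proxy for the
   clinical-relevance judgement a human panel would make; it lives in the
   map config so users can tighten or widen it.
2. Every observed 4-character child of a screened category is evaluated: it
   is accepted when its prevalence among reporters is **at least twice** its
   prevalence among non-reporters (a ratio of exactly 2.0 is accepted; zero
   non-reporter prevalence with nonzero reporter prevalence is +∞ and
   accepted, flagged in the audit). Prevalence denominators are all
   reporters / all non-reporters in the cohort; presence means ≥ 1
   in-window admission carrying the code.

Every evaluated candidate — accepted or not — appears exactly once in the
audit table. Augmentation is monotone (codes are never removed) and
per-condition independent; a code may belong to several conditions. The
backward-coding window defaults to 1 year; which window the original
procedure used is not stated, so it is an explicit config parameter.

## Look-back flags

`LookbackSpec(window_days, include_index)` defines the reference window:
365 days for "previous 12 months", 1826 for "five years", measured backwards
from the index admission day. The early boundary is closed (an admission
exactly `window_days` before the index counts); admissions after the index
day never count (the reference standard is pre-operative status); a
non-index admission on the index day itself counts as history. Day-level
conventions like these are not stated in day units anywhere authoritative,
so they are fixed and documented here for reproducibility. Flags are
insensitive to diagnosis-code position and monotone in the window length.

## Agreement statistics

- **Proportion CIs:** normal-approximation (Wald) intervals by default,
  truncated to [0, 1]; chosen because they reproduce the published
  sensitivity CIs (e.g. kidney disease 18.8% (18.4, 19.2)) to the printed
  decimal. Wilson intervals are available behind `ci_method="wilson"`; they
  behave better at extreme prevalences and tiny denominators.
- **Kappa CI:** the Fleiss–Cohen–Everitt (1969) large-sample variance,
  cross-checked in the test suite against the independent statsmodels
  inter-rater implementation to 1e-12. At cohort sizes in the hundreds of
  thousands the interval is near-degenerate, so printed values cannot
  discriminate between variance formulas; the choice is recorded in output
  metadata.
- **Degenerate inputs:** zero denominators and `p_e = 1` yield an
  `Estimate` carrying `value=None` and a reason string, never an exception;
  empty 2×2 tables are rejected at construction.
- **Kappa bands:** poor < 0.40, moderate [0.40, 0.60], substantial
  (0.60, 0.80], near perfect (0.80, 1.00]. The conventional band list leaves
  (0.60, 0.61) and (0.80, 0.81) unassigned at 2-decimal granularity; both
  gaps go to the upper band.
- **Display:** percentages to 1 d.p., kappa to 2 d.p.; machine-readable
  output keeps full precision. Published tables are trusted at the cell
  level and marginals are recomputed (two known printed inconsistencies: the
  heart-disease cells sum to an admin marginal of 122,196 against a printed
  122,219, and the leg-pain cells sum to one more than the printed N).

## Subcategory sensitivity

Codes can carry free-text subcategory labels (cause / manifestation /
consequence of disease, or disease-specific labels such as
"insulin-dependent diabetes"); unlabelled codes form "other". For each
(condition, subcategory), the denominator is patients flagged through any
code with that label in-window and the numerator is those also
self-reporting the condition, with the same proportion CI machinery.
Subcategories overlap in patients; the rows are not a partition. Only
sensitivity is computed at this level. `forest_table` emits a plot-ready
frame and `forest_plot` an optional matplotlib figure.

## Synthetic data generator

The generator emulates the linked data-generating situation, with a single
seed driving everything (identical configs are byte-identical on disk):

- latent truth per patient × condition (Bernoulli, per-condition
  prevalence);
- questionnaire responses via per-condition report sensitivity/specificity;
- one index admission per patient (first procedure day uniform in a
  one-year accrual window after the history span), Poisson prior admissions
  with days uniform over the history span before the index;
- per-admission, per-condition coding: with probability
  `code_sensitivity_per_admission` (truth) or
  `code_false_positive_per_admission` (no truth), one uniformly drawn
  mapped code lands on the admission; codes are shuffled within an
  admission and truncated at 20;
- planted data problems: exact-copy duplicate questionnaires (distinct row
  id), repeat procedures (a second, later index admission with its own
  questionnaire), and high-count responders who tick exactly 8 randomly
  chosen conditions regardless of truth (comfortably past the ≥ 7
  exclusion).

Dates are integer day offsets from an arbitrary cohort start; no calendar or
timezone arithmetic exists anywhere in the package.

Defaults are set to resemble the large English arthroplasty cohort the
method was developed on: per-condition prevalence and reporting accuracy
follow the published 1-year-look-back figures; structural rates are repeat
procedures 13%, duplicate questionnaires 1.5%, high-count responders 0.1%,
mean 1.5 prior admissions over a 5-year history span, per-admission coding
sensitivity 0.6 and false-positive rate 0.002 (values without a published
counterpart were chosen once as realistic magnitudes).

What the generator does **not** emulate: demographic covariates and their
correlation with disease, severity gradients within conditions, correlated
multimorbidity (conditions are independent given the patient), coding-depth
drift over calendar time, and imperfect linkage. Passing tests therefore
demonstrate algorithmic correctness and statistical calibration under a
known-truth model, not performance on real extracts.

## Problem sizes used in the test and acceptance runs

Oracle-equivalence tests run 10⁴ random 2×2 tables against direct scalar
formulas and 300-patient cohorts against per-patient brute-force re-scans.
The parameter-recovery study runs 100 seeded replicates of n = 20,000
patients with reporting sensitivity 0.875 / specificity 0.99 and noise-free
coding (so admin flags equal latent truth), checking that the pipeline's 95%
CIs cover the configured rates; these sizes give per-replicate standard
errors of ~0.7% (sensitivity) and ~0.08% (specificity). The acceptance
script re-analyses the shipped published 2×2 cells (N = 676,428) and one
20,000-patient recovery replicate.

## Known limitations

- The default code map is illustrative; results on real data depend
  entirely on the map supplied.
- Backward coding's chapter allowlist is a mechanical stand-in for clinical
  judgement; its output should be reviewed, which is why the full audit is
  always written.
- Wald intervals undercover slightly at extreme prevalences with moderate
  denominators; use `ci_method="wilson"` when denominators are small.
- Episode/spell structure within admissions, outpatient and primary-care
  sources, and probabilistic linkage are out of scope.
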