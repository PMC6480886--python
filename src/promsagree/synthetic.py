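"""Synthetic linked questionnaire + admissions generator with known truth.

Emulates the data-generating situation of a pre-operative questionnaire
programme linked to inpatient admission records: each patient has a latent
true status per chronic condition, reports it on the questionnaire with
condition-specific sensitivity/specificity, and accumulates hospital
admissions whose diagnosis fields carry mapped codes with per-admission
coding sensitivity and false-positive rates. The generator also plants the
data problems the cohort builder must handle: duplicate questionnaires,
repeat (subsequent) procedures and high-count responders.

Dates are integer day offsets from an arbitrary cohort start (day 0); no
calendar arithmetic is involved. All randomness flows from a single seed, so
identical configurations produce byte-identical fixtures.

Default rates are chosen to resemble a large national arthroplasty cohort:
per-condition prevalences and reporting accuracies follow the published
1-year look-back validation figures for the eleven analysis conditions, and
the structural rates (repeat procedures ≈ 13%, duplicate questionnaires
1.5%, high-count responders 0.1%) match the magnitudes seen in such
programmes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .codemap import CodeMap, load_default_codemap
from .conditions import CONDITIONS
from .exceptions import ConfigurationError

MAX_DIAG_CODES = 20

# (true_prevalence, report_sensitivity, report_specificity) per condition;
# reporting accuracies follow the published 1-year validation estimates.
_DEFAULT_RATES: dict[str, tuple[float, float, float]] = {
    "heart_disease": (0.181, 0.464, 0.981),
    "high_blood_pressure": (0.497, 0.743, 0.903),
    "stroke": (0.011, 0.322, 0.987),
    "leg_pain_poor_circulation": (0.016, 0.261, 0.932),
    "lung_disease": (0.148, 0.468, 0.985),
    "diabetes": (0.117, 0.875, 0.988),
    "kidney_disease": (0.054, 0.188, 0.991),
    "nervous_system_disease": (0.029, 0.209, 0.997),
    "liver_disease": (0.006, 0.343, 0.997),
    "cancer": (0.019, 0.688, 0.964),
    "depression": (0.044, 0.610, 0.933),
    "arthritis": (0.810, 0.950, 0.700),
}


@dataclass(frozen=True)
class ConditionParams:
    """Per-condition generative rates."""

    true_prevalence: float
    report_sensitivity: float
    report_specificity: float
    code_sensitivity_per_admission: float = 0.6
    code_false_positive_per_admission: float = 0.002

    def __post_init__(self):
        for name in (
            "true_prevalence",
            "report_sensitivity",
            "report_specificity",
            "code_sensitivity_per_admission",
            "code_false_positive_per_admission",
        ):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ConfigurationError(f"{name} must be in [0, 1], got {v}")


@dataclass(frozen=True)
class SimulationConfig:
    """Full description of one synthetic cohort."""

    n_patients: int
    seed: int = 0
    conditions: tuple[str, ...] = CONDITIONS
    params: dict[str, ConditionParams] = field(default_factory=dict)
    admissions_per_patient_mean: float = 1.5
    history_span_days: int = 1826
    duplicate_questionnaire_rate: float = 0.015
    repeat_procedure_rate: float = 0.13
    high_count_responder_rate: float = 0.001

    def __post_init__(self):
        if self.n_patients < 1:
            raise ConfigurationError(
                f"n_patients must be >= 1, got {self.n_patients}"
            )
        if self.admissions_per_patient_mean <= 0:
            raise ConfigurationError(
                "admissions_per_patient_mean must be positive, got "
                f"{self.admissions_per_patient_mean}"
            )
        if self.history_span_days < 1:
            raise ConfigurationError(
                f"history_span_days must be >= 1, got {self.history_span_days}"
            )
        for name in (
            "duplicate_questionnaire_rate",
            "repeat_procedure_rate",
            "high_count_responder_rate",
        ):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ConfigurationError(f"{name} must be in [0, 1], got {v}")
        if not self.params:
            object.__setattr__(
                self,
                "params",
                {
                    c: ConditionParams(*_DEFAULT_RATES[c])
                    for c in self.conditions
                    if c in _DEFAULT_RATES
                },
            )
        if set(self.params) != set(self.conditions):
            raise ConfigurationError(
                "params must cover exactly the configured conditions; "
                f"missing {sorted(set(self.conditions) - set(self.params))}, "
                f"extra {sorted(set(self.params) - set(self.conditions))}"
            )

    def with_params(self, **per_condition_overrides) -> "SimulationConfig":
        """Return a copy with some conditions' rates replaced."""
        params = dict(self.params)
        for cond, p in per_condition_overrides.items():
            if cond not in params:
                raise ConfigurationError(f"unknown condition {cond!r}")
            params[cond] = p
        return replace(self, params=params)


def uniform_params(
    conditions=CONDITIONS,
    true_prevalence=0.1,
    report_sensitivity=0.9,
    report_specificity=0.98,
    code_sensitivity_per_admission=0.6,
    code_false_positive_per_admission=0.002,
) -> dict[str, ConditionParams]:
    """Identical rates for every condition — convenient for experiments."""
    p = ConditionParams(
        true_prevalence,
        report_sensitivity,
        report_specificity,
        code_sensitivity_per_admission,
        code_false_positive_per_admission,
    )
    return {c: p for c in conditions}


def generate_cohort(
    config: SimulationConfig, cmap: CodeMap | None = None
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Generate (questionnaire table, admissions table, ground truth).

    The questionnaire table has one row per completed questionnaire (one per
    index procedure, plus exact-copy duplicates); the admissions table one
    row per admission with up to 20 diagnosis code columns; the truth table
    one row per patient with the latent boolean status per condition.
    """
    cmap = cmap or load_default_codemap()
    rng = np.random.default_rng(np.uint32(config.seed))
    n = config.n_patients
    conds = list(config.conditions)
    patient_ids = np.array([f"P{i:07d}" for i in range(n)])

    # latent truth
    truth = {
        c: rng.random(n) < config.params[c].true_prevalence for c in conds
    }

    # index admissions: first procedure in [span, span + 365); repeats later
    span = config.history_span_days
    index_day = rng.integers(span, span + 365, n)
    has_repeat = rng.random(n) < config.repeat_procedure_rate
    repeat_gap = rng.integers(30, 365, n)

    # prior (history) admissions
    n_prior = rng.poisson(config.admissions_per_patient_mean, n)

    # --- assemble admission skeleton -----------------------------------
    rows = []  # (patient_idx, day, is_index)
    for i in range(n):
        rows.append((i, index_day[i], 1))
        if has_repeat[i]:
            rows.append((i, index_day[i] + repeat_gap[i], 1))
    prior_patient = np.repeat(np.arange(n), n_prior)
    prior_day = index_day[prior_patient] - 1 - rng.integers(
        0, span, prior_patient.size
    )
    adm_patient = np.concatenate(
        [np.array([r[0] for r in rows]), prior_patient]
    ).astype(int)
    adm_day = np.concatenate([np.array([r[1] for r in rows]), prior_day]).astype(int)
    adm_index = np.concatenate(
        [np.array([r[2] for r in rows]), np.zeros(prior_patient.size, int)]
    )
    order = np.lexsort((adm_index * -1, adm_day, adm_patient))
    adm_patient, adm_day, adm_index = (
        adm_patient[order],
        adm_day[order],
        adm_index[order],
    )
    n_adm = adm_patient.size
    admission_ids = np.array([f"A{i:08d}" for i in range(n_adm)])

    # --- diagnosis coding ------------------------------------------------
    # per admission × condition Bernoulli, rate depending on latent truth
    code_lists: dict[str, np.ndarray] = {
        c: np.array(sorted(cmap.codes(c))) if c in cmap.conditions else np.array([])
        for c in conds
    }
    diag_rows: list[np.ndarray] = []
    diag_cols: list[np.ndarray] = []
    for c in conds:
        pool = code_lists[c]
        if pool.size == 0:
            continue
        p = config.params[c]
        truth_per_adm = truth[c][adm_patient]
        rate = np.where(
            truth_per_adm,
            p.code_sensitivity_per_admission,
            p.code_false_positive_per_admission,
        )
        hit = rng.random(n_adm) < rate
        idx = np.nonzero(hit)[0]
        if idx.size:
            diag_rows.append(idx)
            diag_cols.append(pool[rng.integers(0, pool.size, idx.size)])
    if diag_rows:
        d_adm = np.concatenate(diag_rows)
        d_code = np.concatenate(diag_cols)
        # shuffle code order within admission so position carries no signal
        shuffle_key = rng.random(d_adm.size)
        order = np.lexsort((shuffle_key, d_adm))
        d_adm, d_code = d_adm[order], d_code[order]
        pos = (
            pd.Series(np.arange(d_adm.size))
            .groupby(d_adm)
            .cumcount()
            .to_numpy()
        )
        keep = pos < MAX_DIAG_CODES
        d_adm, d_code, pos = d_adm[keep], d_code[keep], pos[keep]
    else:  # pragma: no cover - empty coding config
        d_adm = np.array([], int)
        d_code = np.array([], str)
        pos = np.array([], int)

    diag = np.full((n_adm, MAX_DIAG_CODES), "", dtype=object)
    diag[d_adm, pos] = d_code

    admissions = pd.DataFrame(
        {
            "admission_id": admission_ids,
            "patient_id": patient_ids[adm_patient],
            "admission_day": adm_day,
            "is_index_procedure": adm_index,
        }
    )
    for j in range(MAX_DIAG_CODES):
        admissions[f"diag_{j + 1:02d}"] = diag[:, j]

    # --- questionnaires --------------------------------------------------
    # responses per patient
    resp = {}
    for c in conds:
        p = config.params[c]
        yes_if_true = rng.random(n) < p.report_sensitivity
        yes_if_false = rng.random(n) < (1 - p.report_specificity)
        resp[c] = np.where(truth[c], yes_if_true, yes_if_false)
    # high-count responders tick exactly 8 random conditions
    hcr = rng.random(n) < config.high_count_responder_rate
    n_tick = min(8, len(conds))
    for i in np.nonzero(hcr)[0]:
        ticked = rng.choice(len(conds), n_tick, replace=False)
        for k, c in enumerate(conds):
            resp[c][i] = k in ticked

    # one questionnaire per index admission, completed on the admission day
    q_mask = adm_index == 1
    q_patient = adm_patient[q_mask]
    q_link = admission_ids[q_mask]
    q_day = adm_day[q_mask]
    questionnaire = pd.DataFrame(
        {
            "patient_id": patient_ids[q_patient],
            "procedure_link_id": q_link,
            "completion_day": q_day,
        }
    )
    for c in conds:
        questionnaire[c] = resp[c][q_patient].astype(int)

    # exact-copy duplicate questionnaires (same procedure link, new row id)
    dup = rng.random(len(questionnaire)) < config.duplicate_questionnaire_rate
    if dup.any():
        questionnaire = pd.concat(
            [questionnaire, questionnaire[dup]], ignore_index=True
        )
    questionnaire = questionnaire.sort_values(
        ["patient_id", "completion_day", "procedure_link_id"], kind="stable"
    ).reset_index(drop=True)
    questionnaire.insert(
        0, "row_id", [f"Q{i:08d}" for i in range(len(questionnaire))]
    )

    truth_df = pd.DataFrame({"patient_id": patient_ids})
    for c in conds:
        truth_df[c] = truth[c].astype(bool)
    return questionnaire, admissions, truth_df


def write_fixture(
    questionnaire: pd.DataFrame,
    admissions: pd.DataFrame,
    truth: pd.DataFrame,
    outdir: str | Path,
) -> dict[str, Path]:
    """Write questionnaire.csv, admissions.csv and truth.json; the CSVs
    round-trip losslessly through the pipeline readers."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "questionnaire": outdir / "questionnaire.csv",
        "admissions": outdir / "admissions.csv",
        "truth": outdir / "truth.json",
    }
    questionnaire.to_csv(paths["questionnaire"], index=False)
    admissions.to_csv(paths["admissions"], index=False)
    payload = {
        row["patient_id"]: {
            c: bool(row[c]) for c in truth.columns if c != "patient_id"
        }
        for _, row in truth.iterrows()
    }
    paths["truth"].write_text(json.dumps(payload, indent=1) + "\n")
    return paths
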