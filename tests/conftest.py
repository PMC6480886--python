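import numpy as np
import pandas as pd
import pytest

from promsagree import (
    CONDITIONS,
    SimulationConfig,
    generate_cohort,
    load_default_codemap,
)

N_DIAG = 20


def make_admissions(rows):
    """Build an admissions table from (admission_id, patient_id, day,
    is_index, [codes...]) tuples."""
    records = []
    for admission_id, patient_id, day, is_index, *codes in rows:
        rec = {
            "admission_id": admission_id,
            "patient_id": patient_id,
            "admission_day": day,
            "is_index_procedure": int(is_index),
        }
        codes = codes[0] if codes else []
        for j in range(N_DIAG):
            rec[f"diag_{j + 1:02d}"] = codes[j] if j < len(codes) else ""
        records.append(rec)
    return pd.DataFrame(records)


def make_questionnaire(rows, conditions=CONDITIONS):
    """Build a questionnaire table from (row_id, patient_id,
    procedure_link_id, day, yes_set) tuples."""
    records = []
    for row_id, patient_id, link, day, yes in rows:
        rec = {
            "row_id": row_id,
            "patient_id": patient_id,
            "procedure_link_id": link,
            "completion_day": day,
        }
        for c in conditions:
            rec[c] = int(c in yes)
        records.append(rec)
    return pd.DataFrame(records)


def make_cohort(rows, conditions=CONDITIONS):
    """Build a built-cohort table from (patient_id, link, index_day, yes_set)
    tuples."""
    records = []
    for i, (patient_id, link, index_day, yes) in enumerate(rows):
        rec = {
            "row_id": f"Q{i:04d}",
            "patient_id": patient_id,
            "procedure_link_id": link,
            "index_day": index_day,
        }
        for c in conditions:
            rec[c] = c in yes
        records.append(rec)
    return pd.DataFrame(records)


@pytest.fixture(scope="session")
def default_codemap():
    return load_default_codemap()


@pytest.fixture(scope="session")
def small_fixture():
    """A 300-patient synthetic fixture shared across oracle tests."""
    config = SimulationConfig(n_patients=300, seed=11)
    return config, *generate_cohort(config)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
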