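"""Study-sample construction: dedup, first procedure, high-count exclusion.

The raw material is a table of linked records — one pre-operative
questionnaire row per index procedure — plus the admissions table. The
builder applies three exclusion stages in a fixed order:

1. duplicates: more than one questionnaire linked to a procedure, or more
   than one index admission sharing a procedure identifier;
2. subsequent procedures: each patient keeps only the earliest index
   admission (and its questionnaire);
3. high-count responders: questionnaires ticking "yes" to seven or more of
   the listed conditions are dropped (the response pattern is considered
   unreliable).

Counts are reported in linked-record (questionnaire-row) units and satisfy
n_final = n_input − Σ exclusions; because duplicates are resolved before the
first-procedure rule, the counts are order-dependent and the order is part
of the contract.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import pandas as pd

from .conditions import CONDITIONS
from .exceptions import ConfigurationError, SchemaError

logger = logging.getLogger(__name__)

_Q_REQUIRED = ("row_id", "patient_id", "procedure_link_id")
_A_REQUIRED = ("admission_id", "patient_id", "admission_day", "is_index_procedure")


@dataclass(frozen=True)
class ExclusionReport:
    """Flow-chart bookkeeping for one cohort build."""

    n_input: int
    n_duplicate_questionnaires: int
    n_duplicate_procedures: int
    n_subsequent_procedures: int
    n_high_count_responders: int
    n_final: int
    n_no_index_admission: int = 0  # defensive category; zero on valid input

    def __post_init__(self):
        expected = self.n_input - (
            self.n_duplicate_questionnaires
            + self.n_duplicate_procedures
            + self.n_subsequent_procedures
            + self.n_high_count_responders
            + self.n_no_index_admission
        )
        if self.n_final != expected:
            raise SchemaError(
                f"exclusion arithmetic violated: n_final={self.n_final} but "
                f"input minus exclusions = {expected}"
            )

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2) + "\n")


def _require(frame: pd.DataFrame, columns, name: str) -> None:
    missing = [c for c in columns if c not in frame.columns]
    if missing:
        raise SchemaError(f"{name} table is missing column(s) {missing}")


def drop_duplicates(
    questionnaire: pd.DataFrame,
    admissions: pd.DataFrame,
    mode: str = "drop-all",
) -> tuple[pd.DataFrame, pd.DataFrame, int, int]:
    """Resolve many-to-one linkage groups.

    ``drop-all`` (default) removes every row of an ambiguous group — the
    reproducible, conservative reading of "duplicates were excluded".
    ``keep-first`` keeps the first row (smallest row id) of each group for
    sensitivity checks. Returns (questionnaire, admissions, n_dup_q,
    n_dup_proc) with counts in questionnaire-row units.
    """
    _require(questionnaire, _Q_REQUIRED, "questionnaire")
    _require(admissions, _A_REQUIRED, "admissions")
    if mode not in ("drop-all", "keep-first"):
        raise ConfigurationError(f"unknown dedup mode {mode!r}")

    q = questionnaire.copy()
    a = admissions.copy()

    # >1 questionnaire linked to one procedure
    dup_q_mask = q.duplicated("procedure_link_id", keep=False)
    if mode == "keep-first":
        keep = ~q.sort_values("row_id").duplicated("procedure_link_id", keep="first")
        removed_q = (~keep).sum()
        q = q[keep.reindex(q.index)]
    else:
        removed_q = int(dup_q_mask.sum())
        q = q[~dup_q_mask]

    # >1 index admission sharing one procedure id (two procedures linked to
    # the same questionnaire)
    idx = a[a["is_index_procedure"].astype(bool)]
    dup_ids = set(idx.loc[idx.duplicated("admission_id", keep=False), "admission_id"])
    removed_proc = 0
    if dup_ids:
        if mode == "keep-first":
            first = ~a.duplicated("admission_id", keep="first")
            a = a[first | ~a["admission_id"].isin(dup_ids)]
        else:
            affected = q["procedure_link_id"].isin(dup_ids)
            removed_proc = int(affected.sum())
            q = q[~affected]
            a = a[~(a["admission_id"].isin(dup_ids) & a["is_index_procedure"].astype(bool))]
    if removed_q or removed_proc:
        logger.info(
            "dedup (%s): removed %d duplicate questionnaires, %d duplicate "
            "procedures",
            mode,
            removed_q,
            removed_proc,
        )
    return q.reset_index(drop=True), a.reset_index(drop=True), int(removed_q), removed_proc


def keep_first_procedure(admissions: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Keep each patient's earliest index admission (smallest admission_day,
    ties broken by admission_id); later index admissions are removed. History
    (non-index) admissions are untouched."""
    _require(admissions, _A_REQUIRED, "admissions")
    a = admissions.copy()
    idx = a[a["is_index_procedure"].astype(bool)].sort_values(
        ["patient_id", "admission_day", "admission_id"], kind="stable"
    )
    first_ids = set(idx.drop_duplicates("patient_id", keep="first")["admission_id"])
    drop_mask = a["is_index_procedure"].astype(bool) & ~a["admission_id"].isin(first_ids)
    removed = int(drop_mask.sum())
    if removed:
        logger.info("first-procedure rule: removed %d subsequent index admissions", removed)
    return a[~drop_mask].reset_index(drop=True), removed


def exclude_high_count_responders(
    questionnaire: pd.DataFrame,
    threshold: int = 7,
    conditions=None,
) -> tuple[pd.DataFrame, int]:
    """Drop questionnaires reporting ``threshold`` or more conditions
    ("seven or more" is inclusive). All listed conditions present in the
    table — including arthritis — contribute to the count."""
    if threshold < 1:
        raise ConfigurationError(f"high-count threshold must be >= 1, got {threshold}")
    if conditions is None:
        conditions = [c for c in CONDITIONS if c in questionnaire.columns]
    missing = [c for c in conditions if c not in questionnaire.columns]
    if missing:
        raise SchemaError(f"questionnaire table is missing condition column(s) {missing}")
    n_yes = questionnaire[list(conditions)].astype(bool).sum(axis=1)
    mask = n_yes >= threshold
    removed = int(mask.sum())
    if removed:
        logger.info(
            "high-count rule (>= %d of %d conditions): removed %d questionnaires",
            threshold,
            len(conditions),
            removed,
        )
    return questionnaire[~mask].reset_index(drop=True), removed


def build_cohort(
    questionnaire: pd.DataFrame,
    admissions: pd.DataFrame,
    threshold: int = 7,
    dedup: str = "drop-all",
    conditions=None,
) -> tuple[pd.DataFrame, pd.DataFrame, ExclusionReport]:
    """Apply the three exclusion stages in order and assemble the cohort.

    Returns (cohort, reduced admissions, report). The cohort has one row per
    patient: linkage keys, the index admission day, and the questionnaire
    responses as booleans.
    """
    n_input = len(questionnaire)
    q, a, n_dup_q, n_dup_p = drop_duplicates(questionnaire, admissions, dedup)
    a, _ = keep_first_procedure(a)

    # questionnaires whose linked index admission survived
    idx = a[a["is_index_procedure"].astype(bool)][["admission_id", "admission_day"]]
    idx = idx.rename(columns={"admission_id": "procedure_link_id", "admission_day": "index_day"})
    merged = q.merge(idx, on="procedure_link_id", how="left", validate="many_to_one")
    linked = merged["index_day"].notna()
    # rows linked to a removed subsequent procedure vs truly orphaned rows
    all_index_ids = set(
        admissions.loc[
            admissions["is_index_procedure"].astype(bool), "admission_id"
        ]
    )
    had_procedure = merged["procedure_link_id"].isin(all_index_ids)
    n_subsequent = int((~linked & had_procedure).sum())
    n_orphan = int((~linked & ~had_procedure).sum())
    if n_orphan:
        logger.warning(
            "%d questionnaire row(s) have no index admission at all; excluded",
            n_orphan,
        )
    q = merged[linked].reset_index(drop=True)

    q, n_high = exclude_high_count_responders(q, threshold, conditions)

    report = ExclusionReport(
        n_input=n_input,
        n_duplicate_questionnaires=n_dup_q,
        n_duplicate_procedures=n_dup_p,
        n_subsequent_procedures=n_subsequent,
        n_high_count_responders=n_high,
        n_final=len(q),
        n_no_index_admission=n_orphan,
    )
    if conditions is None:
        conditions = [c for c in CONDITIONS if c in q.columns]
    cohort = q[
        ["row_id", "patient_id", "procedure_link_id", "index_day", *conditions]
    ].copy()
    cohort["index_day"] = cohort["index_day"].astype(int)
    for c in conditions:
        cohort[c] = cohort[c].astype(bool)
    return cohort, a, report
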