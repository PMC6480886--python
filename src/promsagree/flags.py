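"""Administrative reference-standard flags with a configurable look-back.

A patient is flagged positive for a condition when any diagnosis code on the
index admission (optional) or on an admission within the look-back window
matches the condition's code set. The window covers admission days in
``[index_day − window_days, index_day)``: closed on the early side, open at
the index day, whose contribution is controlled separately — the index
admission itself only counts when ``include_index`` is set, while any OTHER
admission falling on the index day is treated as in-window history.
Admissions after the index day never contribute: the reference standard is
pre-operative status.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .codemap import CodeMap
from .conditions import CONDITIONS
from .exceptions import ContractViolationError, SchemaError

#: "previous 12 months"
LOOKBACK_1Y_DAYS = 365
#: "previous five years"
LOOKBACK_5Y_DAYS = 1826


@dataclass(frozen=True)
class LookbackSpec:
    window_days: int = LOOKBACK_1Y_DAYS
    include_index: bool = True

    def __post_init__(self):
        if self.window_days < 1:
            raise SchemaError(f"window_days must be >= 1, got {self.window_days}")


@dataclass
class AdminFlagTable:
    """Per-patient, per-condition boolean flags plus the window used."""

    frame: pd.DataFrame  # patient_id + one bool column per condition
    spec: LookbackSpec

    @property
    def conditions(self) -> list[str]:
        return [c for c in self.frame.columns if c != "patient_id"]

    def write(self, path: str | Path, codemap_checksum: str | None = None) -> None:
        path = Path(path)
        out = self.frame.copy()
        for c in self.conditions:
            out[c] = out[c].astype(int)
        out.to_csv(path, index=False)
        sidecar = {
            "window_days": self.spec.window_days,
            "include_index": self.spec.include_index,
            "codemap_sha256": codemap_checksum,
        }
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2) + "\n")


def _diag_columns(admissions: pd.DataFrame) -> list[str]:
    cols = [c for c in admissions.columns if c.startswith("diag_")]
    if not cols:
        raise SchemaError("admissions table has no diag_* columns")
    return cols


def window_code_table(
    cohort: pd.DataFrame, admissions: pd.DataFrame, spec: LookbackSpec
) -> pd.DataFrame:
    """Long table (patient_id, admission_id, code) of soft-normalized codes
    on in-window admissions of cohort patients. Codes are uppercased and
    dot-stripped; strings that still do not look like ICD-10 codes simply
    never match anything."""
    for col in ("patient_id", "index_day", "procedure_link_id"):
        if col not in cohort.columns:
            raise SchemaError(f"cohort table is missing column {col!r}")
    a = admissions.merge(
        cohort[["patient_id", "index_day", "procedure_link_id"]],
        on="patient_id",
        how="inner",
    )
    is_index = a["admission_id"] == a["procedure_link_id"]
    if spec.include_index:
        missing = set(cohort["patient_id"]) - set(a.loc[is_index, "patient_id"])
        if missing:
            raise ContractViolationError(
                f"{len(missing)} cohort patient(s) lack their index admission "
                f"(e.g. {sorted(missing)[:3]})"
            )
    in_window = (
        (a["admission_day"] >= a["index_day"] - spec.window_days)
        & (a["admission_day"] <= a["index_day"])
        & ~is_index
    )
    keep = in_window | (is_index if spec.include_index else False)
    a = a[keep]
    long = a.melt(
        id_vars=["patient_id", "admission_id"],
        value_vars=_diag_columns(a),
        value_name="code",
    )[["patient_id", "admission_id", "code"]]
    long = long[long["code"].astype(str).str.len() > 0]
    long = long.dropna(subset=["code"])
    long["code"] = (
        long["code"].astype(str).str.strip().str.upper().str.replace(".", "", regex=False).str[:4]
    )
    return long.reset_index(drop=True)


def derive_flags(
    cohort: pd.DataFrame,
    admissions: pd.DataFrame,
    cmap: CodeMap,
    spec: LookbackSpec | None = None,
    conditions=None,
) -> AdminFlagTable:
    """Derive the admin flag for every cohort patient and mapped condition."""
    spec = spec or LookbackSpec()
    if conditions is None:
        conditions = [c for c in CONDITIONS if c in cmap.conditions]
    codes = window_code_table(cohort, admissions, spec)
    flags = pd.DataFrame({"patient_id": cohort["patient_id"].to_numpy()})
    prefix3 = codes["code"].str[:3]
    for c in conditions:
        full = cmap.code_set(c)
        pref = cmap.prefix_set(c)
        hit = codes.loc[codes["code"].isin(full) | prefix3.isin(pref), "patient_id"]
        positive = set(hit)
        flags[c] = flags["patient_id"].isin(positive).to_numpy()
    return AdminFlagTable(flags, spec)


def flag_prevalence(flags: AdminFlagTable) -> pd.DataFrame:
    """Counts and cohort fractions per condition."""
    n = len(flags.frame)
    if n == 0:
        raise SchemaError("flag table is empty")
    rows = [
        {
            "condition": c,
            "count": int(flags.frame[c].sum()),
            "fraction": float(flags.frame[c].mean()),
        }
        for c in flags.conditions
    ]
    return pd.DataFrame(rows)
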