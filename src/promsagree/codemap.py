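"""Condition → ICD-10 code mapping, with backward-coding augmentation.

A :class:`CodeMap` holds, per condition, a set of normalized ICD-10 codes.
Codes are stored uppercase and dot-free, either at the three-character
category level (``E11``) or the four-character subcategory level (``E119``).
A three-character code in a condition's set implicitly covers all of its
four-character children (prefix matching).

Backward coding augments a condition's code set from the data itself: among
patients who self-reported the condition but carry no mapped code in their
look-back window, common three-character categories (in clinically allowed
chapters) are screened, and each observed four-character child is accepted
when its prevalence among reporters is at least twice its prevalence among
non-reporters.

The shipped default map is a reconstruction assembled from the published
ICD-10 lists of the Royal College of Surgeons Charlson index, the Quan
Charlson index and the Elixhauser index; it is NOT an authoritative
transcription of any validated instrument, and every entry point accepts a
user-supplied map.
"""

from __future__ import annotations

import json
import logging
import math
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .exceptions import (
    CodeValidationError,
    ConfigurationError,
    EvaluationError,
    UnknownConditionError,
)

logger = logging.getLogger(__name__)

_ICD10_RE = re.compile(r"^[A-Z][0-9]{2}[A-Z0-9]?$")

PROVENANCE_SEED = "seed-index"
PROVENANCE_BACKWARD = "backward-coded"
PROVENANCE_USER = "user"


def normalize_code(raw: str) -> str:
    """Normalize a raw ICD-10 string: uppercase, strip the dot, truncate to
    four characters. Raises :class:`CodeValidationError` for anything that
    does not look like an ICD-10 code (letter + two digits + optional
    alphanumeric fourth character)."""
    if not isinstance(raw, str) or not raw.strip():
        raise CodeValidationError(raw, f"empty or non-string code: {raw!r}")
    code = raw.strip().upper().replace(".", "")[:4]
    if not _ICD10_RE.match(code):
        raise CodeValidationError(raw)
    return code


@dataclass(frozen=True)
class MappedCode:
    """One code in a condition's set, with its subcategory label (free text,
    e.g. 'cause', 'manifestation', 'consequence') and provenance tag."""

    code: str
    subcategory: str | None = None
    provenance: str = PROVENANCE_USER


@dataclass
class CodeMap:
    """Condition → set of normalized ICD-10 codes with labels and provenance.

    ``chapters`` holds, per condition, the ICD-10 chapter letters considered
    clinically relevant for backward coding (a reproducible proxy for the
    manual clinical-relevance judgement).
    """

    _codes: dict[str, dict[str, MappedCode]] = field(default_factory=dict)
    chapters: dict[str, set[str]] = field(default_factory=dict)

    # -- construction -----------------------------------------------------

    def add_condition(self, condition: str, chapters: Iterable[str] = ()) -> None:
        self._codes.setdefault(condition, {})
        self.chapters.setdefault(condition, set()).update(chapters)

    def add_code(
        self,
        condition: str,
        raw_code: str,
        subcategory: str | None = None,
        provenance: str = PROVENANCE_USER,
    ) -> str:
        """Add a (normalized) code to a condition; returns the stored code.
        Adding an already-present code keeps the existing entry."""
        self._codes.setdefault(condition, {})
        self.chapters.setdefault(condition, set())
        code = normalize_code(raw_code)
        if code not in self._codes[condition]:
            self._codes[condition][code] = MappedCode(code, subcategory, provenance)
        return code

    def copy(self) -> "CodeMap":
        return CodeMap(
            {c: dict(m) for c, m in self._codes.items()},
            {c: set(s) for c, s in self.chapters.items()},
        )

    # -- lookup -----------------------------------------------------------

    @property
    def conditions(self) -> list[str]:
        return list(self._codes)

    def codes(self, condition: str) -> dict[str, MappedCode]:
        if condition not in self._codes:
            raise UnknownConditionError(condition)
        return self._codes[condition]

    def code_set(self, condition: str) -> frozenset[str]:
        return frozenset(self.codes(condition))

    def prefix_set(self, condition: str) -> frozenset[str]:
        """Three-character members, which cover all their children."""
        return frozenset(c for c in self.codes(condition) if len(c) == 3)

    def match(self, condition: str, code: str) -> bool:
        """True iff ``code`` or its three-character prefix is mapped to the
        condition. ``code`` must already be normalized."""
        codes = self.codes(condition)
        return code in codes or code[:3] in self.prefix_set(condition)

    def subcategories(self, condition: str) -> dict[str, list[str]]:
        """Group the condition's codes by subcategory label; unlabelled codes
        fall into ``"other"``."""
        out: dict[str, list[str]] = {}
        for code, entry in self.codes(condition).items():
            out.setdefault(entry.subcategory or "other", []).append(code)
        return {k: sorted(v) for k, v in out.items()}

    # -- serialisation ----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            cond: {
                "chapters": sorted(self.chapters.get(cond, ())),
                "codes": [
                    {
                        "code": e.code,
                        "subcategory": e.subcategory,
                        "provenance": e.provenance,
                    }
                    for e in sorted(entries.values(), key=lambda e: e.code)
                ],
            }
            for cond, entries in self._codes.items()
        }

    @classmethod
    def from_dict(cls, payload: Mapping) -> "CodeMap":
        cmap = cls()
        for cond, spec in payload.items():
            cmap.add_condition(cond, spec.get("chapters", ()))
            for entry in spec.get("codes", ()):
                cmap.add_code(
                    cond,
                    entry["code"],
                    entry.get("subcategory"),
                    entry.get("provenance", PROVENANCE_USER),
                )
        return cmap

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "CodeMap":
        return cls.from_dict(json.loads(Path(path).read_text()))

    def checksum(self) -> str:
        import hashlib

        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()


def match_code(cmap: CodeMap, condition: str, code: str) -> bool:
    """Functional form of :meth:`CodeMap.match`."""
    return cmap.match(condition, code)


def load_default_codemap() -> CodeMap:
    """The shipped reconstructed default map (non-authoritative)."""
    with resources.files("promsagree.data").joinpath(
        "default_codemap.json"
    ).open() as fh:
        return CodeMap.from_dict(json.load(fh))


# ---------------------------------------------------------------------------
# Backward coding
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BackwardCodingCandidate:
    """One four-character code evaluated during backward coding."""

    condition: str
    code: str
    n_reporters_with_code: int
    n_reporters: int
    n_nonreporters_with_code: int
    n_nonreporters: int
    prevalence_ratio: float  # math.inf when non-reporter prevalence is zero
    accepted: bool

    @property
    def reporter_prevalence(self) -> float:
        return self.n_reporters_with_code / self.n_reporters

    @property
    def nonreporter_prevalence(self) -> float:
        return self.n_nonreporters_with_code / self.n_nonreporters


def _patient_codes_in_window(cohort, admissions, lookback) -> pd.DataFrame:
    """Long table (patient_id, code) of normalized codes on in-window
    admissions. Imported lazily from the flag-derivation module to keep the
    window convention in one place."""
    from .flags import window_code_table

    return window_code_table(cohort, admissions, lookback)


def find_unexplained_reporters(
    cohort: pd.DataFrame,
    admissions: pd.DataFrame,
    cmap: CodeMap,
    condition: str,
    lookback,
) -> set:
    """Patients answering "yes" to the condition whose in-window admissions
    carry no code currently mapped to it."""
    reporters = set(cohort.loc[cohort[condition].astype(bool), "patient_id"])
    codes = _patient_codes_in_window(cohort, admissions, lookback)
    codes = codes[codes["patient_id"].isin(reporters)]
    matched = codes[_match_series(cmap, condition, codes["code"])]
    return reporters - set(matched["patient_id"])


def _match_series(cmap: CodeMap, condition: str, codes: pd.Series) -> pd.Series:
    full = cmap.code_set(condition)
    prefixes = cmap.prefix_set(condition)
    return codes.isin(full) | codes.str[:3].isin(prefixes)


def screen_three_char(
    cohort: pd.DataFrame,
    admissions: pd.DataFrame,
    cmap: CodeMap,
    condition: str,
    chapters: Iterable[str] | None = None,
    min_fraction: float = 0.01,
    lookback=None,
) -> list[str]:
    """Candidate three-character categories for backward coding.

    Categories must (a) appear on an in-window admission of at least one
    unexplained reporter, (b) fall in an allowed ICD-10 chapter, (c) occur in
    strictly more than ``min_fraction`` of all condition reporters, and (d)
    not already be fully mapped (i.e. present at the three-character level).
    """
    from .flags import LookbackSpec

    lookback = lookback or LookbackSpec()
    chapters = set(chapters) if chapters is not None else set(
        cmap.chapters.get(condition, ())
    )
    if not chapters:
        raise ConfigurationError(
            f"empty ICD-10 chapter allowlist for condition {condition!r}"
        )

    reporter_mask = cohort[condition].astype(bool)
    reporters = set(cohort.loc[reporter_mask, "patient_id"])
    n_reporters = len(reporters)
    if n_reporters == 0:
        return []

    codes = _patient_codes_in_window(cohort, admissions, lookback)
    codes = codes.assign(category=codes["code"].str[:3])

    unexplained = find_unexplained_reporters(
        cohort, admissions, cmap, condition, lookback
    )
    observed = set(
        codes.loc[codes["patient_id"].isin(unexplained), "category"]
    )

    rep_codes = codes[codes["patient_id"].isin(reporters)]
    # Patients per category, among reporters.
    counts = (
        rep_codes.drop_duplicates(["patient_id", "category"])
        .groupby("category")
        .size()
    )
    out = []
    already = cmap.prefix_set(condition)
    for cat, n in counts.items():
        if cat not in observed or cat[0] not in chapters or cat in already:
            continue
        if n / n_reporters > min_fraction:
            out.append(cat)
    return sorted(out)


def evaluate_four_char(
    cohort: pd.DataFrame,
    admissions: pd.DataFrame,
    cmap: CodeMap,
    condition: str,
    category: str,
    ratio_threshold: float = 2.0,
    lookback=None,
) -> list[BackwardCodingCandidate]:
    """Evaluate every observed four-character child of ``category``.

    A child is accepted when reporter prevalence ≥ ratio_threshold ×
    non-reporter prevalence ("at least twice": a ratio of exactly 2.0 is
    accepted; a zero non-reporter prevalence with a nonzero reporter
    prevalence is treated as +inf and accepted).
    """
    from .flags import LookbackSpec

    lookback = lookback or LookbackSpec()
    reporter_mask = cohort[condition].astype(bool)
    reporters = set(cohort.loc[reporter_mask, "patient_id"])
    nonreporters = set(cohort.loc[~reporter_mask, "patient_id"])
    if not reporters or not nonreporters:
        raise EvaluationError(
            f"cannot compare prevalences for {condition!r}: "
            f"{len(reporters)} reporters, {len(nonreporters)} non-reporters"
        )

    codes = _patient_codes_in_window(cohort, admissions, lookback)
    children = codes[(codes["code"].str[:3] == category) & (codes["code"].str.len() == 4)]
    per_patient = children.drop_duplicates(["patient_id", "code"])

    results = []
    for code, grp in per_patient.groupby("code"):
        carriers = set(grp["patient_id"])
        n_rep = len(carriers & reporters)
        n_non = len(carriers & nonreporters)
        p_rep = n_rep / len(reporters)
        p_non = n_non / len(nonreporters)
        if p_non > 0:
            ratio = p_rep / p_non
        elif p_rep > 0:
            ratio = math.inf
        else:
            ratio = 0.0
        results.append(
            BackwardCodingCandidate(
                condition=condition,
                code=code,
                n_reporters_with_code=n_rep,
                n_reporters=len(reporters),
                n_nonreporters_with_code=n_non,
                n_nonreporters=len(nonreporters),
                prevalence_ratio=ratio,
                accepted=ratio >= ratio_threshold,
            )
        )
    return sorted(results, key=lambda c: c.code)


def backward_code(
    cohort: pd.DataFrame,
    admissions: pd.DataFrame,
    cmap: CodeMap,
    condition: str,
    chapters: Iterable[str] | None = None,
    lookback=None,
    min_fraction: float = 0.01,
    ratio_threshold: float = 2.0,
) -> tuple[CodeMap, list[BackwardCodingCandidate]]:
    """Run the two-stage augmentation for one condition.

    Returns an augmented copy of the map (the input map is never mutated and
    never loses codes) and the complete audit of evaluated candidates.
    """
    augmented = cmap.copy()
    audit: list[BackwardCodingCandidate] = []
    categories = screen_three_char(
        cohort, admissions, cmap, condition, chapters, min_fraction, lookback
    )
    for category in categories:
        candidates = evaluate_four_char(
            cohort, admissions, cmap, condition, category, ratio_threshold, lookback
        )
        audit.extend(candidates)
        for cand in candidates:
            if cand.accepted:
                augmented.add_code(
                    condition, cand.code, provenance=PROVENANCE_BACKWARD
                )
                logger.info(
                    "backward coding: %s += %s (reporter %.4f vs non-reporter "
                    "%.4f, ratio %.2f)",
                    condition,
                    cand.code,
                    cand.reporter_prevalence,
                    cand.nonreporter_prevalence,
                    cand.prevalence_ratio,
                )
            else:
                logger.info(
                    "backward coding: %s rejected %s (ratio %.2f < %.2f)",
                    condition,
                    cand.code,
                    cand.prevalence_ratio,
                    ratio_threshold,
                )
    return augmented, audit


def audit_to_frame(audit: list[BackwardCodingCandidate]) -> pd.DataFrame:
    """Audit list as a CSV-ready table, one row per candidate."""
    return pd.DataFrame(
        [
            {
                "condition": c.condition,
                "code": c.code,
                "n_reporters_with_code": c.n_reporters_with_code,
                "n_reporters": c.n_reporters,
                "n_nonreporters_with_code": c.n_nonreporters_with_code,
                "n_nonreporters": c.n_nonreporters,
                "prevalence_ratio": c.prevalence_ratio,
                "accepted": c.accepted,
            }
            for c in audit
        ],
        columns=[
            "condition",
            "code",
            "n_reporters_with_code",
            "n_reporters",
            "n_nonreporters_with_code",
            "n_nonreporters",
            "prevalence_ratio",
            "accepted",
        ],
    )
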