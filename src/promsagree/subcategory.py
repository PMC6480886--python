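"""Sensitivity of patient report against administrative subcategories.

Each condition's code set can be partitioned by free-text subcategory labels
(e.g. a cause such as subarachnoid haemorrhage, a manifestation such as
asthma, a consequence such as renal failure; unlabelled codes form "other").
For every (condition, subcategory) the denominator is the set of patients
flagged positive through any code carrying that label within the look-back
window, and the numerator is the subset who also self-reported the
condition. Subcategories overlap in patients — a patient coded in two
subcategories counts in both denominators — so the rows are not a partition
of the admin-positive group.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from .agreement import Estimate, _proportion_estimate
from .codemap import CodeMap
from .exceptions import SchemaError
from .flags import LookbackSpec, window_code_table

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SubcategoryResult:
    condition: str
    subcategory: str
    n_admin_positive: int
    n_also_reported: int
    sensitivity: Estimate


def subcategory_sensitivity(
    cohort: pd.DataFrame,
    admissions: pd.DataFrame,
    cmap: CodeMap,
    spec: LookbackSpec | None = None,
    conditions=None,
    ci_level: float = 0.95,
    ci_method: str = "wald",
) -> list[SubcategoryResult]:
    """One row per (condition, subcategory), in map order."""
    spec = spec or LookbackSpec()
    if conditions is None:
        conditions = [c for c in cmap.conditions if c in cohort.columns]
    codes = window_code_table(cohort, admissions, spec)
    prefix3 = codes["code"].str[:3]
    results = []
    for cond in conditions:
        if cond not in cohort.columns:
            raise SchemaError(f"cohort table is missing condition column {cond!r}")
        reported = set(cohort.loc[cohort[cond].astype(bool), "patient_id"])
        groups = cmap.subcategories(cond)
        if set(groups) == {"other"}:
            logger.warning(
                "condition %r has no labelled codes; only an 'other' row emitted",
                cond,
            )
        for label, members in groups.items():
            full = frozenset(members)
            pref = frozenset(c for c in members if len(c) == 3)
            hit = codes.loc[
                codes["code"].isin(full) | prefix3.isin(pref), "patient_id"
            ]
            positive = set(hit)
            n_pos = len(positive)
            n_rep = len(positive & reported)
            results.append(
                SubcategoryResult(
                    condition=cond,
                    subcategory=label,
                    n_admin_positive=n_pos,
                    n_also_reported=n_rep,
                    sensitivity=_proportion_estimate(n_rep, n_pos, ci_level, ci_method),
                )
            )
    return results


def forest_table(results: list[SubcategoryResult]) -> pd.DataFrame:
    """Plot-ready table: ordered rows with estimate and truncated bounds."""
    if not results:
        raise SchemaError("no subcategory results to tabulate")
    return pd.DataFrame(
        [
            {
                "condition": r.condition,
                "subcategory": r.subcategory,
                "n": r.n_admin_positive,
                "numerator": r.n_also_reported,
                "estimate": r.sensitivity.value,
                "ci_low": r.sensitivity.ci_low,
                "ci_high": r.sensitivity.ci_high,
            }
            for r in results
        ]
    )


def forest_plot(results: list[SubcategoryResult], path=None):
    """Optional rendered forest plot (matplotlib); returns the figure."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    table = forest_table(results)
    table = table[table["estimate"].notna()]
    labels = table["condition"] + " — " + table["subcategory"]
    y = range(len(table))[::-1]
    fig, ax = plt.subplots(figsize=(7, 0.35 * len(table) + 1.5))
    est = table["estimate"].to_numpy(float)
    ax.errorbar(
        est,
        list(y),
        xerr=[
            est - table["ci_low"].to_numpy(float),
            table["ci_high"].to_numpy(float) - est,
        ],
        fmt="o",
        color="black",
        ecolor="gray",
        capsize=2,
    )
    ax.set_yticks(list(y), labels)
    ax.set_xlabel("sensitivity of patient report (95% CI)")
    ax.set_xlim(0, 1)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path)
    return fig
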