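"""Agreement statistics: 2×2 tables, sensitivity/specificity, Cohen's kappa.

The administrative flag is the reference standard throughout:

* sensitivity = P(patient reports yes | admin flag positive)
  = both / (both + admin_only)
* specificity = P(patient reports no | admin flag negative)
  = neither / (neither + patient_only)
* Cohen's kappa = (p_o − p_e) / (1 − p_e), the chance-corrected agreement,
  where p_o is the observed agreement proportion and p_e the agreement
  expected from the two marginal prevalences.

Proportion confidence intervals use the normal-approximation (Wald) interval
by default, with Wilson available behind a flag; kappa intervals use the
Fleiss–Cohen–Everitt (1969) large-sample variance. All intervals are
truncated to their parameter range.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.proportion import proportion_confint

from .conditions import ANALYSIS_CONDITIONS
from .exceptions import AlignmentError, ConfigurationError, SchemaError

@dataclass(frozen=True)
class TwoByTwo:
    """Agreement counts for one condition: patient report × admin flag."""

    both: int
    admin_only: int
    patient_only: int
    neither: int

    def __post_init__(self):
        for name in ("both", "admin_only", "patient_only", "neither"):
            v = getattr(self, name)
            if v < 0 or v != int(v):
                raise SchemaError(f"cell {name} must be a nonnegative count, got {v!r}")
        if self.total == 0:
            raise SchemaError("2x2 table is empty (total = 0)")

    @property
    def total(self) -> int:
        return self.both + self.admin_only + self.patient_only + self.neither

    @property
    def n_admin_positive(self) -> int:
        return self.both + self.admin_only

    @property
    def n_patient_positive(self) -> int:
        return self.both + self.patient_only

    @property
    def admin_prevalence(self) -> float:
        return self.n_admin_positive / self.total

    @property
    def patient_prevalence(self) -> float:
        return self.n_patient_positive / self.total

    @property
    def either_prevalence(self) -> float:
        return (self.both + self.admin_only + self.patient_only) / self.total

    def swapped(self) -> "TwoByTwo":
        """Exchange the roles of the two sources."""
        return TwoByTwo(self.both, self.patient_only, self.admin_only, self.neither)


@dataclass(frozen=True)
class Estimate:
    """A point estimate with its confidence interval, or a documented reason
    why it is undefined (zero denominator, degenerate marginals)."""

    value: float | None
    ci_low: float | None = None
    ci_high: float | None = None
    reason: str | None = None

    @property
    def defined(self) -> bool:
        return self.value is not None

    def as_tuple(self):
        return (self.value, self.ci_low, self.ci_high)


def _proportion_estimate(
    count: int, nobs: int, ci_level: float, method: str
) -> Estimate:
    if nobs == 0:
        return Estimate(None, reason="zero denominator")
    p = count / nobs
    sm_method = {"wald": "normal", "wilson": "wilson"}.get(method)
    if sm_method is None:
        raise ConfigurationError(f"unknown CI method {method!r}")
    lo, hi = proportion_confint(count, nobs, alpha=1 - ci_level, method=sm_method)
    return Estimate(p, float(np.clip(lo, 0, 1)), float(np.clip(hi, 0, 1)))


def sens_spec(
    table: TwoByTwo, ci_level: float = 0.95, method: str = "wald"
) -> tuple[Estimate, Estimate]:
    """Sensitivity and specificity of the patient report against the
    administrative reference standard, with binomial CIs."""
    sens = _proportion_estimate(table.both, table.n_admin_positive, ci_level, method)
    spec = _proportion_estimate(
        table.neither, table.neither + table.patient_only, ci_level, method
    )
    return sens, spec


def _kappa_variance(table: TwoByTwo) -> float:
    """Fleiss–Cohen–Everitt (1969) large-sample variance of kappa-hat for a
    two-category table."""
    n = table.total
    p = np.array(
        [
            [table.both, table.patient_only],
            [table.admin_only, table.neither],
        ],
        dtype=float,
    ) / n
    # rows: patient yes/no; cols: admin yes/no
    row = p.sum(axis=1)
    col = p.sum(axis=0)
    po = np.trace(p)
    pe = float(row @ col)
    term1 = sum(
        p[i, i] * ((1 - pe) - (row[i] + col[i]) * (1 - po)) ** 2 for i in range(2)
    )
    term2 = (1 - po) ** 2 * sum(
        p[i, j] * (col[i] + row[j]) ** 2
        for i in range(2)
        for j in range(2)
        if i != j
    )
    term3 = (po * pe - 2 * pe + po) ** 2
    return (term1 + term2 - term3) / (n * (1 - pe) ** 4)


def cohens_kappa(table: TwoByTwo, ci_level: float = 0.95) -> Estimate:
    """Cohen's kappa with an asymptotic CI.

    Undefined (with reason) when the expected agreement p_e equals 1, i.e.
    when both marginals are degenerate.
    """
    n = table.total
    po = (table.both + table.neither) / n
    pa = table.admin_prevalence
    pp = table.patient_prevalence
    pe = pa * pp + (1 - pa) * (1 - pp)
    if pe == 1.0:
        return Estimate(None, reason="degenerate marginals (expected agreement = 1)")
    kappa = (po - pe) / (1 - pe)
    from scipy.stats import norm

    z = norm.ppf(0.5 + ci_level / 2)
    se = math.sqrt(max(_kappa_variance(table), 0.0))
    return Estimate(
        kappa,
        float(np.clip(kappa - z * se, -1, 1)),
        float(np.clip(kappa + z * se, -1, 1)),
    )


def kappa_band(kappa: float) -> str:
    """Qualitative label for a kappa value: poor below 0.40, moderate on
    [0.40, 0.60], substantial on (0.60, 0.80], near perfect above 0.80
    (values in the conventional bands' unprinted gaps go to the upper band);
    negative values are 'poor'."""
    if not -1 <= kappa <= 1:
        raise ConfigurationError(f"kappa must be in [-1, 1], got {kappa}")
    if kappa < 0.40:
        return "poor agreement"
    if kappa <= 0.60:
        return "moderate agreement"
    if kappa <= 0.80:
        return "substantial agreement"
    return "near perfect agreement"


@dataclass(frozen=True)
class AgreementResult:
    """All agreement statistics for one condition."""

    condition: str
    table: TwoByTwo
    sensitivity: Estimate
    specificity: Estimate
    kappa: Estimate
    patient_prevalence: float
    admin_prevalence: float
    either_prevalence: float
    kappa_band: str | None


def evaluate_table(
    condition: str,
    table: TwoByTwo,
    ci_level: float = 0.95,
    ci_method: str = "wald",
) -> AgreementResult:
    """Compute the full agreement result from a 2×2 table. Marginal
    prevalences are recomputed from the cells."""
    sens, spec = sens_spec(table, ci_level, ci_method)
    kap = cohens_kappa(table, ci_level)
    return AgreementResult(
        condition=condition,
        table=table,
        sensitivity=sens,
        specificity=spec,
        kappa=kap,
        patient_prevalence=table.patient_prevalence,
        admin_prevalence=table.admin_prevalence,
        either_prevalence=table.either_prevalence,
        kappa_band=kappa_band(kap.value) if kap.defined else None,
    )


def _align(responses: pd.DataFrame, flags: pd.DataFrame):
    left = set(responses["patient_id"])
    right = set(flags["patient_id"])
    if left != right:
        raise AlignmentError(left - right, right - left)
    r = responses.set_index("patient_id").sort_index()
    f = flags.set_index("patient_id").sort_index()
    return r, f


def crosstab(responses: pd.DataFrame, flags: pd.DataFrame, condition: str) -> TwoByTwo:
    """Cross-tabulate patient report against the admin flag for one
    condition. Both frames carry ``patient_id`` plus one boolean/0-1 column
    per condition; patient sets must match exactly."""
    for frame, name in ((responses, "responses"), (flags, "flags")):
        if condition not in frame.columns:
            raise SchemaError(f"column {condition!r} missing from {name}")
    r, f = _align(responses, flags)
    pat = r[condition].astype(bool).to_numpy()
    adm = f[condition].astype(bool).to_numpy()
    return TwoByTwo(
        both=int(np.sum(pat & adm)),
        admin_only=int(np.sum(~pat & adm)),
        patient_only=int(np.sum(pat & ~adm)),
        neither=int(np.sum(~pat & ~adm)),
    )


def agreement_suite(
    responses: pd.DataFrame,
    flags: pd.DataFrame,
    conditions=None,
    ci_level: float = 0.95,
    ci_method: str = "wald",
) -> list[AgreementResult]:
    """One AgreementResult per condition. By default the eleven analysis
    conditions are used (arthritis excluded)."""
    if conditions is None:
        conditions = [c for c in ANALYSIS_CONDITIONS if c in responses.columns]
    return [
        evaluate_table(c, crosstab(responses, flags, c), ci_level, ci_method)
        for c in conditions
    ]


def results_to_frame(results: list[AgreementResult]) -> pd.DataFrame:
    """Machine-readable table of results at full precision (one row per
    condition, mirroring the published column layout)."""
    rows = []
    for r in results:
        t = r.table
        rows.append(
            {
                "condition": r.condition,
                "n": t.total,
                "patient_reported_n": t.n_patient_positive,
                "patient_reported_pct": 100 * r.patient_prevalence,
                "admin_n": t.n_admin_positive,
                "admin_pct": 100 * r.admin_prevalence,
                "either_n": t.both + t.admin_only + t.patient_only,
                "either_pct": 100 * r.either_prevalence,
                "both": t.both,
                "admin_only": t.admin_only,
                "patient_only": t.patient_only,
                "neither": t.neither,
                "sensitivity_pct": _pct(r.sensitivity.value),
                "sensitivity_ci_low_pct": _pct(r.sensitivity.ci_low),
                "sensitivity_ci_high_pct": _pct(r.sensitivity.ci_high),
                "specificity_pct": _pct(r.specificity.value),
                "specificity_ci_low_pct": _pct(r.specificity.ci_low),
                "specificity_ci_high_pct": _pct(r.specificity.ci_high),
                "kappa": r.kappa.value,
                "kappa_ci_low": r.kappa.ci_low,
                "kappa_ci_high": r.kappa.ci_high,
                "kappa_band": r.kappa_band,
            }
        )
    return pd.DataFrame(rows)


def _pct(x):
    return None if x is None else 100 * x


def format_result(r: AgreementResult) -> str:
    """Display form: percentages to 1 d.p., kappa to 2 d.p."""
    sens = (
        f"{100 * r.sensitivity.value:.1f}% "
        f"({100 * r.sensitivity.ci_low:.1f}, {100 * r.sensitivity.ci_high:.1f})"
        if r.sensitivity.defined
        else f"undefined ({r.sensitivity.reason})"
    )
    spec = (
        f"{100 * r.specificity.value:.1f}% "
        f"({100 * r.specificity.ci_low:.1f}, {100 * r.specificity.ci_high:.1f})"
        if r.specificity.defined
        else f"undefined ({r.specificity.reason})"
    )
    kap = (
        f"{r.kappa.value:.2f} ({r.kappa.ci_low:.2f}, {r.kappa.ci_high:.2f})"
        f" [{r.kappa_band}]"
        if r.kappa.defined
        else f"undefined ({r.kappa.reason})"
    )
    return (
        f"{r.condition}: sensitivity {sens}; specificity {spec}; kappa {kap}"
    )
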