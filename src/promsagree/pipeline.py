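"""End-to-end orchestration, table readers, and the from-counts entry point.

``run`` executes the whole analysis — simulate or ingest, build the cohort,
optionally backward-code the map, derive flags at each look-back, compute
agreement and subcategory outputs — and writes a manifest (config echo,
code-map checksum, file checksums) sufficient to re-run bit-identically.

``ingest_tables``/``from_counts`` evaluate published 2×2 contingency cells
directly, with no cohort data: this is how printed validation tables are
re-analysed. The package ships the published 1-year look-back cells of a
large English arthroplasty cohort (N = 676,428) as
``data/published_counts_1yr.csv``.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import pandas as pd

from . import __version__
from .agreement import (
    AgreementResult,
    TwoByTwo,
    agreement_suite,
    evaluate_table,
    results_to_frame,
)
from .codemap import CodeMap, audit_to_frame, backward_code, load_default_codemap
from .cohort import build_cohort
from .conditions import CONDITIONS
from .exceptions import SchemaError
from .flags import (
    LOOKBACK_1Y_DAYS,
    LOOKBACK_5Y_DAYS,
    LookbackSpec,
    derive_flags,
    flag_prevalence,
)
from .subcategory import forest_table, subcategory_sensitivity
from .synthetic import SimulationConfig, generate_cohort

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Readers (round-trip partners of synthetic.write_fixture)
# ---------------------------------------------------------------------------


def read_questionnaire(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"row_id": str, "patient_id": str, "procedure_link_id": str})
    missing = [c for c in ("row_id", "patient_id", "procedure_link_id") if c not in df.columns]
    if missing:
        raise SchemaError(f"questionnaire file is missing column(s) {missing}")
    return df


def read_admissions(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(
        path,
        dtype={"admission_id": str, "patient_id": str},
        keep_default_na=False,
        na_values=[""],
    )
    missing = [
        c
        for c in ("admission_id", "patient_id", "admission_day", "is_index_procedure")
        if c not in df.columns
    ]
    if missing:
        raise SchemaError(f"admissions file is missing column(s) {missing}")
    diag = [c for c in df.columns if c.startswith("diag_")]
    df[diag] = df[diag].fillna("")
    return df


def read_truth(path: str | Path) -> pd.DataFrame:
    payload = json.loads(Path(path).read_text())
    rows = [{"patient_id": pid, **status} for pid, status in payload.items()]
    return pd.DataFrame(rows)


def ingest_tables(path: str | Path) -> list[tuple[str, TwoByTwo]]:
    """Read per-condition 2×2 cells from a CSV with columns
    condition, both, admin_only, patient_only, neither."""
    df = pd.read_csv(path)
    required = ["condition", "both", "admin_only", "patient_only", "neither"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"counts file is missing column(s) {missing}")
    out = []
    for _, row in df.iterrows():
        out.append(
            (
                str(row["condition"]),
                TwoByTwo(
                    both=int(row["both"]),
                    admin_only=int(row["admin_only"]),
                    patient_only=int(row["patient_only"]),
                    neither=int(row["neither"]),
                ),
            )
        )
    return out


def published_counts_path() -> Path:
    """Path of the shipped published 1-year 2×2 cells."""
    return Path(str(resources.files("promsagree.data").joinpath("published_counts_1yr.csv")))


def from_counts(
    tables: list[tuple[str, TwoByTwo]],
    ci_level: float = 0.95,
    ci_method: str = "wald",
) -> list[AgreementResult]:
    """Agreement statistics straight from 2×2 cells."""
    return [evaluate_table(c, t, ci_level, ci_method) for c, t in tables]


# ---------------------------------------------------------------------------
# Full pipeline
# ---------------------------------------------------------------------------


@dataclass
class RunConfig:
    """Configuration of one end-to-end run.

    Either ``simulation`` (a SimulationConfig) or the three input paths must
    be provided.
    """

    output_dir: str | Path
    simulation: SimulationConfig | None = None
    questionnaire_path: str | Path | None = None
    admissions_path: str | Path | None = None
    codemap_path: str | Path | None = None
    lookback_days: tuple[int, ...] = (LOOKBACK_1Y_DAYS, LOOKBACK_5Y_DAYS)
    include_index: bool = True
    dedup: str = "drop-all"
    high_count_threshold: int = 7
    ci_level: float = 0.95
    ci_method: str = "wald"
    run_backward_coding: bool = False
    backward_lookback_days: int = LOOKBACK_1Y_DAYS
    seed: int = 0

    def __post_init__(self):
        if not self.lookback_days:
            raise SchemaError("at least one look-back window is required")
        has_sim = self.simulation is not None
        has_paths = self.questionnaire_path is not None and self.admissions_path is not None
        if not has_sim and not has_paths:
            raise SchemaError(
                "provide either a simulation config or questionnaire + admissions paths"
            )


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run(config: RunConfig) -> dict:
    """Execute the pipeline; returns the manifest (also written to disk)."""
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    if config.simulation is not None:
        questionnaire, admissions, _truth = generate_cohort(config.simulation)
    else:
        questionnaire = read_questionnaire(config.questionnaire_path)
        admissions = read_admissions(config.admissions_path)

    cmap = (
        CodeMap.from_json(config.codemap_path)
        if config.codemap_path
        else load_default_codemap()
    )

    cohort, admissions, report = build_cohort(
        questionnaire,
        admissions,
        threshold=config.high_count_threshold,
        dedup=config.dedup,
    )
    report.to_json(outdir / "exclusion_report.json")
    outputs = [outdir / "exclusion_report.json"]

    if config.run_backward_coding:
        audit_all = []
        bc_spec = LookbackSpec(config.backward_lookback_days, config.include_index)
        for cond in [c for c in CONDITIONS if c in cmap.conditions and c != "arthritis"]:
            cmap, audit = backward_code(cohort, admissions, cmap, cond, lookback=bc_spec)
            audit_all.extend(audit)
        audit_to_frame(audit_all).to_csv(outdir / "backward_coding_audit.csv", index=False)
        cmap.to_json(outdir / "codemap_augmented.json")
        outputs += [outdir / "backward_coding_audit.csv", outdir / "codemap_augmented.json"]

    responses = cohort[["patient_id", *[c for c in CONDITIONS if c in cohort.columns]]]

    for days in config.lookback_days:
        spec = LookbackSpec(days, config.include_index)
        flags = derive_flags(cohort, admissions, cmap, spec)
        tag = f"lookback{days}"
        flags.write(outdir / f"admin_flags_{tag}.csv", cmap.checksum())
        flag_prevalence(flags).to_csv(outdir / f"flag_prevalence_{tag}.csv", index=False)
        results = agreement_suite(
            responses, flags.frame, ci_level=config.ci_level, ci_method=config.ci_method
        )
        results_to_frame(results).to_csv(outdir / f"agreement_{tag}.csv", index=False)
        with open(outdir / f"agreement_{tag}.json", "w") as fh:
            json.dump(
                results_to_frame(results).to_dict(orient="records"), fh, indent=1
            )
        sub = subcategory_sensitivity(
            cohort, admissions, cmap, spec,
            conditions=[c for c in cmap.conditions if c != "arthritis" and c in cohort.columns],
            ci_level=config.ci_level, ci_method=config.ci_method,
        )
        forest_table(sub).to_csv(outdir / f"subcategory_sensitivity_{tag}.csv", index=False)
        outputs += [
            outdir / f"admin_flags_{tag}.csv",
            outdir / f"admin_flags_{tag}.json",
            outdir / f"flag_prevalence_{tag}.csv",
            outdir / f"agreement_{tag}.csv",
            outdir / f"agreement_{tag}.json",
            outdir / f"subcategory_sensitivity_{tag}.csv",
        ]

    manifest = {
        "package_version": __version__,
        "seed": config.seed,
        "codemap_sha256": cmap.checksum(),
        "config": _config_echo(config),
        "outputs": {str(p.name): _sha256(p) for p in outputs},
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest


def _config_echo(config: RunConfig) -> dict:
    def default(o):
        if dataclasses.is_dataclass(o):
            return dataclasses.asdict(o)
        return str(o)

    return json.loads(json.dumps(dataclasses.asdict(config), default=default))
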