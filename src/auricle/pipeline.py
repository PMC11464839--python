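"""End-to-end study orchestration from a single configuration.

``run_study`` chains ingest → drug-name normalization → case selection →
descriptive summaries → disproportionality screening → ranking, writing a
fixed artifact layout (CSV tables, reject logs, a JSON manifest of stage
counts) under the configured output directory.  Any stage failure aborts the
run, removes partial outputs and re-raises with the stage name attached.
"""

from __future__ import annotations

import json
import logging
import shutil
from pathlib import Path

import pandas as pd
import yaml
from pydantic import BaseModel, Field, ValidationError, field_validator

from . import case_selection, descriptive, ingest
from .disproportionality import CriteriaConfig, rank_signals, screen_drugs

__all__ = ["StudyConfig", "StudyError", "validate_config", "run_study"]

log = logging.getLogger("auricle.pipeline")


class StudyError(Exception):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


class RankingConfig(BaseModel):
    by: str = "ror"
    top_k: int = Field(default=50, ge=1)

    @field_validator("by")
    @classmethod
    def _v_by(cls, v):
        if v not in {"ror", "prr", "a"}:
            raise ValueError("ranking.by must be 'ror', 'prr' or 'a'")
        return v


class FilterBlock(BaseModel):
    report_types: list[str] = Field(default_factory=lambda: ["direct"])
    drug_roles: list[str] = Field(default_factory=lambda: ["primary_suspect"])
    require_outcome_serious: bool = False

    def to_filter_config(self) -> case_selection.FilterConfig:
        return case_selection.FilterConfig(
            report_types=frozenset(ingest.ReportType(t) for t in self.report_types),
            drug_roles=frozenset(ingest.DrugRole(r) for r in self.drug_roles),
            require_outcome_serious=self.require_outcome_serious,
        )


class CriteriaBlock(BaseModel):
    min_a: int = Field(default=3, ge=1)
    prr_threshold: float = 2.0
    chi2_threshold: float = 4.0
    haldane_correction: bool = False

    def to_criteria(self) -> CriteriaConfig:
        return CriteriaConfig(min_a=self.min_a, prr_threshold=self.prr_threshold,
                              chi2_threshold=self.chi2_threshold)


class StudyConfig(BaseModel):
    """Validated study configuration (YAML- or JSON-loadable)."""

    demo_path: str
    drug_path: str
    reac_path: str
    outc_path: str
    dialect: str = "faers"
    termset_path: str | None = None
    synonym_map_path: str | None = None
    filters: FilterBlock = Field(default_factory=FilterBlock)
    criteria: CriteriaBlock = Field(default_factory=CriteriaBlock)
    ranking: RankingConfig = Field(default_factory=RankingConfig)
    deduplicate: bool = False
    out_dir: str = "study_out"
    seed: int = 0
    log_level: str = "INFO"


def validate_config(path: str | Path) -> StudyConfig:
    """Load and validate a config file; missing optional fields get the
    study defaults (direct-only, primary-suspect-only, min_a=3, top_k=50).

    Raises ``ValueError`` listing every failing field path, including input
    files that do not exist.
    """
    doc = yaml.safe_load(Path(path).read_text())
    try:
        cfg = StudyConfig.model_validate(doc or {})
    except ValidationError as exc:
        issues = "; ".join(
            ".".join(str(p) for p in e["loc"]) + ": " + e["msg"]
            for e in exc.errors()
        )
        raise ValueError(f"invalid study config: {issues}") from exc
    missing = [
        name for name in ("demo_path", "drug_path", "reac_path", "outc_path")
        if not Path(getattr(cfg, name)).exists()
    ]
    for name in ("termset_path", "synonym_map_path"):
        v = getattr(cfg, name)
        if v is not None and not Path(v).exists():
            missing.append(name)
    if missing:
        raise ValueError(
            "invalid study config: missing input files for " + ", ".join(missing)
        )
    return cfg


def run_study(config: StudyConfig) -> dict:
    """Execute the full pipeline; returns the manifest (also written as JSON).

    The manifest records counts at every stage (reports read, after the type
    filter, cases, drugs screened, signals) plus the artifact paths.  If no
    cases survive the filters the run exits gracefully with status
    ``no cases`` and writes no signal table.
    """
    out = Path(config.out_dir)
    created = not out.exists()
    out.mkdir(parents=True, exist_ok=True)
    stage = "setup"
    try:
        stage = "ingest"
        report_set = ingest.read_reports(
            config.demo_path, config.drug_path, config.reac_path,
            config.outc_path, config.dialect,
        )
        report_set.write_quarantine_log(out / "quarantine.csv")
        if config.deduplicate:
            report_set = ingest.deduplicate_cases(report_set)

        stage = "normalize"
        synonym_map = case_selection.load_synonym_map(config.synonym_map_path)
        report_set, dropped = case_selection.normalize_drugs(report_set, synonym_map)
        pd.DataFrame(dropped, columns=["report_id", "raw_name", "reason"]).to_csv(
            out / "dropped_drugs.csv", index=False
        )

        stage = "select"
        termset = case_selection.load_termset(config.termset_path)
        filters = config.filters.to_filter_config()
        case_set = case_selection.select_cases(report_set, termset, filters)

        manifest: dict = {
            "status": "ok",
            "counts": {
                "demo_rows_read": report_set.provenance.get("demo_rows_read"),
                "reports_linked": len(report_set.reports),
                "universe": len(case_set.universe),
                "cases": len(case_set.cases),
            },
            "termset": termset.name,
            "artifacts": {
                "quarantine": "quarantine.csv",
                "dropped_drugs": "dropped_drugs.csv",
            },
        }

        stage = "describe"
        if case_set.cases:
            for var in ("sex", "age_band", "reporter", "country", "outcomes"):
                tab = descriptive.tabulate(case_set.cases, var)
                tab.to_frame().to_csv(out / f"table_{var}.csv", index=False)
                manifest["artifacts"][f"table_{var}"] = f"table_{var}.csv"
            series = descriptive.yearly_counts(case_set.cases)
            series.to_frame().to_csv(out / "yearly_counts.csv", index=False)
            manifest["artifacts"]["yearly_counts"] = "yearly_counts.csv"
            onsets = [descriptive.time_to_onset(r) for r in case_set.cases]
            onsets = [o for o in onsets if o is not None]
            if onsets:
                q = descriptive.median_iqr(onsets)
                manifest["time_to_onset_days"] = {
                    "median": q.median, "q1": q.q1, "q3": q.q3,
                    "n": q.n_nonmissing,
                }

        stage = "signal"
        if not case_set.cases:
            manifest["status"] = "no cases"
            manifest["counts"]["drugs_screened"] = 0
            manifest["counts"]["signals"] = 0
        else:
            criteria = config.criteria.to_criteria()
            stats_list, skipped = screen_drugs(
                case_set, criteria, correction=config.criteria.haldane_correction
            )
            ranked = rank_signals(stats_list, by=config.ranking.by,
                                  top_k=config.ranking.top_k)
            df = pd.DataFrame([
                {
                    "generic_name": s.drug, "a": s.a,
                    "ROR": round(s.ror, 2),
                    "ROR_CI_low": round(s.ror_ci[0], 2),
                    "ROR_CI_high": round(s.ror_ci[1], 2),
                    "PRR": round(s.prr, 2),
                    "PRR_CI_low": round(s.prr_ci[0], 2),
                    "PRR_CI_high": round(s.prr_ci[1], 2),
                    "chi2": round(s.chi2, 2),
                    "ror_criterion": s.flags.ror_criterion,
                    "prr_criterion": s.flags.prr_criterion,
                    "headline_signal": s.flags.headline_signal,
                }
                for s in ranked
            ])
            df.to_csv(out / "signals.csv", index=False)
            manifest["artifacts"]["signals"] = "signals.csv"
            if skipped:
                pd.DataFrame(skipped).to_csv(out / "skipped_drugs.csv", index=False)
                manifest["artifacts"]["skipped_drugs"] = "skipped_drugs.csv"
            manifest["counts"]["drugs_screened"] = len(stats_list) + len(skipped)
            manifest["counts"]["signals"] = int(sum(
                s.flags.headline_signal for s in stats_list
            ))

        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2)
        return manifest
    except Exception as exc:
        # remove partial outputs: the whole directory if we created it,
        # else just the files written during this run
        if created:
            shutil.rmtree(out, ignore_errors=True)
        else:
            for p in out.glob("*.csv"):
                p.unlink(missing_ok=True)
            (out / "manifest.json").unlink(missing_ok=True)
        if isinstance(exc, StudyError):
            raise
        raise StudyError(stage, exc) from exc
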