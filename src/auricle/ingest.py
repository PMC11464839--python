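"""Reading, writing and linking of FAERS-style multi-table report files.

A spontaneous-report extract is stored as four delimited tables sharing a
report identifier, mirroring the FAERS quarterly-file layout:

* a demographics table (one row per report: patient, reporter and
  administrative fields),
* a drug table (one row per drug mention, with a suspect-role code),
* a reaction table (one row per MedDRA Preferred-Term reaction),
* an outcome table (one row per outcome code).

:func:`read_reports` joins the four tables into linked :class:`SafetyReport`
records.  Rows that cannot be parsed, and demographics rows left without any
drug or any reaction after linking, are *quarantined* — recorded with their
table, line number and reason — rather than silently dropped, so that every
input row is accounted for: ``len(reports) + len(quarantined demographics
rows) == demographics rows read``.

The counting unit throughout the package is the ICSR (individual case safety
report): one report is one adverse-event record.  FAERS-style case versioning
(several reports sharing a ``case_id``) is supported via
:func:`deduplicate_cases`, which keeps the highest version per case; it is
not applied automatically.
"""

from __future__ import annotations

import csv
import datetime as _dt
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

__all__ = [
    "ReportType",
    "Sex",
    "Reporter",
    "DrugRole",
    "OutcomeCode",
    "DrugMention",
    "ReactionMention",
    "SafetyReport",
    "QuarantinedRow",
    "ReportSet",
    "Dialect",
    "DIALECTS",
    "IngestError",
    "read_reports",
    "write_reports",
    "deduplicate_cases",
]


class IngestError(Exception):
    """Unrecoverable ingest failure (unreadable file, duplicate report id)."""


class ReportType(str, Enum):
    DIRECT = "direct"
    EXPEDITED = "expedited"
    PERIODIC = "periodic"
    UNKNOWN = "unknown"


class Sex(str, Enum):
    FEMALE = "female"
    MALE = "male"
    UNKNOWN = "unknown"


class Reporter(str, Enum):
    PHYSICIAN = "physician"
    PHARMACIST = "pharmacist"
    OTHER_HEALTH_PROFESSIONAL = "other-health-professional"
    CONSUMER = "consumer"
    LAWYER = "lawyer"
    UNKNOWN = "unknown"


class DrugRole(str, Enum):
    PRIMARY_SUSPECT = "primary_suspect"
    SECONDARY_SUSPECT = "secondary_suspect"
    CONCOMITANT = "concomitant"
    INTERACTING = "interacting"


class OutcomeCode(str, Enum):
    CONGENITAL_ANOMALY = "congenital_anomaly"
    HOSPITALIZATION = "hospitalization"
    DEATH = "death"
    DISABILITY = "disability"
    LIFE_THREATENING = "life_threatening"
    REQUIRED_INTERVENTION = "required_intervention"
    OTHER_SERIOUS = "other_serious"


@dataclass(slots=True)
class DrugMention:
    """One drug row of a report: raw (as-reported) name, resolved generic,
    suspect-role code and optional therapy start date."""

    raw_name: str
    generic_name: str | None = None
    role: DrugRole = DrugRole.PRIMARY_SUSPECT
    start_date: _dt.date | None = None

    def __post_init__(self) -> None:
        if not self.raw_name:
            raise ValueError("raw_name must be non-empty")


@dataclass(slots=True)
class ReactionMention:
    """One MedDRA Preferred-Term reaction, optionally with its numeric code
    and the date the event occurred."""

    pt_name: str
    pt_code: int | None = None
    event_date: _dt.date | None = None

    def __post_init__(self) -> None:
        if not self.pt_name:
            raise ValueError("pt_name must be non-empty")
        if self.pt_code is not None and self.pt_code <= 0:
            raise ValueError("pt_code must be positive when present")


@dataclass(slots=True)
class SafetyReport:
    """One linked ICSR: demographics plus its drug mentions, reactions and
    outcome codes."""

    report_id: str
    case_id: str
    version: int = 1
    report_type: ReportType = ReportType.UNKNOWN
    receipt_date: _dt.date | None = None
    sex: Sex = Sex.UNKNOWN
    age_years: float | None = None
    weight_kg: float | None = None
    country: str | None = None
    reporter: Reporter = Reporter.UNKNOWN
    outcomes: frozenset[OutcomeCode] = field(default_factory=frozenset)
    drugs: list[DrugMention] = field(default_factory=list)
    reactions: list[ReactionMention] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.version < 1:
            raise ValueError("version must be >= 1")
        if self.age_years is not None and self.age_years < 0:
            raise ValueError("age_years must be non-negative")
        if self.weight_kg is not None and self.weight_kg <= 0:
            raise ValueError("weight_kg must be positive")


@dataclass(slots=True, frozen=True)
class QuarantinedRow:
    table: str
    line: int  # 1-based physical line in the source file; 0 if synthesized
    report_id: str
    reason: str


@dataclass(slots=True)
class ReportSet:
    """A collection of linked reports plus ingest provenance."""

    reports: list[SafetyReport]
    provenance: dict = field(default_factory=dict)
    quarantined: list[QuarantinedRow] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [r.report_id for r in self.reports]
        if len(ids) != len(set(ids)):
            raise IngestError("duplicate report_id within ReportSet")

    def __len__(self) -> int:
        return len(self.reports)

    def write_quarantine_log(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["table", "line", "report_id", "reason"])
            for q in self.quarantined:
                w.writerow([q.table, q.line, q.report_id, q.reason])


# ---------------------------------------------------------------------------
# dialects

@dataclass(frozen=True, slots=True)
class Dialect:
    """Delimited-text conventions for the four tables.

    FAERS raw quarterly files are ``$``-delimited with ``YYYYMMDD`` dates;
    the ``csv`` preset uses commas and ISO-8601 dates.
    """

    name: str
    delimiter: str
    date_format: str  # strftime/strptime pattern
    encoding: str = "utf-8"

    def format_date(self, d: _dt.date | None) -> str:
        return "" if d is None else d.strftime(self.date_format)

    def parse_date(self, s: str) -> _dt.date | None:
        if not s:
            return None
        return _dt.datetime.strptime(s, self.date_format).date()


DIALECTS: dict[str, Dialect] = {
    "faers": Dialect("faers", "$", "%Y%m%d"),
    "csv": Dialect("csv", ",", "%Y-%m-%d"),
}


def _resolve_dialect(dialect: str | Dialect) -> Dialect:
    if isinstance(dialect, Dialect):
        return dialect
    try:
        return DIALECTS[dialect]
    except KeyError:
        raise IngestError(
            f"unknown dialect {dialect!r}; registered: {sorted(DIALECTS)}"
        ) from None


# ---------------------------------------------------------------------------
# table schemas

DEMO_COLUMNS = [
    "report_id", "case_id", "version", "report_type", "receipt_date",
    "sex", "age_years", "weight_kg", "country", "reporter",
]
DRUG_COLUMNS = ["report_id", "drug_seq", "raw_name", "generic_name", "role", "start_date"]
REAC_COLUMNS = ["report_id", "pt_name", "pt_code", "event_date"]
OUTC_COLUMNS = ["report_id", "outcome_code"]

TABLE_FILENAMES = {"demo": "DEMO.txt", "drug": "DRUG.txt", "reac": "REAC.txt", "outc": "OUTC.txt"}


def _read_rows(path: str | Path, dialect: Dialect, columns: Sequence[str], table: str):
    """Yield (line_number, dict) for each data row; validate the header."""
    try:
        fh = open(path, "r", encoding=dialect.encoding, newline="")
    except OSError as exc:
        raise IngestError(f"cannot read {table} table {path}: {exc}") from exc
    with fh:
        reader = csv.reader(fh, delimiter=dialect.delimiter)
        try:
            header = next(reader)
        except StopIteration:
            raise IngestError(f"{table} table {path} is empty (missing header)")
        if [h.strip() for h in header] != list(columns):
            raise IngestError(
                f"{table} table {path} header mismatch: got {header}, expected {list(columns)}"
            )
        for lineno, row in enumerate(reader, start=2):
            if not row or all(not f.strip() for f in row):
                continue
            yield lineno, dict(zip(columns, (f.strip() for f in row))), row


def _opt_float(s: str) -> float | None:
    return None if s == "" else float(s)


def _opt_int(s: str) -> int | None:
    return None if s == "" else int(s)


def read_reports(
    demo_path: str | Path,
    drug_path: str | Path,
    reac_path: str | Path,
    outc_path: str | Path,
    dialect: str | Dialect = "faers",
) -> ReportSet:
    """Read the four tables and assemble linked :class:`SafetyReport` records.

    Reports missing a drug or a reaction, and rows that fail to parse, are
    quarantined with a reason; a duplicate ``report_id`` in the demographics
    table is a hard error.  Output reports are ordered by ``report_id``.
    """
    dia = _resolve_dialect(dialect)
    quarantined: list[QuarantinedRow] = []
    bad_report_ids: set[str] = set()

    demo_rows: dict[str, dict] = {}
    n_demo_rows = 0
    for lineno, rec, _raw in _read_rows(demo_path, dia, DEMO_COLUMNS, "demo"):
        n_demo_rows += 1
        rid = rec["report_id"]
        if rid in demo_rows or rid in bad_report_ids:
            raise IngestError(
                f"duplicate report_id {rid!r} in demographics table (line {lineno})"
            )
        try:
            parsed = {
                "report_id": rid,
                "case_id": rec["case_id"] or rid,
                "version": int(rec["version"]) if rec["version"] else 1,
                "report_type": ReportType(rec["report_type"] or "unknown"),
                "receipt_date": dia.parse_date(rec["receipt_date"]),
                "sex": Sex(rec["sex"] or "unknown"),
                "age_years": _opt_float(rec["age_years"]),
                "weight_kg": _opt_float(rec["weight_kg"]),
                "country": rec["country"] or None,
                "reporter": Reporter(rec["reporter"] or "unknown"),
            }
            if parsed["version"] < 1:
                raise ValueError("version < 1")
            a = parsed["age_years"]
            if a is not None and a < 0:
                raise ValueError("negative age_years")
            w = parsed["weight_kg"]
            if w is not None and w <= 0:
                raise ValueError("non-positive weight_kg")
        except (ValueError, KeyError) as exc:
            quarantined.append(QuarantinedRow("demo", lineno, rid, f"unparseable: {exc}"))
            bad_report_ids.add(rid)
            continue
        parsed["_line"] = lineno
        demo_rows[rid] = parsed

    drugs: dict[str, list[tuple[int, DrugMention]]] = {}
    for lineno, rec, _raw in _read_rows(drug_path, dia, DRUG_COLUMNS, "drug"):
        rid = rec["report_id"]
        try:
            m = DrugMention(
                raw_name=rec["raw_name"],
                generic_name=rec["generic_name"] or None,
                role=DrugRole(rec["role"]),
                start_date=dia.parse_date(rec["start_date"]),
            )
            seq = int(rec["drug_seq"]) if rec["drug_seq"] else 0
        except ValueError as exc:
            quarantined.append(QuarantinedRow("drug", lineno, rid, f"unparseable: {exc}"))
            continue
        drugs.setdefault(rid, []).append((seq, m))

    reactions: dict[str, list[ReactionMention]] = {}
    for lineno, rec, _raw in _read_rows(reac_path, dia, REAC_COLUMNS, "reac"):
        rid = rec["report_id"]
        try:
            m = ReactionMention(
                pt_name=rec["pt_name"],
                pt_code=_opt_int(rec["pt_code"]),
                event_date=dia.parse_date(rec["event_date"]),
            )
        except ValueError as exc:
            quarantined.append(QuarantinedRow("reac", lineno, rid, f"unparseable: {exc}"))
            continue
        reactions.setdefault(rid, []).append(m)

    outcomes: dict[str, set[OutcomeCode]] = {}
    for lineno, rec, _raw in _read_rows(outc_path, dia, OUTC_COLUMNS, "outc"):
        rid = rec["report_id"]
        try:
            code = OutcomeCode(rec["outcome_code"])
        except ValueError as exc:
            quarantined.append(QuarantinedRow("outc", lineno, rid, f"unparseable: {exc}"))
            continue
        outcomes.setdefault(rid, set()).add(code)

    # orphan child rows (no demographics row) are logged but do not affect
    # the demographics-row conservation count
    for table, mapping in (("drug", drugs), ("reac", reactions), ("outc", outcomes)):
        for rid in sorted(set(mapping) - set(demo_rows) - bad_report_ids):
            quarantined.append(QuarantinedRow(table, 0, rid, "orphan row: no demographics row"))

    reports: list[SafetyReport] = []
    for rid in sorted(demo_rows):
        rec = demo_rows[rid]
        line = rec.pop("_line")
        dms = [m for _, m in sorted(drugs.get(rid, []), key=lambda t: t[0])]
        rms = reactions.get(rid, [])
        if not dms:
            quarantined.append(QuarantinedRow("demo", line, rid, "no drugs"))
            continue
        if not rms:
            quarantined.append(QuarantinedRow("demo", line, rid, "no reactions"))
            continue
        reports.append(
            SafetyReport(
                drugs=dms,
                reactions=rms,
                outcomes=frozenset(outcomes.get(rid, set())),
                **rec,
            )
        )

    provenance = {
        "demo_path": str(demo_path),
        "drug_path": str(drug_path),
        "reac_path": str(reac_path),
        "outc_path": str(outc_path),
        "dialect": dia.name,
        "demo_rows_read": n_demo_rows,
        "reports_linked": len(reports),
        "demo_rows_quarantined": n_demo_rows - len(reports),
    }
    return ReportSet(reports=reports, provenance=provenance, quarantined=quarantined)


def write_reports(
    report_set: ReportSet,
    out_dir: str | Path,
    dialect: str | Dialect = "faers",
    overwrite: bool = False,
) -> dict[str, Path]:
    """Emit the four tables for ``report_set`` under ``out_dir``.

    The output is the exact inverse of :func:`read_reports`: reading the four
    files back yields a field-for-field identical ReportSet (reports sorted
    by ``report_id``).  Existing files raise unless ``overwrite`` is set.
    """
    dia = _resolve_dialect(dialect)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {t: out / fn for t, fn in TABLE_FILENAMES.items()}
    if not overwrite:
        clashes = [p for p in paths.values() if p.exists()]
        if clashes:
            raise IngestError(
                f"refusing to overwrite existing files: {[str(p) for p in clashes]}"
            )

    def fmt_opt(v) -> str:
        return "" if v is None else str(v)

    reports = sorted(report_set.reports, key=lambda r: r.report_id)
    with open(paths["demo"], "w", encoding=dia.encoding, newline="") as fh:
        w = csv.writer(fh, delimiter=dia.delimiter)
        w.writerow(DEMO_COLUMNS)
        for r in reports:
            w.writerow([
                r.report_id, r.case_id, r.version, r.report_type.value,
                dia.format_date(r.receipt_date), r.sex.value,
                fmt_opt(r.age_years), fmt_opt(r.weight_kg),
                fmt_opt(r.country), r.reporter.value,
            ])
    with open(paths["drug"], "w", encoding=dia.encoding, newline="") as fh:
        w = csv.writer(fh, delimiter=dia.delimiter)
        w.writerow(DRUG_COLUMNS)
        for r in reports:
            for seq, m in enumerate(r.drugs, start=1):
                w.writerow([
                    r.report_id, seq, m.raw_name, fmt_opt(m.generic_name),
                    m.role.value, dia.format_date(m.start_date),
                ])
    with open(paths["reac"], "w", encoding=dia.encoding, newline="") as fh:
        w = csv.writer(fh, delimiter=dia.delimiter)
        w.writerow(REAC_COLUMNS)
        for r in reports:
            for m in r.reactions:
                w.writerow([
                    r.report_id, m.pt_name, fmt_opt(m.pt_code),
                    dia.format_date(m.event_date),
                ])
    with open(paths["outc"], "w", encoding=dia.encoding, newline="") as fh:
        w = csv.writer(fh, delimiter=dia.delimiter)
        w.writerow(OUTC_COLUMNS)
        for r in reports:
            for code in sorted(r.outcomes, key=lambda c: c.value):
                w.writerow([r.report_id, code.value])
    return paths


def deduplicate_cases(report_set: ReportSet) -> ReportSet:
    """Keep only the highest-version report per ``case_id``.

    Ties on version are broken by report_id (the lexically last wins), making
    the operation deterministic and idempotent.  The number of removed
    reports is recorded in the provenance.
    """
    best: dict[str, SafetyReport] = {}
    for r in report_set.reports:
        cur = best.get(r.case_id)
        if cur is None or (r.version, r.report_id) > (cur.version, cur.report_id):
            best[r.case_id] = r
    kept = sorted(best.values(), key=lambda r: r.report_id)
    provenance = dict(report_set.provenance)
    provenance["dedup_removed"] = len(report_set.reports) - len(kept)
    return ReportSet(reports=kept, provenance=provenance,
                     quarantined=list(report_set.quarantined))
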