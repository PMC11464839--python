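"""Case definition and report-level filtering.

A *case* is a report carrying at least one reaction whose Preferred Term
belongs to the event term set (here, by default, the ten congenital
external-ear anomaly PTs).  The *universe* is the set of reports passing the
report-level filters — by default direct-type reports with a primary-suspect
drug — and serves as the denominator for all disproportionality statistics.

Matching is by PT name primarily (case-insensitive); a numeric PT code match
is accepted as an alternative when both the reaction and the term-set entry
carry a code.  Names are authoritative because printed code lists in the
wild are unreliable.

Drug names are normalized to generic names through a many-to-one synonym map
(brand → generic), standing in for a registry lookup; mentions whose raw
name has no mapping are removed and logged, mirroring the manual elimination
of unresolvable names.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path

import yaml

from .ingest import DrugRole, ReportSet, ReportType, SafetyReport

__all__ = [
    "TermSet",
    "FilterConfig",
    "SynonymMap",
    "CaseSet",
    "load_termset",
    "load_synonym_map",
    "match_event",
    "normalize_drugs",
    "select_cases",
    "CaseSelectionError",
]

_DATA = resources.files("auricle.data")


class CaseSelectionError(Exception):
    pass


@dataclass(frozen=True, slots=True)
class TermSet:
    """A named set of MedDRA PT entries defining the event of interest."""

    name: str
    pt_entries: tuple[tuple[str, int | None], ...]

    def __post_init__(self) -> None:
        if not self.pt_entries:
            raise CaseSelectionError("term set must be non-empty")
        folded = [n.casefold() for n, _ in self.pt_entries]
        if len(set(folded)) != len(folded):
            raise CaseSelectionError("duplicate PT names (case-insensitive) in term set")

    @property
    def names_folded(self) -> frozenset[str]:
        return frozenset(n.casefold() for n, _ in self.pt_entries)

    @property
    def codes(self) -> frozenset[int]:
        return frozenset(c for _, c in self.pt_entries if c is not None)


@dataclass(frozen=True, slots=True)
class FilterConfig:
    """Report-level selection: admissible report types, drug roles counted as
    exposure, and an optional requirement that the report carry any serious
    outcome code."""

    report_types: frozenset[ReportType] = frozenset({ReportType.DIRECT})
    drug_roles: frozenset[DrugRole] = frozenset({DrugRole.PRIMARY_SUSPECT})
    require_outcome_serious: bool = False

    def __post_init__(self) -> None:
        if not self.report_types:
            raise CaseSelectionError("report_types must be non-empty")
        if not self.drug_roles:
            raise CaseSelectionError("drug_roles must be non-empty")


ALL_REPORT_TYPES = frozenset(ReportType)


class SynonymMap:
    """Case-folded many-to-one mapping from raw/brand names to generic names.

    Every generic name appearing as a value is also accepted as a key, so
    already-generic raw names resolve to themselves.
    """

    def __init__(self, mapping: dict[str, str]):
        self._map: dict[str, str] = {}
        for raw, generic in mapping.items():
            generic = generic.strip().casefold()
            if not generic:
                raise CaseSelectionError(f"empty generic name for {raw!r}")
            self._map[raw.strip().casefold()] = generic
        for generic in list(self._map.values()):
            self._map.setdefault(generic, generic)

    def get(self, raw_name: str) -> str | None:
        return self._map.get(raw_name.strip().casefold())

    def __len__(self) -> int:
        return len(self._map)

    @property
    def generics(self) -> frozenset[str]:
        return frozenset(self._map.values())


@dataclass(slots=True)
class CaseSet:
    """Event-positive reports (cases) inside their filtered universe."""

    cases: list[SafetyReport]
    universe: list[SafetyReport]
    termset: TermSet
    filters: FilterConfig
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        case_ids = {r.report_id for r in self.cases}
        uni_ids = {r.report_id for r in self.universe}
        if not case_ids <= uni_ids:
            raise CaseSelectionError("cases must be a subset of the universe")

    @property
    def case_ids(self) -> frozenset[str]:
        return frozenset(r.report_id for r in self.cases)


def load_termset(config_path: str | Path | None = None) -> TermSet:
    """Load a term set from YAML; with no path, return the bundled default
    ten-PT congenital external-ear anomaly set."""
    if config_path is None:
        text = (_DATA / "termset_external_ear.yaml").read_text()
    else:
        text = Path(config_path).read_text()
    doc = yaml.safe_load(text)
    entries = tuple(
        (e["pt_name"], e.get("pt_code")) for e in doc.get("pt_entries", [])
    )
    return TermSet(name=doc.get("name", "unnamed"), pt_entries=entries)


def load_synonym_map(csv_path: str | Path | None = None) -> SynonymMap:
    """Load a brand→generic synonym CSV; defaults to the bundled map."""
    if csv_path is None:
        text = (_DATA / "drug_synonyms.csv").read_text()
    else:
        text = Path(csv_path).read_text()
    reader = csv.DictReader(text.splitlines())
    mapping = {row["raw_name"]: row["generic_name"] for row in reader}
    return SynonymMap(mapping)


def match_event(report: SafetyReport, termset: TermSet) -> bool:
    """True iff any reaction PT matches the term set by name
    (case-insensitive) or, when both sides carry codes, by code."""
    names = termset.names_folded
    codes = termset.codes
    for m in report.reactions:
        if m.pt_name.casefold() in names:
            return True
        if m.pt_code is not None and m.pt_code in codes:
            return True
    return False


def normalize_drugs(
    report_set: ReportSet, synonym_map: SynonymMap
) -> tuple[ReportSet, list[dict]]:
    """Resolve each drug mention's generic name through the synonym map.

    Mentions whose raw name has no mapping are removed and logged; reports
    left with no drug mentions are removed and logged.  Applying the map
    twice is a no-op (generic names map to themselves).
    """
    dropped: list[dict] = []
    out_reports: list[SafetyReport] = []
    for r in report_set.reports:
        kept: list = []
        for m in r.drugs:
            generic = synonym_map.get(m.raw_name)
            if generic is None:
                dropped.append({
                    "report_id": r.report_id, "raw_name": m.raw_name,
                    "reason": "no synonym-map entry",
                })
                continue
            kept.append(replace(m, generic_name=generic))
        if not kept:
            dropped.append({
                "report_id": r.report_id, "raw_name": "",
                "reason": "all drug mentions unresolved",
            })
            continue
        out_reports.append(replace(r, drugs=kept))
    provenance = dict(report_set.provenance)
    provenance["normalize_dropped_mentions"] = sum(1 for d in dropped if d["raw_name"])
    provenance["normalize_dropped_reports"] = sum(1 for d in dropped if not d["raw_name"])
    return (
        ReportSet(reports=out_reports, provenance=provenance,
                  quarantined=list(report_set.quarantined)),
        dropped,
    )


def _passes_filters(r: SafetyReport, filters: FilterConfig) -> bool:
    if r.report_type not in filters.report_types:
        return False
    if filters.require_outcome_serious and not r.outcomes:
        return False
    return True


def select_cases(
    report_set: ReportSet, termset: TermSet, filters: FilterConfig | None = None
) -> CaseSet:
    """Apply the case definition and report-level filters.

    The universe is every report passing the report-type (and optional
    serious-outcome) filter; cases are universe reports that additionally
    carry at least one drug in an admissible role and match the event term
    set.  An empty universe is an error — the denominator would be undefined.
    """
    filters = filters or FilterConfig()
    universe = [r for r in report_set.reports if _passes_filters(r, filters)]
    if not universe:
        raise CaseSelectionError("empty universe after filters: denominator undefined")
    roles = filters.drug_roles
    cases = [
        r for r in universe
        if any(m.role in roles for m in r.drugs) and match_event(r, termset)
    ]
    provenance = {
        "reports_in": len(report_set.reports),
        "universe": len(universe),
        "cases": len(cases),
        "termset": termset.name,
    }
    return CaseSet(cases=cases, universe=universe, termset=termset,
                   filters=filters, provenance=provenance)
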