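"""Synthetic spontaneous-report generator with known ground truth.

Generates FAERS-like :class:`~auricle.ingest.ReportSet` collections in which
every drug–event association is planted and therefore known exactly:

* each report receives one primary-suspect drug drawn from a drug marginal
  (optionally plus a concomitant mention, for role-filter testing);
* each event PT occurs independently with its background probability,
  multiplied by a configurable rate ratio when an injected (drug, event)
  signal matches (capped at 1) — so the reporting odds ratio approaches the
  rate ratio when the event is rare;
* demographics (sex, age, weight, country, reporter, report type, outcome
  codes) are drawn from configurable strata mixes whose defaults mirror the
  clinical profile of a congenital external-ear anomaly case series:
  overwhelmingly infants under 1 year, birth weight around a 2.75 kg median,
  onset-gap around a 273-day median (first-trimester exposure reported at
  birth);
* event dates precede receipt dates by a uniform reporting delay, and drug
  start dates precede event dates by the lognormal onset gap, so the
  time-to-onset of a generated report equals its drawn gap.

Closed-form expected 2×2 cells under this model are provided by
:func:`expected_table`, and :func:`recovery_experiment` runs the full
generate → select → screen pipeline repeatedly to measure the operating
characteristics (sensitivity, false-positive rate) of a criteria set.

Determinism: all randomness flows through one ``numpy`` Generator seeded
from ``params.seed``; identical params give identical reports, and
:func:`recovery_experiment` derives one child seed per replicate.
"""

from __future__ import annotations

import datetime as _dt
import math
from dataclasses import dataclass, field as _dc_field
from typing import Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, field_validator, model_validator
from scipy.stats import binomtest

from .case_selection import ALL_REPORT_TYPES, FilterConfig, TermSet, select_cases
from .disproportionality import (
    CriteriaConfig,
    ZeroCellError,
    build_table,
    compute_signal_stats,
)
from .ingest import (
    DrugMention,
    DrugRole,
    OutcomeCode,
    ReactionMention,
    Reporter,
    ReportSet,
    ReportType,
    SafetyReport,
    Sex,
)

__all__ = [
    "DrugSpec",
    "EventSpec",
    "SignalSpec",
    "LogNormalSpec",
    "SimulationParams",
    "GroundTruth",
    "generate",
    "expected_table",
    "recovery_experiment",
    "RecoveryReport",
]

#: PT assigned to reports that drew no event, keeping reactions non-empty.
#: Deliberately outside any bundled term set.
FILLER_PT = "Drug ineffective"

_MIX_TOL = 1e-9


class DrugSpec(BaseModel):
    generic: str
    brand: str = ""
    background_prob: float = Field(gt=0.0, le=1.0)


class EventSpec(BaseModel):
    pt_name: str
    background_prob: float = Field(ge=0.0, le=1.0)


class SignalSpec(BaseModel):
    generic: str
    pt_name: str
    rate_ratio: float = Field(gt=0.0)


class LogNormalSpec(BaseModel):
    """Lognormal with its location given as the median (exp of the log-mean)."""

    median: float = Field(gt=0.0)
    sigma: float = Field(gt=0.0)
    missing_frac: float = Field(default=0.0, ge=0.0, le=1.0)


def _check_mix(name: str, mix: dict) -> dict:
    total = sum(mix.values())
    if abs(total - 1.0) > _MIX_TOL:
        raise ValueError(f"{name} probabilities must sum to 1 (got {total!r})")
    if any(p < 0 for p in mix.values()):
        raise ValueError(f"{name} probabilities must be non-negative")
    return mix


class SimulationParams(BaseModel):
    """Full specification of one synthetic report collection.

    Defaults describe a plausible spontaneous-report background: a small
    drug roster dominated by common analgesics with a few teratogenic-signal
    candidates, rare congenital-ear event PTs against common background PTs,
    and demographic strata matching an infant case series.
    """

    n_reports: int = Field(default=10_000, ge=1)
    drugs: list[DrugSpec] = Field(default_factory=lambda: [
        DrugSpec(generic="primidone", brand="Mysoline", background_prob=0.002),
        DrugSpec(generic="valproic acid", brand="Depakene", background_prob=0.01),
        DrugSpec(generic="nevirapine", brand="Viramune", background_prob=0.005),
        DrugSpec(generic="isotretinoin", brand="Accutane", background_prob=0.008),
        DrugSpec(generic="paracetamol", brand="Tylenol", background_prob=0.4),
        DrugSpec(generic="ibuprofen", brand="", background_prob=0.3),
        DrugSpec(generic="metformin", brand="Glucophage", background_prob=0.175),
        DrugSpec(generic="gabapentin", brand="Neurontin", background_prob=0.1),
    ])
    events: list[EventSpec] = Field(default_factory=lambda: [
        EventSpec(pt_name="Microtia", background_prob=0.0005),
        EventSpec(pt_name="Anotia", background_prob=0.0002),
        EventSpec(pt_name="Accessory auricle", background_prob=0.0003),
        EventSpec(pt_name="Pyrexia", background_prob=0.05),
        EventSpec(pt_name="Nausea", background_prob=0.08),
        EventSpec(pt_name="Headache", background_prob=0.06),
    ])
    signals: list[SignalSpec] = Field(default_factory=lambda: [
        SignalSpec(generic="valproic acid", pt_name="Microtia", rate_ratio=40.0),
        SignalSpec(generic="isotretinoin", pt_name="Anotia", rate_ratio=30.0),
    ])
    report_type_mix: dict[str, float] = Field(default_factory=lambda: {
        "direct": 0.6, "expedited": 0.3, "periodic": 0.1,
    })
    sex_mix: dict[str, float] = Field(default_factory=lambda: {
        "female": 0.3469, "male": 0.4232, "unknown": 0.2299,
    })
    age_band_mix: dict[str, float] = Field(default_factory=lambda: {
        "<1": 0.8830, "1-4": 0.0078, "4-10": 0.0113, ">=10": 0.0374,
        "unknown": 0.0605,
    })
    reporter_mix: dict[str, float] = Field(default_factory=lambda: {
        "other-health-professional": 0.3744, "physician": 0.2919,
        "consumer": 0.1278, "unknown": 0.0985, "pharmacist": 0.0763,
        "lawyer": 0.0311,
    })
    country_mix: dict[str, float] = Field(default_factory=lambda: {
        "Other": 0.5594, "United States": 0.1544, "Germany": 0.1145,
        "France": 0.0763, "United Kingdom": 0.0488, "Denmark": 0.0466,
    })
    outcome_mix: dict[str, float] = Field(default_factory=lambda: {
        "congenital_anomaly": 0.4772, "other_serious": 0.2958,
        "hospitalization": 0.1030, "death": 0.0684, "disability": 0.0318,
        "life_threatening": 0.0228, "required_intervention": 0.0010,
    })
    weight_distribution: LogNormalSpec = Field(
        default_factory=lambda: LogNormalSpec(median=2.75, sigma=0.333, missing_frac=0.3)
    )
    onset_gap_distribution: LogNormalSpec = Field(
        default_factory=lambda: LogNormalSpec(median=273.0, sigma=0.61)
    )
    year_range: tuple[int, int] = (2004, 2024)
    year_weights: dict[int, float] | None = None
    concomitant_rate: float = Field(default=0.0, ge=0.0, le=1.0)
    seed: int = 0

    @field_validator("report_type_mix")
    @classmethod
    def _v_rt(cls, v):
        _check_mix("report_type_mix", v)
        for k in v:
            ReportType(k)
        return v

    @field_validator("sex_mix")
    @classmethod
    def _v_sex(cls, v):
        _check_mix("sex_mix", v)
        for k in v:
            Sex(k)
        return v

    @field_validator("age_band_mix")
    @classmethod
    def _v_age(cls, v):
        return _check_mix("age_band_mix", v)

    @field_validator("reporter_mix")
    @classmethod
    def _v_rep(cls, v):
        _check_mix("reporter_mix", v)
        for k in v:
            Reporter(k)
        return v

    @field_validator("country_mix")
    @classmethod
    def _v_cty(cls, v):
        return _check_mix("country_mix", v)

    @field_validator("outcome_mix")
    @classmethod
    def _v_out(cls, v):
        _check_mix("outcome_mix", v)
        for k in v:
            if k != "none":
                OutcomeCode(k)
        return v

    @model_validator(mode="after")
    def _v_model(self):
        total = sum(d.background_prob for d in self.drugs)
        if abs(total - 1.0) > _MIX_TOL:
            raise ValueError(
                f"drug background probabilities form the suspect-drug marginal "
                f"and must sum to 1 (got {total!r})"
            )
        generics = {d.generic for d in self.drugs}
        if len(generics) != len(self.drugs):
            raise ValueError("duplicate generic names in drug roster")
        pts = {e.pt_name for e in self.events}
        if len(pts) != len(self.events):
            raise ValueError("duplicate PT names in event roster")
        for s in self.signals:
            if s.generic not in generics:
                raise ValueError(f"signal drug {s.generic!r} not in drug roster")
            if s.pt_name not in pts:
                raise ValueError(f"signal event {s.pt_name!r} not in event roster")
        y0, y1 = self.year_range
        if y0 > y1:
            raise ValueError("year_range must be (first, last) with first <= last")
        if self.year_weights is not None:
            if set(self.year_weights) != set(range(y0, y1 + 1)):
                raise ValueError("year_weights keys must cover year_range exactly")
            _check_mix("year_weights", self.year_weights)
        return self


@dataclass(slots=True)
class GroundTruth:
    """Planted structure of one generated collection."""

    params: SimulationParams
    drug_index: np.ndarray          # (n,) index into params.drugs
    event_matrix: np.ndarray        # (n, n_events) bool occurrence
    report_ids: list[str]
    expected_cells: dict[tuple[str, str], tuple[float, float, float, float]]

    def report_ids_with_event(self, pt_name: str) -> frozenset[str]:
        j = [e.pt_name for e in self.params.events].index(pt_name)
        idx = np.flatnonzero(self.event_matrix[:, j])
        return frozenset(self.report_ids[i] for i in idx)

    def report_ids_with_drug(self, generic: str) -> frozenset[str]:
        k = [d.generic for d in self.params.drugs].index(generic)
        idx = np.flatnonzero(self.drug_index == k)
        return frozenset(self.report_ids[i] for i in idx)


def _event_prob(params: SimulationParams, generic: str, pt_name: str) -> float:
    base = next(e.background_prob for e in params.events if e.pt_name == pt_name)
    for s in params.signals:
        if s.generic == generic and s.pt_name == pt_name:
            return min(base * s.rate_ratio, 1.0)
    return base


def expected_table(
    params: SimulationParams,
    drug: str,
    event: str,
    report_types: Sequence[str] | None = None,
) -> tuple[float, float, float, float]:
    """Closed-form expected (a, b, c, d) for one pair under the model.

    With ``report_types`` given, expectations refer to the sub-universe of
    those report types (type is independent of drug and event, so cells
    scale by the selected type mass).
    """
    generics = [d.generic for d in params.drugs]
    pts = [e.pt_name for e in params.events]
    if drug not in generics:
        raise KeyError(f"unknown drug {drug!r}")
    if event not in pts:
        raise KeyError(f"unknown event {event!r}")
    n = params.n_reports
    if report_types is not None:
        n = n * sum(params.report_type_mix.get(t, 0.0) for t in set(report_types))
    p_drug = {d.generic: d.background_prob for d in params.drugs}
    a = n * p_drug[drug] * _event_prob(params, drug, event)
    a_plus_b = n * sum(p_drug[g] * _event_prob(params, g, event) for g in generics)
    b = a_plus_b - a
    c = n * p_drug[drug] - a
    d = n - a - b - c
    return (a, b, c, d)


_EPOCH_CACHE: dict[int, int] = {}


def _year_ordinal(year: int) -> int:
    if year not in _EPOCH_CACHE:
        _EPOCH_CACHE[year] = _dt.date(year, 1, 1).toordinal()
    return _EPOCH_CACHE[year]


def generate(params: SimulationParams) -> tuple[ReportSet, GroundTruth]:
    """Draw one synthetic ReportSet; fully reproducible from ``params.seed``."""
    rng = np.random.default_rng(params.seed)
    n = params.n_reports
    drugs = params.drugs
    events = params.events

    drug_probs = np.array([d.background_prob for d in drugs])
    drug_idx = rng.choice(len(drugs), size=n, p=drug_probs / drug_probs.sum())

    # per-event occurrence, signal-modified per drug
    occ = np.zeros((n, len(events)), dtype=bool)
    for j, ev in enumerate(events):
        pe = np.full(n, ev.background_prob)
        for s in params.signals:
            if s.pt_name == ev.pt_name:
                k = next(i for i, d in enumerate(drugs) if d.generic == s.generic)
                pe[drug_idx == k] = min(ev.background_prob * s.rate_ratio, 1.0)
        occ[:, j] = rng.random(n) < pe

    def draw_mix(mix: dict[str, float]) -> np.ndarray:
        keys = list(mix)
        probs = np.array([mix[k] for k in keys], dtype=float)
        idx = rng.choice(len(keys), size=n, p=probs / probs.sum())
        return np.array(keys, dtype=object)[idx]

    rtype = draw_mix(params.report_type_mix)
    sex = draw_mix(params.sex_mix)
    band = draw_mix(params.age_band_mix)
    reporter = draw_mix(params.reporter_mix)
    country = draw_mix(params.country_mix)
    outcome = draw_mix(params.outcome_mix)

    u_age = rng.random(n)
    band_lo = {"<1": 0.0, "1-4": 1.0, "4-10": 4.0, ">=10": 10.0}
    band_hi = {"<1": 1.0, "1-4": 4.0, "4-10": 10.0, ">=10": 60.0}
    wspec = params.weight_distribution
    weight = rng.lognormal(math.log(wspec.median), wspec.sigma, size=n)
    weight_missing = rng.random(n) < wspec.missing_frac

    gspec = params.onset_gap_distribution
    gap = np.maximum(np.rint(rng.lognormal(math.log(gspec.median), gspec.sigma, size=n)), 0).astype(int)
    delay = rng.integers(0, 61, size=n)

    y0, y1 = params.year_range
    years = np.arange(y0, y1 + 1)
    if params.year_weights is None:
        yw = np.full(len(years), 1.0 / len(years))
    else:
        yw = np.array([params.year_weights[y] for y in years])
    ry = years[rng.choice(len(years), size=n, p=yw / yw.sum())]
    rday = rng.integers(0, 365, size=n)  # day 365 avoided: safe in all years
    receipt_ord = np.array([_year_ordinal(y) for y in ry]) + rday

    conc = rng.random(n) < params.concomitant_rate
    conc_idx = rng.choice(len(drugs), size=n, p=drug_probs / drug_probs.sum())

    pt_names = [e.pt_name for e in events]
    reports: list[SafetyReport] = []
    report_ids: list[str] = []
    for i in range(n):
        rid = f"R{i:08d}"
        report_ids.append(rid)
        receipt = _dt.date.fromordinal(int(receipt_ord[i]))
        event_date = _dt.date.fromordinal(int(receipt_ord[i] - delay[i]))
        start_date = _dt.date.fromordinal(int(receipt_ord[i] - delay[i] - gap[i]))
        spec = drugs[drug_idx[i]]
        mentions = [DrugMention(
            raw_name=spec.brand or spec.generic,
            generic_name=spec.generic,
            role=DrugRole.PRIMARY_SUSPECT,
            start_date=start_date,
        )]
        if conc[i]:
            cspec = drugs[conc_idx[i]]
            mentions.append(DrugMention(
                raw_name=cspec.brand or cspec.generic,
                generic_name=cspec.generic,
                role=DrugRole.CONCOMITANT,
                start_date=None,
            ))
        hits = np.flatnonzero(occ[i])
        if hits.size:
            reactions = [
                ReactionMention(pt_name=pt_names[j], event_date=event_date)
                for j in hits
            ]
        else:
            reactions = [ReactionMention(pt_name=FILLER_PT, event_date=event_date)]
        b = band[i]
        if b == "unknown":
            age = None
        else:
            lo, hi = band_lo[b], band_hi[b]
            age = float(lo + (hi - lo) * u_age[i])
        reports.append(SafetyReport(
            report_id=rid,
            case_id=rid,
            version=1,
            report_type=ReportType(rtype[i]),
            receipt_date=receipt,
            sex=Sex(sex[i]),
            age_years=age,
            weight_kg=None if weight_missing[i] else round(float(weight[i]), 2),
            country=None if country[i] == "unknown" else str(country[i]),
            reporter=Reporter(reporter[i]),
            outcomes=frozenset() if outcome[i] == "none"
            else frozenset({OutcomeCode(outcome[i])}),
            drugs=mentions,
            reactions=reactions,
        ))

    expected = {
        (d.generic, e.pt_name): expected_table(params, d.generic, e.pt_name)
        for d in drugs for e in events
    }
    truth = GroundTruth(
        params=params, drug_index=drug_idx, event_matrix=occ,
        report_ids=report_ids, expected_cells=expected,
    )
    report_set = ReportSet(
        reports=reports,
        provenance={"source": "auricle.synthetic", "seed": params.seed,
                    "n_reports": n},
    )
    return report_set, truth


@dataclass(slots=True)
class RecoveryReport:
    """Operating characteristics of a criteria set over simulated replicates."""

    replicates: pd.DataFrame  # rep, drug, event, kind, a, flagged
    summary: dict = _dc_field(default_factory=dict)


def _wilson_ci(k: int, n: int) -> tuple[float, float]:
    ci = binomtest(k, n).proportion_ci(confidence_level=0.95, method="wilson")
    return (float(ci.low), float(ci.high))


def recovery_experiment(
    params: SimulationParams,
    criteria: CriteriaConfig | None = None,
    n_reps: int = 50,
    base_seed: int | None = None,
    null_pairs: Sequence[tuple[str, str]] | None = None,
    min_expected_a: float = 3.0,
) -> RecoveryReport:
    """Measure sensitivity and false-positive rate of the headline signal
    rule by repeated generate → select → screen runs.

    Injected pairs are ``params.signals``; null pairs default to every
    non-signal (drug, event) pair whose expected case cell is at least
    ``min_expected_a`` (so the a ≥ 3 gate is reachable under the null).
    Each replicate uses a seed derived deterministically from ``base_seed``
    (default ``params.seed``).
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    criteria = criteria or CriteriaConfig()
    base = params.seed if base_seed is None else base_seed

    injected = [(s.generic, s.pt_name) for s in params.signals]
    if null_pairs is None:
        null_pairs = [
            (d.generic, e.pt_name)
            for d in params.drugs for e in params.events
            if (d.generic, e.pt_name) not in injected
            and expected_table(params, d.generic, e.pt_name)[0] >= min_expected_a
        ]
    pairs = [(g, p, "injected") for g, p in injected] + [
        (g, p, "null") for g, p in null_pairs
    ]
    filt = FilterConfig(report_types=ALL_REPORT_TYPES)

    rows = []
    for rep in range(n_reps):
        seed = (base * 1_000_003 + rep) % (2**31 - 1)
        rep_params = params.model_copy(update={"seed": seed})
        report_set, _truth = generate(rep_params)
        by_event: dict[str, frozenset[str]] = {}
        for generic, pt, kind in pairs:
            if pt not in by_event:
                termset = TermSet(name=pt, pt_entries=((pt, None),))
                by_event[pt] = select_cases(report_set, termset, filt).case_ids
            case_ids = by_event[pt]
            table = build_table(report_set.reports, case_ids, generic,
                                filt.drug_roles)
            try:
                stats = compute_signal_stats(table, criteria)
                flagged = stats.flags.headline_signal
            except ZeroCellError:
                flagged = False
            rows.append({
                "rep": rep, "seed": seed, "drug": generic, "event": pt,
                "kind": kind, "a": table.a, "flagged": flagged,
            })
    df = pd.DataFrame(rows)

    summary: dict = {"n_reps": n_reps}
    inj = df[df["kind"] == "injected"]
    if len(inj):
        k, m = int(inj["flagged"].sum()), len(inj)
        summary["sensitivity"] = k / m
        summary["sensitivity_ci"] = _wilson_ci(k, m)
    nul = df[df["kind"] == "null"]
    if len(nul):
        k, m = int(nul["flagged"].sum()), len(nul)
        summary["false_positive_rate"] = k / m
        summary["false_positive_ci"] = _wilson_ci(k, m)
    return RecoveryReport(replicates=df, summary=summary)
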