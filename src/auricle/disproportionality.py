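"""Report-level 2×2 contingency tables and disproportionality statistics.

For one drug–event pair the universe of reports is cross-classified as

=============  ==================  ======================
               event of interest   all other events
=============  ==================  ======================
drug           a                   c
other drugs    b                   d
=============  ==================  ======================

with each report counted at most once per cell regardless of repeated
mentions.  The two frequentist signal statistics computed here are the
reporting odds ratio and the proportional reporting ratio,

    ROR = ad / (bc),        PRR = a(c+d) / (c(a+b)),

with log-scale Wald 95% confidence intervals

    exp( ln ROR ± 1.96·√(1/a + 1/b + 1/c + 1/d) )
    exp( ln PRR ± 1.96·√(1/a + 1/c − 1/(a+b) − 1/(c+d)) )

and the (uncorrected) Pearson chi-squared statistic

    χ² = (ad − bc)² · n / ((a+b)(c+d)(a+c)(b+d)),   n = a+b+c+d.

Three criteria sets are evaluated per drug:

* ROR criterion: lower 95% ROR CI bound > 1 and a ≥ 3;
* PRR criterion: PRR ≥ 2, χ² ≥ 4 and a ≥ 3;
* headline signal rule: lower 95% PRR CI bound > 1 and a ≥ 3.

Zero cells make ROR/PRR undefined; an optional Haldane–Anscombe correction
(+0.5 to every cell) is available but off by default.  No multiplicity
adjustment is applied; see the package docs for the implications.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .case_selection import CaseSet
from .ingest import DrugRole, SafetyReport

__all__ = [
    "ContingencyTable",
    "SignalFlags",
    "SignalStats",
    "CriteriaConfig",
    "ZeroCellError",
    "build_table",
    "ror_stats",
    "prr_stats",
    "chi_square",
    "evaluate_signal",
    "compute_signal_stats",
    "screen_drugs",
    "rank_signals",
]

Z95 = 1.96  # normal quantile used for all 95% Wald intervals


class ZeroCellError(ValueError):
    """A statistic is undefined because a required cell or margin is zero."""


@dataclass(frozen=True, slots=True)
class ContingencyTable:
    """The four report counts for one (drug, event-set) pair.

    Cells are non-negative; real-valued cells are allowed so that tables
    recovered by algebraic inversion of rounded published statistics can be
    evaluated with the same code path.
    """

    drug: str
    a: float
    b: float
    c: float
    d: float
    policy: str = "report-level"

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency cells must be non-negative")

    @property
    def n(self) -> float:
        return self.a + self.b + self.c + self.d

    def corrected(self, continuity: float = 0.5) -> "ContingencyTable":
        """Haldane–Anscombe continuity correction: add ``continuity`` to
        every cell."""
        return ContingencyTable(
            self.drug, self.a + continuity, self.b + continuity,
            self.c + continuity, self.d + continuity,
            policy=self.policy + f"+haldane{continuity}",
        )


@dataclass(frozen=True, slots=True)
class SignalFlags:
    ror_criterion: bool
    prr_criterion: bool
    headline_signal: bool


@dataclass(frozen=True, slots=True)
class SignalStats:
    """All disproportionality outputs for one drug."""

    drug: str
    a: float
    ror: float
    ror_ci: tuple[float, float]
    prr: float
    prr_ci: tuple[float, float]
    chi2: float
    flags: SignalFlags | None = None


@dataclass(frozen=True, slots=True)
class CriteriaConfig:
    """Thresholds for the three criteria sets; ``min_a`` gates all of them."""

    min_a: int = 3
    prr_threshold: float = 2.0
    chi2_threshold: float = 4.0

    def __post_init__(self) -> None:
        if self.min_a < 1:
            raise ValueError("min_a must be >= 1")


def build_table(
    universe: Sequence[SafetyReport],
    cases: Sequence[SafetyReport] | frozenset[str],
    drug: str,
    role_filter: Iterable[DrugRole] = (DrugRole.PRIMARY_SUSPECT,),
) -> ContingencyTable:
    """Count the 2×2 cells for ``drug`` against the case set.

    ``cases`` may be the case reports themselves or their report-id set;
    cases must be a subset of ``universe``.  A drug absent from the universe
    yields a = c = 0 (legal; downstream statistics will refuse it unless a
    continuity correction is applied).
    """
    if isinstance(cases, (frozenset, set)):
        case_ids = frozenset(cases)
    else:
        case_ids = frozenset(r.report_id for r in cases)
    roles = frozenset(role_filter)
    drug_folded = drug.casefold()
    a = b = c = d = 0
    for r in universe:
        has_drug = any(
            m.role in roles and m.generic_name is not None
            and m.generic_name.casefold() == drug_folded
            for m in r.drugs
        )
        is_case = r.report_id in case_ids
        if has_drug and is_case:
            a += 1
        elif has_drug:
            c += 1
        elif is_case:
            b += 1
        else:
            d += 1
    return ContingencyTable(drug=drug, a=a, b=b, c=c, d=d)


def _check_positive(table: ContingencyTable, cells: dict[str, float]) -> None:
    zero = [k for k, v in cells.items() if v <= 0]
    if zero:
        raise ZeroCellError(
            f"statistic undefined for {table.drug!r}: zero cell(s)/margin(s) "
            f"{zero}; enable the Haldane-Anscombe correction or widen the data"
        )


def ror_stats(table: ContingencyTable, correction: bool = False) -> tuple[float, float, float]:
    """Reporting odds ratio with its 95% Wald CI: ``(ror, ci_low, ci_high)``."""
    t = table.corrected() if correction else table
    _check_positive(t, {"a": t.a, "b": t.b, "c": t.c, "d": t.d})
    ror = (t.a * t.d) / (t.b * t.c)
    se = math.sqrt(1 / t.a + 1 / t.b + 1 / t.c + 1 / t.d)
    return ror, ror * math.exp(-Z95 * se), ror * math.exp(Z95 * se)


def prr_stats(table: ContingencyTable, correction: bool = False) -> tuple[float, float, float]:
    """Proportional reporting ratio with its 95% log-scale Wald CI."""
    t = table.corrected() if correction else table
    _check_positive(t, {"a": t.a, "c": t.c, "a+b": t.a + t.b, "c+d": t.c + t.d})
    prr = (t.a * (t.c + t.d)) / (t.c * (t.a + t.b))
    var = 1 / t.a + 1 / t.c - 1 / (t.a + t.b) - 1 / (t.c + t.d)
    se = math.sqrt(max(var, 0.0))
    return prr, prr * math.exp(-Z95 * se), prr * math.exp(Z95 * se)


def chi_square(table: ContingencyTable) -> float:
    """Pearson chi-squared on the 2×2 table, no Yates correction."""
    a, b, c, d = table.a, table.b, table.c, table.d
    _check_positive(table, {"a+b": a + b, "c+d": c + d, "a+c": a + c, "b+d": b + d})
    n = a + b + c + d
    return (a * d - b * c) ** 2 * n / ((a + b) * (c + d) * (a + c) * (b + d))


def evaluate_signal(stats: SignalStats, criteria: CriteriaConfig | None = None) -> SignalFlags:
    """Apply the three criteria sets to computed statistics."""
    cfg = criteria or CriteriaConfig()
    gate = stats.a >= cfg.min_a
    return SignalFlags(
        ror_criterion=gate and stats.ror_ci[0] > 1.0,
        prr_criterion=gate and stats.prr >= cfg.prr_threshold
        and stats.chi2 >= cfg.chi2_threshold,
        headline_signal=gate and stats.prr_ci[0] > 1.0,
    )


def compute_signal_stats(
    table: ContingencyTable,
    criteria: CriteriaConfig | None = None,
    correction: bool = False,
) -> SignalStats:
    """ROR, PRR, CIs, χ² and criteria flags for one table."""
    ror, rlo, rhi = ror_stats(table, correction=correction)
    prr, plo, phi = prr_stats(table, correction=correction)
    x2 = chi_square(table.corrected() if correction else table)
    stats = SignalStats(
        drug=table.drug, a=table.a, ror=ror, ror_ci=(rlo, rhi),
        prr=prr, prr_ci=(plo, phi), chi2=x2,
    )
    flags = evaluate_signal(stats, criteria)
    return SignalStats(
        drug=stats.drug, a=stats.a, ror=stats.ror, ror_ci=stats.ror_ci,
        prr=stats.prr, prr_ci=stats.prr_ci, chi2=stats.chi2, flags=flags,
    )


def screen_drugs(
    case_set: CaseSet,
    criteria: CriteriaConfig | None = None,
    correction: bool = False,
    drugs: Iterable[str] | None = None,
) -> tuple[list[SignalStats], list[dict]]:
    """Compute signal statistics for every candidate drug in a case set.

    Candidates default to all generic names appearing among the cases in an
    admissible role.  Drugs whose table has a zero cell (with the correction
    disabled) are skipped and reported in the second return value.
    """
    roles = case_set.filters.drug_roles
    if drugs is None:
        names = sorted({
            m.generic_name
            for r in case_set.cases
            for m in r.drugs
            if m.role in roles and m.generic_name
        })
    else:
        names = sorted(set(drugs))
    case_ids = case_set.case_ids
    out: list[SignalStats] = []
    skipped: list[dict] = []
    for name in names:
        table = build_table(case_set.universe, case_ids, name, roles)
        try:
            out.append(compute_signal_stats(table, criteria, correction=correction))
        except ZeroCellError as exc:
            skipped.append({
                "drug": name, "a": table.a, "b": table.b,
                "c": table.c, "d": table.d, "reason": str(exc),
            })
    return out, skipped


def rank_signals(
    stats_list: Sequence[SignalStats],
    by: str = "ror",
    top_k: int | None = None,
) -> list[SignalStats]:
    """Stable descending sort by ``ror``, ``prr`` or ``a``; ties broken by
    larger case count, then drug name."""
    if by not in {"ror", "prr", "a"}:
        raise ValueError(f"rank key must be 'ror', 'prr' or 'a', got {by!r}")
    ranked = sorted(
        stats_list,
        key=lambda s: (-getattr(s, by), -s.a, s.drug),
    )
    return ranked[:top_k] if top_k is not None else ranked
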