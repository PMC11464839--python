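"""Algebraic recovery of unpublished 2×2 cells from published statistics.

Published disproportionality tables print, per drug, only the case count
``a``, the ROR, the PRR (each with a CI) and χ² — not the remaining cells
``b`` (event reports without the drug), ``c`` (drug reports without the
event) and ``d``.  Given the total report count ``N``, the pair of defining
equations

    ROR = a·d / (b·c)
    PRR = a·(c + d) / (c·(a + b))

determines (b, c, d = N − a − b − c) up to the rounding of the printed
statistics.  This module solves that system, evaluates the full statistics
on the recovered cells, and compares them with the printed values — turning
a published table into a validation surface for the statistics engine: a row
whose printed χ² or CI bounds cannot be reproduced from its own (a, ROR,
PRR, N) is internally inconsistent.

Cells are recovered as positive *reals* (a continuous relaxation): the
printed ROR/PRR are rounded to two decimals, so exact integer recovery is
ill-posed.  Nearest-integer cells are reported alongside.

The system is solved exactly.  Eliminating ``c`` via the PRR equation,

    c(b) = a·(N − a − b) / (PRR·(a + b)),

gives d(b)/c(b) = (PRR·(a + b) − a)/a, so the ROR equation collapses to a
*linear* equation in ``b``:

    ROR = (PRR·(a + b) − a) / b    ⟹    b = a·(PRR − 1) / (ROR − PRR).

A positive solution exists iff PRR − 1 and ROR − PRR share a sign (true for
every genuine 2×2 table, where sign(ROR − PRR) = sign(ad − bc) =
sign(PRR − 1)); ROR = PRR leaves ``b`` unidentified.  Plug-back residuals
against the printed pair are reported either way.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import pandas as pd

from .disproportionality import (
    ContingencyTable,
    SignalStats,
    compute_signal_stats,
)

__all__ = [
    "DEFAULT_N",
    "PublishedRow",
    "InversionResult",
    "solve_latent_cells",
    "predict_stats",
    "consistency_report",
    "load_published_rows",
]

#: Default total report count for the study window (Q1 2004 – Q1 2024
#: analysis denominator).
DEFAULT_N = 20_754_281

RESIDUAL_TOL = 1e-6


@dataclass(frozen=True, slots=True)
class PublishedRow:
    """One printed row of a published signal table."""

    name: str
    a: int
    ror: float
    ror_ci: tuple[float, float]
    prr: float
    prr_ci: tuple[float, float]
    chi2: float
    brand: str = ""

    def __post_init__(self) -> None:
        if self.a < 1:
            raise ValueError("a must be >= 1")
        if self.ror <= 0 or self.prr <= 0:
            raise ValueError("ror and prr must be positive")
        if not (self.ror_ci[0] < self.ror_ci[1] and self.prr_ci[0] < self.prr_ci[1]):
            raise ValueError("CI bounds out of order")


@dataclass(frozen=True, slots=True)
class InversionResult:
    """Recovered latent cells and plug-back diagnostics for one row."""

    a: float
    b: float
    c: float
    d: float
    residual_ror: float
    residual_prr: float
    converged: bool
    predicted: SignalStats | None  # None when not converged
    message: str = ""

    @property
    def nearest_integer_cells(self) -> tuple[int, int, int, int]:
        return (round(self.a), round(self.b), round(self.c), round(self.d))


def _failed(a: float, msg: str) -> InversionResult:
    return InversionResult(
        a=a, b=math.nan, c=math.nan, d=math.nan,
        residual_ror=math.inf, residual_prr=math.inf,
        converged=False, predicted=None, message=msg,
    )


def solve_latent_cells(
    a: float, ror: float, prr: float, N: float = DEFAULT_N
) -> InversionResult:
    """Recover (b, c, d) from a printed (a, ROR, PRR) and the total N.

    Returns a non-converged result with diagnostics — never raises — when
    the printed row admits no positive solution.
    """
    if a < 1 or ror <= 0 or prr <= 0 or N <= a:
        return _failed(a, "invalid inputs: need a >= 1, ror, prr > 0, N > a")
    if ror == prr:
        return _failed(a, "ROR equals PRR: b is not identifiable")
    b = a * (prr - 1.0) / (ror - prr)
    if b <= 0:
        return _failed(
            a, "no positive solution: PRR - 1 and ROR - PRR have opposite signs"
        )
    if b >= N - a:
        return _failed(a, "no positive solution: recovered b exceeds N - a")
    c = a * (N - a - b) / (prr * (a + b))
    d = N - a - b - c
    if min(c, d) <= 0:
        return _failed(a, "solution has a non-positive cell")

    ror_hat = a * d / (b * c)
    prr_hat = a * (c + d) / (c * (a + b))
    res_ror = abs(ror_hat - ror) / ror
    res_prr = abs(prr_hat - prr) / prr
    converged = res_ror < RESIDUAL_TOL and res_prr < RESIDUAL_TOL
    predicted = predict_stats(a, b, c, d) if converged else None
    return InversionResult(
        a=a, b=b, c=c, d=d,
        residual_ror=res_ror, residual_prr=res_prr,
        converged=converged, predicted=predicted,
        message="" if converged else "plug-back residual above tolerance",
    )


def predict_stats(a: float, b: float, c: float, d: float) -> SignalStats:
    """Evaluate ROR, PRR, CIs and χ² on (possibly non-integer) cells, via the
    same code path as the forward statistics engine."""
    if min(a, b, c, d) <= 0:
        raise ValueError("all cells must be positive")
    return compute_signal_stats(ContingencyTable("inverted", a, b, c, d,
                                                 policy="inverted-real"))


def load_published_rows(csv_path: str | Path | None = None) -> list[PublishedRow]:
    """Load a published signal table from CSV; defaults to the bundled
    transcription of the congenital external-ear anomaly top-drugs table."""
    if csv_path is None:
        text = (resources.files("auricle.data") / "published_signal_table.csv").read_text()
    else:
        text = Path(csv_path).read_text()
    rows = []
    for rec in csv.DictReader(text.splitlines()):
        rows.append(PublishedRow(
            name=rec["generic_name"],
            brand=rec.get("brand_name", ""),
            a=int(rec["a"]),
            ror=float(rec["ror"]),
            ror_ci=(float(rec["ror_ci_low"]), float(rec["ror_ci_high"])),
            prr=float(rec["prr"]),
            prr_ci=(float(rec["prr_ci_low"]), float(rec["prr_ci_high"])),
            chi2=float(rec["chi2"]),
        ))
    return rows


def consistency_report(
    published_rows: list[PublishedRow],
    N: float = DEFAULT_N,
    tolerance: float = 0.01,
) -> pd.DataFrame:
    """Invert every row and compare predicted χ² and ROR CI bounds with the
    printed values.

    Returns one row per input with recovered cells, relative errors and a
    ``consistent`` flag (every comparison within ``tolerance`` relative
    error).  Rows that fail to invert are marked non-converged and
    inconsistent.
    """
    records = []
    for row in published_rows:
        inv = solve_latent_cells(row.a, row.ror, row.prr, N)
        rec = {
            "name": row.name, "brand": row.brand, "a": row.a,
            "converged": inv.converged,
            "b": inv.b, "c": inv.c, "d": inv.d,
            "residual_ror": inv.residual_ror,
            "residual_prr": inv.residual_prr,
            "printed_chi2": row.chi2,
            "predicted_chi2": math.nan,
            "chi2_rel_err": math.inf,
            "chi2_ratio": math.nan,
            "predicted_ror_ci_low": math.nan,
            "predicted_ror_ci_high": math.nan,
            "ror_ci_low_rel_err": math.inf,
            "ror_ci_high_rel_err": math.inf,
            "consistent": False,
            "message": inv.message,
        }
        if inv.converged and inv.predicted is not None:
            p = inv.predicted
            rec["predicted_chi2"] = p.chi2
            rec["chi2_rel_err"] = abs(p.chi2 - row.chi2) / row.chi2
            rec["chi2_ratio"] = p.chi2 / row.chi2
            rec["predicted_ror_ci_low"] = p.ror_ci[0]
            rec["predicted_ror_ci_high"] = p.ror_ci[1]
            rec["ror_ci_low_rel_err"] = abs(p.ror_ci[0] - row.ror_ci[0]) / row.ror_ci[0]
            rec["ror_ci_high_rel_err"] = abs(p.ror_ci[1] - row.ror_ci[1]) / row.ror_ci[1]
            rec["consistent"] = (
                rec["chi2_rel_err"] <= tolerance
                and rec["ror_ci_low_rel_err"] <= tolerance
                and rec["ror_ci_high_rel_err"] <= tolerance
            )
        records.append(rec)
    return pd.DataFrame.from_records(records)
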