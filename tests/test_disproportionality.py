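"""2x2 construction and ROR/PRR/chi-squared against independent oracles."""

import math
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import chi2_contingency
from statsmodels.stats.contingency_tables import Table2x2

from auricle.case_selection import TermSet, FilterConfig, ALL_REPORT_TYPES, select_cases
from auricle.disproportionality import (
    ContingencyTable,
    CriteriaConfig,
    SignalFlags,
    SignalStats,
    ZeroCellError,
    build_table,
    chi_square,
    compute_signal_stats,
    evaluate_signal,
    prr_stats,
    rank_signals,
    ror_stats,
)
from auricle.ingest import DrugRole
from auricle.synthetic import SimulationParams, generate

from conftest import make_report, make_report_set


def _tab(a, b, c, d, drug="drugX"):
    return ContingencyTable(drug, a, b, c, d)


class TestBuildTable:
    def test_hand_enumerable_universe(self):
        """10 reports; 3 with drugX of which 2 event-positive; 4 event-positive
        overall -> a=2 b=2 c=1 d=5."""
        reports = [
            make_report("R0", drug="drugX", pt="Microtia"),
            make_report("R1", drug="drugX", pt="Microtia"),
            make_report("R2", drug="drugX", pt="Pyrexia"),
            make_report("R3", drug="other", pt="Microtia"),
            make_report("R4", drug="other", pt="Microtia"),
        ] + [make_report(f"R{i}", drug="other", pt="Pyrexia") for i in range(5, 10)]
        cases = [r for r in reports if r.reactions[0].pt_name == "Microtia"]
        t = build_table(reports, cases, "drugX")
        assert (t.a, t.b, t.c, t.d) == (2, 2, 1, 5)
        assert t.n == 10

    def test_absent_drug_gives_zero_drug_margin(self):
        reports = [make_report(f"R{i}", drug="other", pt=p)
                   for i, p in enumerate(["Microtia", "Pyrexia", "Pyrexia"])]
        t = build_table(reports, reports[:1], "ghost")
        assert (t.a, t.c) == (0, 0)
        assert (t.b, t.d) == (1, 2)

    def test_repeated_mentions_count_report_once(self):
        r = make_report("R1", drug="drugX", pt="Microtia",
                        extra_drugs=[("drugX", DrugRole.PRIMARY_SUSPECT)])
        t = build_table([r], [r], "drugX")
        assert (t.a, t.b, t.c, t.d) == (1, 0, 0, 0)

    def test_cells_match_generator_bookkeeping(self):
        """Pipeline-built cells equal counts taken straight from the
        generator's planted arrays, and margins are conserved across drugs."""
        params = SimulationParams(n_reports=4000, seed=13)
        rs, truth = generate(params)
        ts = TermSet("m", (("Microtia", None),))
        cs = select_cases(rs, ts, FilterConfig(report_types=ALL_REPORT_TYPES))
        ev = set(truth.report_ids_with_event("Microtia"))
        n = len(rs.reports)
        for drug in ("valproic acid", "paracetamol"):
            t = build_table(cs.universe, cs.case_ids, drug, cs.filters.drug_roles)
            dr = set(truth.report_ids_with_drug(drug))
            assert t.a == len(ev & dr)
            assert t.c == len(dr - ev)
            assert t.a + t.b == len(ev)
            assert t.n == n


class TestFormulas:
    def test_uniform_table_is_null(self):
        t = _tab(10, 10, 10, 10)
        ror, lo, hi = ror_stats(t)
        assert ror == 1.0
        assert lo * hi == pytest.approx(1.0)  # symmetric about 1 on log scale
        prr, plo, phi = prr_stats(t)
        assert prr == 1.0
        assert plo * phi == pytest.approx(1.0)

    def test_large_sparse_table_direct_arithmetic(self):
        ror, _, _ = ror_stats(_tab(4, 186, 1121, 20_752_970))
        assert ror == pytest.approx(83_011_880 / 208_506)
        assert ror == pytest.approx(398.1, abs=0.05)

    def test_prr_hand_arithmetic(self):
        prr, _, _ = prr_stats(_tab(3, 7, 5, 85))
        assert prr == pytest.approx(3 * 90 / (5 * 10))

    def test_chi2_hand_arithmetic_and_independence(self):
        assert chi_square(_tab(3, 7, 5, 85)) == pytest.approx(
            220**2 * 100 / (10 * 90 * 8 * 92))
        assert chi_square(_tab(1, 9, 9, 81)) == 0.0  # ad == bc

    def test_zero_cell_raises_unless_corrected(self):
        t = _tab(3, 0, 5, 85)
        with pytest.raises(ZeroCellError):
            ror_stats(t)
        ror, _, _ = ror_stats(t, correction=True)
        assert ror == pytest.approx((3.5 * 85.5) / (0.5 * 5.5))

    @given(
        a=st.integers(1, 1000), b=st.integers(1, 1000),
        c=st.integers(1, 1000), d=st.integers(1, 1000),
    )
    @settings(max_examples=300, deadline=None, derandomize=True)
    def test_rational_arithmetic_oracle(self, a, b, c, d):
        """ROR, PRR and chi-squared agree with exact Fraction recomputation."""
        t = _tab(a, b, c, d)
        assert ror_stats(t)[0] == pytest.approx(
            float(Fraction(a * d, b * c)), rel=1e-12)
        assert prr_stats(t)[0] == pytest.approx(
            float(Fraction(a * (c + d), c * (a + b))), rel=1e-12)
        n = a + b + c + d
        exact = Fraction((a * d - b * c) ** 2 * n,
                         (a + b) * (c + d) * (a + c) * (b + d))
        assert chi_square(t) == pytest.approx(float(exact), rel=1e-12)

    @given(
        a=st.integers(1, 200), b=st.integers(1, 200),
        c=st.integers(1, 200), d=st.integers(1, 200),
    )
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_against_statsmodels_and_scipy(self, a, b, c, d):
        """Cross-check ROR + CI against statsmodels' Table2x2 and chi-squared
        against scipy's uncorrected test."""
        t = _tab(a, b, c, d)
        sm = Table2x2(np.array([[a, c], [b, d]]))
        ror, lo, hi = ror_stats(t)
        assert ror == pytest.approx(sm.oddsratio, rel=1e-12)
        sm_lo, sm_hi = sm.oddsratio_confint(0.05)
        # statsmodels uses the exact normal quantile; we use 1.96
        assert lo == pytest.approx(sm_lo, rel=1e-3)
        assert hi == pytest.approx(sm_hi, rel=1e-3)
        sp = chi2_contingency(np.array([[a, c], [b, d]]), correction=False)
        assert chi_square(t) == pytest.approx(sp.statistic, rel=1e-10)

    def test_ror_and_prr_converge_when_event_is_rare(self):
        """|ROR - PRR|/ROR -> 0 as the event becomes rare in both exposure
        strata (PRR/ROR = (b/(a+b)) * ((c+d)/d) -> 1)."""
        gaps = []
        for b in (10, 100, 1000, 10000):
            t = _tab(5, b, 100, 100 * b)
            gap = abs(ror_stats(t)[0] - prr_stats(t)[0]) / ror_stats(t)[0]
            gaps.append(gap)
        assert gaps == sorted(gaps, reverse=True)
        assert gaps[-1] < 1e-3


class TestCriteria:
    def _stats(self, a=10, prr=5.0, prr_lo=2.0, ror_lo=2.0, chi2=50.0):
        return SignalStats(
            drug="x", a=a, ror=prr, ror_ci=(ror_lo, prr * 10),
            prr=prr, prr_ci=(prr_lo, prr * 10), chi2=chi2,
        )

    def test_headline_rule(self):
        flags = evaluate_signal(self._stats(a=3, prr_lo=1.2))
        assert flags.headline_signal

    def test_min_a_gates_everything(self):
        flags = evaluate_signal(self._stats(a=2, prr=1e6, prr_lo=1e5, ror_lo=1e5, chi2=1e6))
        assert flags == SignalFlags(False, False, False)

    def test_prr_threshold(self):
        flags = evaluate_signal(self._stats(a=10, prr=1.9, chi2=50.0, prr_lo=1.1))
        assert not flags.prr_criterion
        assert flags.headline_signal  # PRR CI low 1.1 > 1 and a >= 3

    def test_monotone_in_a_and_prr_ci(self):
        cfg = CriteriaConfig()
        for a_small, a_big in [(1, 3), (2, 50)]:
            f1 = evaluate_signal(self._stats(a=a_small), cfg)
            f2 = evaluate_signal(self._stats(a=a_big), cfg)
            assert f2.headline_signal >= f1.headline_signal
        for lo_small, lo_big in [(0.5, 1.01), (1.01, 7.0)]:
            f1 = evaluate_signal(self._stats(prr_lo=lo_small), cfg)
            f2 = evaluate_signal(self._stats(prr_lo=lo_big), cfg)
            assert f2.headline_signal >= f1.headline_signal


class TestRanking:
    def _mk(self, drug, ror, a):
        return SignalStats(drug=drug, a=a, ror=ror, ror_ci=(ror / 2, ror * 2),
                           prr=ror * 0.98, prr_ci=(ror / 2, ror * 2), chi2=10.0)

    def test_descending_by_ror(self):
        stats = [self._mk("methimazole", 198.35, 3), self._mk("primidone", 397.05, 4),
                 self._mk("valproic acid", 239.46, 122)]
        ranked = rank_signals(stats, by="ror")
        assert [s.drug for s in ranked] == ["primidone", "valproic acid", "methimazole"]

    def test_tie_broken_by_case_count(self):
        ranked = rank_signals([self._mk("zeta", 50.0, 3), self._mk("alpha", 50.0, 10)])
        assert [s.drug for s in ranked] == ["alpha", "zeta"]

    def test_permutation_invariance_and_top_k(self):
        rng = np.random.default_rng(0)
        stats = [self._mk(f"d{i}", float(r), int(a))
                 for i, (r, a) in enumerate(zip(rng.uniform(1, 100, 40),
                                                rng.integers(3, 50, 40)))]
        ranked = rank_signals(stats, top_k=10)
        for seed in (1, 2):
            perm = list(np.random.default_rng(seed).permutation(len(stats)))
            assert rank_signals([stats[i] for i in perm], top_k=10) == ranked

    def test_bad_key_rejected(self):
        with pytest.raises(ValueError):
            rank_signals([], by="chi2")
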