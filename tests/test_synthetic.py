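"""Generator ground truth, expected cells, determinism, operating characteristics."""

import filecmp
import math

import numpy as np
import pytest
from pydantic import ValidationError

from auricle.disproportionality import CriteriaConfig
from auricle.ingest import write_reports
from auricle.synthetic import (
    DrugSpec,
    EventSpec,
    SignalSpec,
    SimulationParams,
    expected_table,
    generate,
    recovery_experiment,
)


class TestParamsValidation:
    def test_bad_mix_reported_with_field(self):
        with pytest.raises(ValidationError, match="sex_mix"):
            SimulationParams(sex_mix={"female": 0.5, "male": 0.4})

    def test_drug_marginal_must_sum_to_one(self):
        with pytest.raises(ValidationError, match="marginal"):
            SimulationParams(drugs=[DrugSpec(generic="a", background_prob=0.5)])

    def test_signal_must_reference_roster(self):
        with pytest.raises(ValidationError, match="not in drug roster"):
            SimulationParams(signals=[SignalSpec(generic="ghost", pt_name="Microtia",
                                                 rate_ratio=2.0)])


class TestExpectedTable:
    def test_independence_under_null_rate_ratio(self):
        params = SimulationParams(signals=[])
        a, b, c, d = expected_table(params, "valproic acid", "Microtia")
        assert a * d == pytest.approx(b * c)

    def test_hand_arithmetic_with_injected_signal(self):
        """drug prob 0.01, event prob 0.001, rate ratio 50, n=1e6 ->
        a = 1e6 * 0.01 * 0.05 = 500; margins fix the rest."""
        params = SimulationParams(
            n_reports=10**6,
            drugs=[DrugSpec(generic="dx", background_prob=0.01),
                   DrugSpec(generic="rest", background_prob=0.99)],
            events=[EventSpec(pt_name="ev", background_prob=0.001)],
            signals=[SignalSpec(generic="dx", pt_name="ev", rate_ratio=50.0)],
        )
        a, b, c, d = expected_table(params, "dx", "ev")
        assert a == pytest.approx(500.0)
        assert c == pytest.approx(10**6 * 0.01 - 500)
        assert b == pytest.approx(10**6 * 0.99 * 0.001)
        assert a + b + c + d == pytest.approx(10**6)

    def test_cells_sum_to_n_for_any_pair(self):
        params = SimulationParams()
        for d in params.drugs:
            for e in params.events:
                assert sum(expected_table(params, d.generic, e.pt_name)) == pytest.approx(
                    params.n_reports)

    def test_unknown_pair_rejected(self):
        with pytest.raises(KeyError):
            expected_table(SimulationParams(), "ghost", "Microtia")

    def test_report_type_subset_scales_cells(self):
        params = SimulationParams()
        full = expected_table(params, "valproic acid", "Microtia")
        direct = expected_table(params, "valproic acid", "Microtia",
                                report_types=["direct"])
        assert direct == pytest.approx(tuple(0.6 * x for x in full))


def _cells_from_truth(truth, drug, event):
    ev = truth.report_ids_with_event(event)
    dr = truth.report_ids_with_drug(drug)
    n = len(truth.report_ids)
    a = len(ev & dr)
    return a, len(ev) - a, len(dr) - a, n - len(ev) - len(dr) + a


class TestGenerate:
    def test_same_seed_byte_identical_files(self, tmp_path):
        params = SimulationParams(n_reports=500, seed=99)
        for name in ("one", "two"):
            rs, _ = generate(params)
            write_reports(rs, tmp_path / name)
        for fn in ("DEMO.txt", "DRUG.txt", "REAC.txt", "OUTC.txt"):
            assert filecmp.cmp(tmp_path / "one" / fn, tmp_path / "two" / fn,
                               shallow=False), fn

    def test_different_seed_differs(self):
        rs1, _ = generate(SimulationParams(n_reports=300, seed=1))
        rs2, _ = generate(SimulationParams(n_reports=300, seed=2))
        assert rs1.reports != rs2.reports

    def test_null_model_ror_ci_contains_one(self):
        """With rate ratio 1 everywhere the empirical ROR's 95% CI covers 1."""
        params = SimulationParams(
            n_reports=10_000, seed=4, signals=[],
            drugs=[DrugSpec(generic="dx", background_prob=0.2),
                   DrugSpec(generic="rest", background_prob=0.8)],
            events=[EventSpec(pt_name="ev", background_prob=0.05)],
        )
        _, truth = generate(params)
        a, b, c, d = _cells_from_truth(truth, "dx", "ev")
        ror = a * d / (b * c)
        se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
        assert ror * math.exp(-1.96 * se) < 1 < ror * math.exp(1.96 * se)

    def test_injected_signal_ror_near_expected(self):
        """Empirical ROR of a rate-ratio-50 pair lies within the Wald 95% CI
        of the ROR implied by the expected cells."""
        params = SimulationParams(
            n_reports=200_000, seed=12,
            drugs=[DrugSpec(generic="dx", background_prob=0.01),
                   DrugSpec(generic="rest", background_prob=0.99)],
            events=[EventSpec(pt_name="ev", background_prob=0.001)],
            signals=[SignalSpec(generic="dx", pt_name="ev", rate_ratio=50.0)],
        )
        _, truth = generate(params)
        ea, eb, ec, ed = expected_table(params, "dx", "ev")
        expected_ror = (ea * ed) / (eb * ec)
        a, b, c, d = _cells_from_truth(truth, "dx", "ev")
        se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
        ror = a * d / (b * c)
        assert abs(math.log(ror) - math.log(expected_ror)) < 1.96 * se

    def test_empirical_cells_near_expected(self):
        """Every drawn cell is within 3 binomial standard deviations of its
        expectation."""
        params = SimulationParams(n_reports=50_000, seed=7)
        _, truth = generate(params)
        n = params.n_reports
        # the independent draws are the drug margin (multinomial) and, given
        # it, each a-cell (binomial in the within-drug event probability);
        # derived cells b/c/d only replicate these fluctuations
        from auricle.synthetic import _event_prob
        for k, spec in enumerate(params.drugs):
            m_k = int((truth.drug_index == k).sum())
            sd = math.sqrt(n * spec.background_prob * (1 - spec.background_prob))
            assert abs(m_k - n * spec.background_prob) <= 4 * sd, spec.generic
            for j, ev in enumerate(params.events):
                q = _event_prob(params, spec.generic, ev.pt_name)
                a = int(truth.event_matrix[truth.drug_index == k, j].sum())
                sd_a = math.sqrt(max(m_k * q * (1 - q), 1.0))
                assert abs(a - m_k * q) <= 4 * sd_a, (spec.generic, ev.pt_name)

    def test_reports_always_have_reactions_and_one_primary_suspect(self):
        rs, _ = generate(SimulationParams(n_reports=400, seed=2,
                                          concomitant_rate=0.5))
        from auricle.ingest import DrugRole
        for r in rs.reports:
            assert r.reactions
            assert sum(m.role is DrugRole.PRIMARY_SUSPECT for m in r.drugs) == 1


class TestRecoveryExperiment:
    def test_single_replicate_report_shape(self):
        params = SimulationParams(n_reports=2000, seed=5)
        rep = recovery_experiment(params, n_reps=1)
        assert rep.replicates["rep"].nunique() == 1
        assert set(rep.replicates["kind"]) <= {"injected", "null"}
        assert rep.summary["n_reps"] == 1

    def test_strong_signal_recovered(self):
        """A rate-ratio-50 pair with expected a = 20 is flagged in every one
        of a handful of replicates."""
        params = SimulationParams(
            n_reports=10_000, seed=31,
            drugs=[DrugSpec(generic="dx", background_prob=0.02),
                   DrugSpec(generic="rest", background_prob=0.98)],
            events=[EventSpec(pt_name="ev", background_prob=0.002),
                    EventSpec(pt_name="bg", background_prob=0.05)],
            signals=[SignalSpec(generic="dx", pt_name="ev", rate_ratio=50.0)],
        )
        rep = recovery_experiment(params, CriteriaConfig(), n_reps=8)
        assert rep.summary["sensitivity"] == 1.0
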