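import datetime as dt

import pytest

from auricle.ingest import (
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


def make_report(
    report_id,
    drug="drugX",
    role=DrugRole.PRIMARY_SUSPECT,
    pt="Pyrexia",
    report_type=ReportType.DIRECT,
    case_id=None,
    version=1,
    receipt=dt.date(2018, 6, 1),
    sex=Sex.UNKNOWN,
    age=None,
    start_date=None,
    event_date=None,
    outcomes=(),
    extra_drugs=(),
    extra_pts=(),
):
    """One-liner SafetyReport factory for tests."""
    drugs = [DrugMention(raw_name=drug, generic_name=drug, role=role,
                         start_date=start_date)]
    drugs += [DrugMention(raw_name=d, generic_name=d, role=r)
              for d, r in extra_drugs]
    reactions = [ReactionMention(pt_name=pt, event_date=event_date)]
    reactions += [ReactionMention(pt_name=p) for p in extra_pts]
    return SafetyReport(
        report_id=report_id,
        case_id=case_id or report_id,
        version=version,
        report_type=report_type,
        receipt_date=receipt,
        sex=sex,
        age_years=age,
        reporter=Reporter.UNKNOWN,
        outcomes=frozenset(outcomes),
        drugs=drugs,
        reactions=reactions,
    )


@pytest.fixture
def report_factory():
    return make_report


def make_report_set(reports):
    return ReportSet(reports=list(reports), provenance={"source": "test"})


@pytest.fixture
def report_set_factory():
    return make_report_set
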