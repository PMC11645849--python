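import numpy as np
import pytest

from qalyval.qaly import (
    EventOccurrence,
    EventType,
    PatientRecord,
    UtilityTable,
)
from qalyval.microsim import RiskEquation, RiskEquationSet


@pytest.fixture(scope="session")
def default_table() -> UtilityTable:
    return UtilityTable.default()


@pytest.fixture
def event_free_patient() -> PatientRecord:
    return PatientRecord("p1", 62.0, False, 12.0, censor_time=2.0)


@pytest.fixture
def stroke_renal_decedent() -> PatientRecord:
    """Stroke in year 2, renal failure in year 3, death during year 4."""
    return PatientRecord(
        "p2",
        62.0,
        False,
        12.0,
        events=[
            EventOccurrence(EventType.STROKE, 1, 2),
            EventOccurrence(EventType.RENAL_FAILURE, 1, 3),
        ],
        death_time=3.4,
        censor_time=3.4,
        administrative_end_time=4.0,
    )


def constant_hazard_equations(p: float, event=EventType.STROKE) -> RiskEquationSet:
    """Single event with constant annual probability p, death impossible."""
    logit = float(np.log(p / (1 - p)))
    return RiskEquationSet(
        {event: RiskEquation("logistic", {"intercept": logit})},
        RiskEquation("logistic", {"intercept": -50.0}),
    )


@pytest.fixture
def zero_risk_equations() -> RiskEquationSet:
    zero = RiskEquation("logistic", {"intercept": -50.0})
    return RiskEquationSet({ev: zero for ev in EventType}, zero)
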