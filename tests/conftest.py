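from decimal import Decimal

import pytest

from vtecost.econ_model import CostScenario, DrugCourse
from vtecost.report_io import INR_MONITORING_USD, packaged_drug_table


@pytest.fixture(scope="session")
def drugs() -> list[DrugCourse]:
    """The five packaged regimens (1-month retail course prices)."""
    return packaged_drug_table()


@pytest.fixture(scope="session")
def regimens(drugs) -> dict[str, DrugCourse]:
    """All six analysed regimens keyed by label, including the
    warfarin + INR-monitoring variant."""
    by_label = {d.label: d for d in drugs}
    warfarin = by_label["Warfarin 5"]
    inr = warfarin.with_monitoring(INR_MONITORING_USD)
    by_label[inr.label] = inr
    return by_label


@pytest.fixture
def low_rate_scenario() -> CostScenario:
    """Institutional treatment cost at the lowest literature VTE rate."""
    return CostScenario(treatment_cost=Decimal("9407"), initial_rate=0.0046)
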