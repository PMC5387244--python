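import pytest

from coarctcost.parameters import DiscountSpec
from coarctcost.scenarios import builtin_scenarios
from coarctcost.synthetic import baseline_2014

# Table 3 of the published base-case analysis (GBP, pound-rounded).
# Rows: initial, short_term, mid_term, overall, avoidable.
PUBLISHED_TABLE = {
    "Baseline": (4790, 5980, 5919, 16688, None),
    "Scenario 1": (4781, 5933, 5836, 16551, 137),
    "Scenario 2": (4769, 5861, 5709, 16338, 350),
    "Scenario 3": (4550, 5741, 5498, 15790, 898),
    "Best case": (4508, 5492, 5061, 15061, 1627),
}


@pytest.fixture(scope="session")
def baseline():
    return baseline_2014()


@pytest.fixture(scope="session")
def specs():
    return builtin_scenarios()


@pytest.fixture(scope="session")
def disc():
    return DiscountSpec()
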