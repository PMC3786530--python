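import pytest

from cauticost import CostParams, HospitalScenario, RiskParams


@pytest.fixture
def default_risks() -> RiskParams:
    return RiskParams()


@pytest.fixture
def default_costs() -> CostParams:
    return CostParams()


@pytest.fixture
def hospital() -> HospitalScenario:
    """The published hypothetical hospital: 3000 admissions, 15% catheterized."""
    return HospitalScenario(admissions=3000, prop_catheterized=0.15)
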