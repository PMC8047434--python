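import pytest

from liefep.thermo import GAS_CONSTANT_KCAL, ThermoParams


@pytest.fixture
def thermo298():
    return ThermoParams(temperature=298.0)


def thermo_from_kT(kT: float) -> ThermoParams:
    """ThermoParams whose thermal energy equals the requested kT (kcal/mol)."""
    return ThermoParams(temperature=kT / GAS_CONSTANT_KCAL)


@pytest.fixture
def thermo_kT0596():
    return thermo_from_kT(0.596)
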