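import pytest

from glycobind import KineticParams, ModelKind, PhaseSchedule, serial_dilution


@pytest.fixture
def compound11_params():
    """1:1 rate constants of the strongest neo-glycoprotein ligand regime."""
    return KineticParams(ModelKind.LANGMUIR_1TO1, 5.9e6, 8.5e-5, 100.0)


@pytest.fixture
def schedule():
    return PhaseSchedule(t_assoc=120.0, t_dissoc=600.0, dt=0.5)


@pytest.fixture
def coarse_schedule():
    """Coarser sampling used where many fits are run."""
    return PhaseSchedule(t_assoc=120.0, t_dissoc=600.0, dt=1.5)


@pytest.fixture
def picomolar_ladder():
    return serial_dilution(250e-12, 2.0, 5)


@pytest.fixture
def nanomolar_ladder():
    return serial_dilution(250e-9, 2.0, 5)
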