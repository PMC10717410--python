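import pytest
from hypothesis import HealthCheck, settings

import tastecell as tc
from tastecell.cell import tmc4_only_cell

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def calibrated() -> tc.CellParams:
    """The default model cell calibrated to the experimental anchors."""
    return tc.default_cell_params()


@pytest.fixture(scope="session")
def kcl_cell() -> tc.CellParams:
    """TMC4-only cell in the KCl whole-cell configuration (E_rev = -27.6 mV)."""
    return tmc4_only_cell(tc.Tmc4Params())


@pytest.fixture(scope="session")
def kcl_sweeps(kcl_cell) -> tc.SweepSet:
    """Standard step family (-100..+100 by 10 mV) on the KCl TMC4 cell."""
    return tc.simulate_voltage_clamp(kcl_cell, tc.VoltageClampProtocol(sample_dt=1.0))
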