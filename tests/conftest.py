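import pytest

from ltcisim import (
    CalibrationSpec,
    ModelParameters,
    calibrate_escalation,
)


@pytest.fixture(scope="session")
def params() -> ModelParameters:
    """Base-year default parameter set (published values, default esc)."""
    return ModelParameters()


@pytest.fixture(scope="session")
def calibrated_params(params) -> ModelParameters:
    """Defaults with esc freshly re-solved from the scenario anchor."""
    return params.replace(esc=calibrate_escalation(params, CalibrationSpec()))
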