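import dataclasses

import pytest

from copingsim import Protocol, build_reference_circuit
from copingsim.circuit import EXPERIENCE_PRESETS, LESION_PRESETS
from copingsim.fitting import fitted_reference_circuit
from copingsim.protocols import default_conditions, run_condition_suite


@pytest.fixture(scope="session")
def reference_circuit():
    return build_reference_circuit()


@pytest.fixture(scope="session")
def fitted_circuit():
    return fitted_reference_circuit()


@pytest.fixture(scope="session")
def sham_protocol():
    return Protocol()


@pytest.fixture(scope="session")
def condition_suite(fitted_circuit):
    """Sham, both depletions, the long-experience preset and the IL-VTA
    lesion, run once on the fitted reference circuit and shared."""
    conditions = default_conditions()
    conditions["long"] = dataclasses.replace(
        Protocol(), experience=EXPERIENCE_PRESETS["long"]
    )
    conditions["IL-VTA"] = dataclasses.replace(
        Protocol(), lesion=LESION_PRESETS["IL-VTA"]
    )
    return run_condition_suite(fitted_circuit, conditions)
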