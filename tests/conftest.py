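import pytest
from hypothesis import HealthCheck, settings

from oncocircuit import load_reference_circuit, toy_stuck_nand

settings.register_profile(
    "ci", derandomize=True, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow], deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def reference():
    """The bundled CRPC reference circuit."""
    return load_reference_circuit()


@pytest.fixture()
def toy():
    """The 4-input NAND/AND/OR teaching circuit with one stuck-at-1 site."""
    return toy_stuck_nand()
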