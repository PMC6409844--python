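import numpy as np
import pytest
from hypothesis import settings

from bioload import ConcentrationPanel, fixtures

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def table2_panel() -> ConcentrationPanel:
    return fixtures.table2_panel()


@pytest.fixture(scope="session")
def unit_background():
    return fixtures.unit_background()


@pytest.fixture
def tiny_panel() -> ConcentrationPanel:
    """One site, two compartments, one element, two replicates."""
    return ConcentrationPanel(
        [
            ("S", "soil", "Pb", 1, 2.0),
            ("S", "soil", "Pb", 2, 4.0),
            ("S", "biota", "Pb", 1, 10.0),
            ("S", "biota", "Pb", 2, 30.0),
        ]
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
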