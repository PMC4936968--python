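import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from fermopt.datasets import published_models, table1_fixture, table2_fixture

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def table2():
    """The eight-run U8(8^3) campaign: (DesignTable, [RunRecord])."""
    return table2_fixture()


@pytest.fixture(scope="session")
def table1():
    """The five-run rotating-simplex campaign: (Region, [RunRecord])."""
    return table1_fixture()


@pytest.fixture(scope="session")
def pub_models():
    """The study's printed coded regression equations."""
    return published_models()


@pytest.fixture(scope="session")
def full_region(table2):
    design, _ = table2
    return design.space.region()
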