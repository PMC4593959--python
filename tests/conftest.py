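import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from oiecare.fragments import Proteoform, generate_fragments
from oiecare.io import load_worked_example
from oiecare.matching import SearchParams, fish_ion
from oiecare.simgen import MYOGLOBIN_SEQUENCE

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def myoglobin():
    return Proteoform("MYG_HORSE", MYOGLOBIN_SEQUENCE)


@pytest.fixture(scope="session")
def myoglobin_y_ions(myoglobin):
    """y-series database at charges 1..7, IPACO 20 — holds the colliding
    y10-1+/y20-2+/y72-7+ trio near m/z 1142.61."""
    return generate_fragments(myoglobin, {"y"}, set(), max_charge=7, ipaco=20.0)


@pytest.fixture(scope="session")
def overlap_trio(myoglobin_y_ions):
    wanted = {"y10-1+", "y20-2+", "y72-7+"}
    ions = [i for i in myoglobin_y_ions if i.label in wanted]
    assert len(ions) == 3
    return ions


@pytest.fixture()
def worked_example():
    """Printed three-ion overlap excerpt: (ions, spectrum)."""
    return load_worked_example()


@pytest.fixture()
def product_params():
    return SearchParams(20.0, 15.0, 50.0, "product")


@pytest.fixture()
def worked_matches(worked_example, product_params):
    ions, spectrum = worked_example
    matches = [
        fish_ion(ion, spectrum, product_params, require_base=False)
        for ion in ions
    ]
    assert all(m is not None for m in matches)
    return matches, spectrum
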