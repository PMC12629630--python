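import pytest

from mcwound.structure_io import load_radii_table
from mcwound.synthetic_data import make_verdict_suite


@pytest.fixture(scope="session")
def radii():
    return load_radii_table()


@pytest.fixture(scope="session")
def verdict_suite():
    """The four oracle-validated fixtures; expensive, built once."""
    return make_verdict_suite(seed=0)
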