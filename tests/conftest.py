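import numpy as np
import pytest

from clampkit.blockerdesign import DesignConfig
from clampkit.fixtures import FixtureSpec, make_design_fixture
from clampkit.thermo import ThermoParams


@pytest.fixture(scope="session")
def thermo_params():
    return ThermoParams()


@pytest.fixture(scope="session")
def paper_geometry_config():
    """Window geometry of the published clamp: a single 16-mer ending six
    bases downstream of the reverse primer 3'-end position."""
    return DesignConfig(window_length_range=(16, 16), offset_downstream_range=(6, 6))


@pytest.fixture(scope="session")
def design_fixture():
    """Planted design fixture: 6 hosts in 2 haplotypes differing at one A/T
    column, plus an exclusion sequence with 3 planted mismatches."""
    return make_design_fixture(FixtureSpec(seed=7))


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)


def random_iupac(rng, n, alphabet="ACGTRYSWKMBDHVN"):
    letters = np.array(list(alphabet))
    return "".join(letters[rng.integers(len(letters), size=n)])


def random_dna(rng, n):
    return random_iupac(rng, n, "ACGT")
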