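import numpy as np
import pytest

from hyperbranch.fixtures import make_fixtures
from hyperbranch.mol2 import MapFile


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory):
    """Toy mol2 templates + map file, written once per session."""
    d = tmp_path_factory.mktemp("templates")
    make_fixtures(d)
    return d


@pytest.fixture(scope="session")
def mapfile(fixture_dir):
    return MapFile.parse(fixture_dir / "units.map")


def random_tree_parents(n, rng):
    """Random parent array of a rooted tree on n nodes (parents precede)."""
    return [None] + [int(rng.integers(0, i)) for i in range(1, n)]
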