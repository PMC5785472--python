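import pytest

from pksmine import mine_cluster
from pksmine.audit import load_product_spec
from pksmine.config import default_config
from pksmine.synthetic import sce_fixture


@pytest.fixture(scope="session")
def config():
    return default_config()


@pytest.fixture(scope="session")
def sce():
    """The shipped sceliphrolactam-cluster fixture (5 proteins, 10 modules)."""
    return sce_fixture()


@pytest.fixture(scope="session")
def sce_line(sce):
    return mine_cluster(sce.genes)


@pytest.fixture(scope="session")
def sce_spec():
    return load_product_spec()
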