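import numpy as np
import pytest
from hypothesis import settings

from chordsift.model import default_panel, load_fixture
from chordsift.pathogenicity import classify

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def panel():
    return default_panel()


@pytest.fixture(scope="session")
def table1():
    return load_fixture("european_table1")


@pytest.fixture(scope="session")
def table2():
    return load_fixture("chinese_table2")


@pytest.fixture(scope="session")
def table1_classified(table1):
    return [(rec, classify(rec, ann)) for rec, ann in table1.items()]


@pytest.fixture(scope="session")
def table2_classified(table2):
    return [(rec, classify(rec, ann)) for rec, ann in table2.items()]


@pytest.fixture(scope="session")
def small_assoc_instance():
    """A 200-sample, 5-variant case-control instance with moderately rare
    variants; shared by analytic-vs-permutation comparisons."""
    rng = np.random.default_rng(7)
    n, m = 200, 5
    maf = rng.uniform(0.03, 0.12, m)
    G = rng.binomial(2, maf, size=(n, m)).astype(float)
    y = np.zeros(n)
    y[:60] = 1.0
    rng.shuffle(y)
    return G, y
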