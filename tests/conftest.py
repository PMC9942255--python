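import numpy as np
import pytest

from spscreen import SPRecord, generate_reference_set


@pytest.fixture
def example_record() -> SPRecord:
    # AxA cleavage site, regions N=MKKR, H=ILSLVLAAVLLFAA, C=QPAKA, Ac=AEH
    return SPRecord(id="sp1", aa_seq="MKKRILSLVLAAVLLFAAQPAKAAEH", n_end=4, h_end=18, c_end=23)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def reference_set():
    return generate_reference_set(60, np.random.default_rng(7))
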