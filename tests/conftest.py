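import numpy as np
import pytest

from xpand5s.schema import load_schema


@pytest.fixture(scope="session")
def bacterial():
    return load_schema("bacterial")


@pytest.fixture(scope="session")
def archaeal():
    return load_schema("archaeal")


@pytest.fixture()
def rng():
    return np.random.default_rng(20210201)


def random_rna(rng, n: int) -> str:
    return "".join(np.array(list("ACGU"))[rng.integers(0, 4, n)])
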