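import random

import pytest

from movedex import textcore as tc
from movedex.index import BuildConfig, build_index

#: the 19-character example text whose every index component is known exactly
EXAMPLE = "CTATGTCATATGTTGGTC"


@pytest.fixture(scope="session")
def example_text() -> tc.Text:
    return tc.concat_with_sentinel([tc.Text(EXAMPLE, name="toy")])


@pytest.fixture(scope="session")
def example_ss(example_text):
    return tc.build_suffix_structures(example_text)


@pytest.fixture(scope="session")
def example_ss_rev(example_text):
    return tc.build_suffix_structures(tc.reverse_text(example_text))


@pytest.fixture(scope="session")
def example_index():
    return build_index([tc.Text(EXAMPLE, name="toy")])


@pytest.fixture(scope="session")
def example_index_nophi():
    return build_index([tc.Text(EXAMPLE, name="toy")],
                       BuildConfig(with_phi_tables=False))


def random_text(rng: random.Random, lo: int = 1, hi: int = 300) -> tc.Text:
    body = "".join(rng.choice("ACGT") for _ in range(rng.randint(lo, hi)))
    return tc.Text(body + "$", name="rand")


@pytest.fixture
def rng():
    return random.Random(0xB10B)
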