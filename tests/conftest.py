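import random

import pytest

from musekit.compose import (
    WWII_DECOY,
    WWII_MESSAGE,
    Communication,
    build_strands,
)
from musekit.ikey import build_reference_ikey, randomize_ikey
from musekit.io import load_construct_strands, load_fixture


@pytest.fixture(scope="session")
def reference_ikey():
    return build_reference_ikey()


@pytest.fixture(scope="session")
def constructs():
    """The printed construct fixtures keyed by name."""
    return load_construct_strands()


@pytest.fixture(scope="session")
def primer_key():
    return load_fixture("Primer_Key")


@pytest.fixture(scope="session")
def primer_message():
    return load_fixture("Primer_Message")


@pytest.fixture(scope="session")
def wwii_communication(reference_ikey):
    return Communication(message=WWII_MESSAGE, decoy=WWII_DECOY, ikey=reference_ikey)


# Word pool for random communications: lowercase-only so texts survive the
# shift roundtrip, distinct words so unrelated fragments never coincide.
_WORDS = [
    "alpha", "bravo", "charlie", "delta", "echo", "foxtrot", "golf", "hotel",
    "india", "juliett", "kilo", "lima", "mike", "november", "oscar", "papa",
    "quebec", "romeo", "sierra", "tango", "uniform", "victor", "whiskey",
    "xray", "yankee", "zulu",
]


def random_communication(seed: int, reference_ikey=None) -> Communication:
    """A seeded random communication with 2, 4, or 6 strands."""
    rng = random.Random(seed)
    n = rng.choice([2, 4, 6])
    pool = rng.sample(_WORDS, len(_WORDS))
    n_msg = rng.randint(n // 2, n + 3)
    n_dec = rng.randint(n // 2, n + 3)
    message = " ".join(pool[:n_msg])
    decoy = " ".join(pool[n_msg : n_msg + n_dec])
    ikey = reference_ikey or build_reference_ikey()
    if rng.random() < 0.5:
        ikey = randomize_ikey(ikey, rng.randrange(2**31))
    return Communication(message=message, decoy=decoy, ikey=ikey, strand_count=n)


@pytest.fixture
def make_random_communication(reference_ikey):
    return lambda seed: random_communication(seed, reference_ikey)


@pytest.fixture
def built_wwii(wwii_communication):
    return build_strands(wwii_communication, filler_seed=11)
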