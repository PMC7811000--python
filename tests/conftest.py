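import random

import pytest
from hypothesis import HealthCheck, settings

from guidescout.scoring import load_tables

settings.register_profile(
    "suite", derandomize=True, max_examples=25, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("suite")


@pytest.fixture(scope="session")
def tables():
    return load_tables()


@pytest.fixture()
def rng():
    return random.Random(20240101)


def random_guide(rng, n=20):
    return "".join(rng.choices("ACGT", k=n))


def naive_hits(contigs: dict, pattern: str):
    """Brute-force both-strand exact search: all (contig, pos, strand).

    Independent of the package's index: plain str.find over the forward
    sequence for the pattern and for its reverse complement.
    """
    comp = str.maketrans("ACGT", "TGCA")
    rc = pattern.translate(comp)[::-1]
    out = []
    for name, seq in contigs.items():
        for pat, strand in ((pattern, "+"), (rc, "-")):
            start = 0
            while (i := seq.find(pat, start)) != -1:
                out.append((name, i, strand))
                start = i + 1
    return sorted(set(out))
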