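import numpy as np
import pytest

from pgpmkit.io_formats import Genome, Read, load_published_tables


@pytest.fixture(scope="session")
def tables():
    return load_published_tables()


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)


def random_genome(rng, length, gid="g"):
    return Genome(id=gid, sequence="".join(rng.choice(list("ACGT"), size=length)))


def mutate(rng, seq, positions):
    out = list(seq)
    for p in positions:
        out[p] = rng.choice([b for b in "ACGT" if b != out[p]])
    return "".join(out)


@pytest.fixture
def make_genome(rng):
    def _make(length, gid="g"):
        return random_genome(rng, length, gid)

    return _make


@pytest.fixture
def make_read():
    def _make(seq, rid="r"):
        return Read(id=rid, sequence=seq)

    return _make
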