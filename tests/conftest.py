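import pytest
from hypothesis import settings

from domainskip.synthetic_fixtures import FixtureSpec, load_toy_gene

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_spec():
    """The canonical fixture: 13 domains of 102 aa, two exons per domain,
    so the designated pair spans 306 coding nt."""
    return FixtureSpec()


@pytest.fixture(scope="session")
def toy(default_spec):
    """(GeneModel, domain TSV path) for the default fixture."""
    return load_toy_gene(default_spec)


@pytest.fixture(scope="session")
def toy_tx(toy):
    return toy[0].transcripts[0]


def small_spec(seed, **kw):
    """A fast-to-generate gene for randomized sweeps."""
    kw.setdefault("n_domains", 4)
    kw.setdefault("domain_aa", 24)
    kw.setdefault("flank_intron_nt", 40)
    return FixtureSpec(seed=seed, **kw)
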