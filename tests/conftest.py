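import pytest

from clrlipid import (
    AcylProfile,
    get_class,
    parse_chain,
    default_chain_pool,
    registry_from_tables,
    load_synonyms,
)


@pytest.fixture(scope="session")
def chain_pool():
    """Default 26-chain simulation pool."""
    return default_chain_pool()


@pytest.fixture(scope="session")
def registry():
    """Multi-platform compound registry built from the packaged tables."""
    return registry_from_tables()


@pytest.fixture(scope="session")
def synonyms():
    return load_synonyms()


@pytest.fixture
def toy_profile():
    """Two-chain diacyl profile with a 10/90 split at 100 uM."""
    a, b = parse_chain("C16:0"), parse_chain("C18:0")
    return AcylProfile(get_class("PC"), {a: 0.1, b: 0.9}, 100.0)


def random_profile(rng, class_spec, chains, zero_fraction=0.0):
    """Random normalized acyl profile over a subset of ``chains``."""
    weights = rng.dirichlet([1.0] * len(chains))
    if zero_fraction:
        mask = rng.random(len(chains)) < zero_fraction
        if mask.all():
            mask[rng.integers(len(chains))] = False
        weights = weights * ~mask
        weights = weights / weights.sum()
    total = float(rng.uniform(1.0, 1000.0))
    entries = {c: float(w) for c, w in zip(chains, weights)}
    return AcylProfile(class_spec, entries, total)
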