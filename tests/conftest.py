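import pytest

from crossring import load_barrier_table, parse_glycan


@pytest.fixture(scope="session")
def barrier_table():
    return load_barrier_table()


@pytest.fixture(scope="session")
def man12_labeled():
    return parse_glycan("Manb1-2Manb-18O1")


@pytest.fixture(scope="session")
def mannobiose_candidates():
    return [parse_glycan(f"Manb1-{p}Manb") for p in (2, 3, 4, 6)]
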