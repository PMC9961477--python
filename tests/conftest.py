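import pytest

import peptaibolkit as pk


@pytest.fixture(scope="session")
def alphabet():
    return pk.Alphabet.default()


@pytest.fixture(scope="session")
def table():
    return pk.endophytin_table()


def by_name(table, short):
    """Fixture row by short name, e.g. 'A2'."""
    return next(r for r in table if r.name == f"Endophytin {short}")


@pytest.fixture(scope="session")
def rec_a2(table):
    return by_name(table, "A2")


@pytest.fixture(scope="session")
def rec_b1(table):
    return by_name(table, "B1")


@pytest.fixture(scope="session")
def cset15():
    return pk.builtin_constraints("endophytin_15mod")


@pytest.fixture(scope="session")
def cset14():
    return pk.builtin_constraints("harzianin_14mod")


@pytest.fixture()
def noiseless_a2(rec_a2):
    return pk.generate_spectrum(rec_a2.sequence)
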