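import pytest

from tboxkit.fixtures import FixtureSpec, make_corpus, make_host_trnas, make_tbox
from tboxkit.pipeline import scan


@pytest.fixture(scope="session")
def corpus20():
    """The small reference corpus used throughout the suite."""
    return make_corpus(20, 7)


@pytest.fixture(scope="session")
def report20(corpus20):
    return scan(corpus20.records, corpus20.hits, corpus20.trnas)


@pytest.fixture(scope="session")
def trp_fixture():
    """A single class I Trp leader with full evidence."""
    spec = FixtureSpec(seed=42, specifier="UGG", uggn_n="A")
    record, hit, truth = make_tbox(spec)
    return spec, record, hit, truth


@pytest.fixture(scope="session")
def class2_fixture():
    spec = FixtureSpec(
        seed=43, tbox_class="II", specifier="AUC",
        with_terminator=False, with_polyU=False,
    )
    record, hit, truth = make_tbox(spec)
    return spec, record, hit, truth
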