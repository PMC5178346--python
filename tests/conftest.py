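import pathlib

import pytest

from envotag import fixtures, parse_obo, tagger
from envotag.metadata_store import build_store, open_store


@pytest.fixture(scope="session")
def mini_obo(tmp_path_factory) -> pathlib.Path:
    return fixtures.make_mini_ontology(
        tmp_path_factory.mktemp("obo") / "mini.obo"
    )


@pytest.fixture(scope="session")
def diamond_obo(tmp_path_factory) -> pathlib.Path:
    return fixtures.make_mini_ontology(
        tmp_path_factory.mktemp("obo") / "diamond.obo", diamond=True
    )


@pytest.fixture(scope="session")
def mini_graph(mini_obo):
    return parse_obo(mini_obo)


@pytest.fixture(scope="session")
def diamond_graph(diamond_obo):
    return parse_obo(diamond_obo)


@pytest.fixture(scope="session")
def mini_lexicon(mini_graph):
    return tagger.build_lexicon(mini_graph)


@pytest.fixture(scope="session")
def toy(tmp_path_factory):
    """Toy dataset (seed 1, 10 sequences x 3 samples) plus its SQLite store."""
    out = tmp_path_factory.mktemp("toy")
    ds = fixtures.make_toy_dataset(n_seqs=10, n_samples=3, seed=1, out_dir=out)
    store = open_store(build_store(ds.store_tsv, out / "store.sqlite"))
    return ds, store
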