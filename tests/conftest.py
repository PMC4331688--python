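import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=60, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_corpus():
    """A 20-document synthetic corpus shared by read-only tests."""
    from chemner.synthetic import GeneratorConfig, gen_corpus

    return gen_corpus(GeneratorConfig(n_docs=20, seed=11))


@pytest.fixture
def abstracts_file(tmp_path, small_corpus):
    from chemner.corpus import write_abstracts

    path = tmp_path / "abstracts.tsv"
    write_abstracts(small_corpus.documents, path)
    return path


@pytest.fixture
def gold_file(tmp_path, small_corpus):
    from chemner.corpus import write_annotations

    path = tmp_path / "gold.tsv"
    write_annotations(small_corpus.gold, path)
    return path
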