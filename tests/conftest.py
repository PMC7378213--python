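import pytest

from varpanel.corpus_io import parse_document
from varpanel.synthetic_data import CorpusConfig, generate_corpus


def make_doc(body: str, title: str = "", abstract: str = "", doc_id: str = "doc1"):
    return parse_document(
        {"doc_id": doc_id, "title": title, "abstract": abstract, "body": body}
    )


@pytest.fixture(scope="session")
def small_corpus():
    """Mixed corpus with default planting (distractors, mixed distances)."""
    config = CorpusConfig(n_variant_docs=30, n_background_docs=30)
    return config, *generate_corpus(config, seed=11)


@pytest.fixture(scope="session")
def unambiguous_corpus():
    """Corpus where every gold pair is co-sentential with no distractors."""
    config = CorpusConfig(
        n_variant_docs=25,
        n_background_docs=5,
        distance_distribution=(1.0, 0.0, 0.0),
        n_distractor_diseases=0,
    )
    return config, *generate_corpus(config, seed=23)
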