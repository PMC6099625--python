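import pytest

from textmill import engine
from textmill.corpus import Corpus, CorpusFile


@pytest.fixture
def five_file_corpus() -> Corpus:
    """The canonical worked example: files of cost 7, 5, 4, 3, 2."""
    return Corpus(
        tuple(
            CorpusFile(file_id=f"f{i}", size_chars=s)
            for i, s in enumerate([7, 5, 4, 3, 2])
        )
    )


SAMPLE_PUBTATOR = (
    "26094|t|BRAF V600E in melanoma.\n"
    "26094|a|We report the V600E mutation.\n"
    "26094\t5\t10\tV600E\tMutation\n"
    "\n"
    "31415|t|TP53 and breast cancer risk.\n"
    "31415|a|A cohort study of TP53 carriers.\n"
    "\n"
    "27182|t|Benchmarks only.\n"
)


@pytest.fixture
def sample_pubtator_text() -> str:
    return SAMPLE_PUBTATOR


@pytest.fixture
def demo_registry():
    """Fresh plugin registry holding only the bundled demo annotators."""
    engine.clear_registry()
    engine.register_demo_plugins()
    yield engine
    engine.clear_registry()


@pytest.fixture
def annotated_corpus_dir(tmp_path):
    """A small materialized synthetic corpus with entity mentions."""
    from textmill.corpus import generate_corpus, materialize_corpus

    corpus = generate_corpus(8, "uniform", {"low": 300, "high": 1500}, seed=11)
    paths = materialize_corpus(corpus, tmp_path / "corpus", seed=11)
    return [str(p) for p in paths]
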