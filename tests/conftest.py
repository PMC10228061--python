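import pytest

from ddial.corpus_io import Corpus, Document
from ddial.synthetic_corpus import (
    GeneratorConfig,
    make_two_pool_corpus,
    split_corpus,
)


def make_doc(doc_id, tokens, pool="screened", label="unlabeled", source="none"):
    return Document(
        doc_id=doc_id,
        title=" ".join(tokens[:3]),
        abstract=" ".join(tokens[3:]),
        tokens=tuple(tokens),
        pool=pool,
        label=label,
        label_source=source,
    )


@pytest.fixture(scope="session")
def tiny_cfg():
    """Small two-pool configuration for fast loop tests."""
    return GeneratorConfig(
        vocab_size=400,
        doc_length_mean=40.0,
        n_screened=500,
        n_unscreened=1500,
        n_labeled_pos=160,
        n_labeled_neg=180,
        prevalence_unscreened=0.005,
        seed=11,
    )


@pytest.fixture(scope="session")
def tiny_world(tiny_cfg):
    """(labeled stock, screened pool, unscreened pool, truth) at test scale."""
    corpus, truth = make_two_pool_corpus(tiny_cfg)
    labeled, screened, unscreened = split_corpus(corpus)
    return labeled, screened, unscreened, truth


@pytest.fixture
def small_corpus():
    """Four hand-built tokenized documents."""
    return Corpus(
        [
            make_doc("d1", ["loratadine", "simvastatin", "myopathy", "risk"]),
            make_doc("d2", ["simvastatin", "statin", "muscle", "pain"]),
            make_doc("d3", ["aspirin", "headache", "relief", "trial"]),
            make_doc("d4", ["loratadine", "allergy", "rhinitis", "trial"]),
        ]
    )
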