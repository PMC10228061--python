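"""Term-document statistics used by the samplers and the linear backend.

The similarity machinery follows the key-term construction used for
similarity sampling: per document, TF(t) = count(t)/len(doc),
IDF(t) = ln(n_docs/df(t)) over a reference collection, TFIDF = TF x IDF;
each abstract is summarised by its 30 highest-TFIDF key terms and their
within-document frequency vector, and two abstracts are compared with
cosine similarity |A.B|/(|A||B|) over the union of their key terms.

The linear max-margin backend consumes a term-document count matrix whose
columns are restricted to terms whose across-document relative-frequency
standard deviation exceeds 0.03 — low-SD terms carry no class signal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import scipy.sparse as sp
from scipy.io import mmwrite

from .corpus_io import Corpus, Document


@dataclass
class TermIndex:
    """Document frequencies and ln-IDF over a reference collection."""

    n_docs: int
    df: dict[str, int]

    def idf(self, term: str) -> float:
        # Out-of-index terms are treated as df=1 (maximal idf): unscreened
        # abstracts routinely contain vocabulary unseen in the corpus.
        return math.log(self.n_docs / self.df.get(term, 1))


@dataclass
class KeyTermVector:
    """Top-k TFIDF terms of one document with their relative frequencies."""

    doc_id: str
    key_terms: tuple[str, ...]
    freq: dict[str, float]


@dataclass
class TermDocumentMatrix:
    terms: list[str]
    docs: list[str]
    counts: sp.csr_matrix  # term x doc, non-negative integers
    doc_lengths: np.ndarray

    def export(self, prefix: str | Path) -> None:
        """Write MatrixMarket counts plus terms/docs sidecar text files."""
        prefix = Path(prefix)
        mmwrite(str(prefix.with_suffix(".mtx")), self.counts)
        prefix.with_name(prefix.name + ".terms.txt").write_text(
            "\n".join(self.terms) + "\n"
        )
        prefix.with_name(prefix.name + ".docs.txt").write_text(
            "\n".join(self.docs) + "\n"
        )


def term_frequency(term: str, doc: Document) -> float:
    """Within-document relative frequency, count(t)/len(tokens)."""
    if not doc.tokens:
        raise ValueError(f"document {doc.doc_id!r} has no tokens")
    return doc.tokens.count(term) / len(doc.tokens)


def build_term_index(ref_corpus: Corpus | Iterable[Document]) -> TermIndex:
    """Document frequencies over a tokenized reference collection."""
    docs = list(ref_corpus)
    if not docs:
        raise ValueError("empty reference corpus")
    df: dict[str, int] = {}
    for d in docs:
        for t in set(d.tokens):
            df[t] = df.get(t, 0) + 1
    return TermIndex(n_docs=len(docs), df=df)


def tfidf(term: str, doc: Document, index: TermIndex) -> float:
    return term_frequency(term, doc) * index.idf(term)


def key_term_vector(doc: Document, index: TermIndex, k: int = 30) -> KeyTermVector:
    """The (up to) k terms of highest TFIDF, ties broken lexicographically.

    Coordinates of the returned vector are within-document relative
    frequencies of the selected key terms.
    """
    if not doc.tokens:
        return KeyTermVector(doc.doc_id, (), {})
    n = len(doc.tokens)
    counts: dict[str, int] = {}
    for t in doc.tokens:
        counts[t] = counts.get(t, 0) + 1
    scored = sorted(
        counts, key=lambda t: (-(counts[t] / n) * index.idf(t), t)
    )
    selected = tuple(scored[:k])
    return KeyTermVector(
        doc.doc_id, selected, {t: counts[t] / n for t in selected}
    )


def cosine_similarity(a: KeyTermVector, b: KeyTermVector) -> float:
    """|A.B|/(|A||B|) over the union of key terms; missing terms are 0."""
    terms = set(a.key_terms) | set(b.key_terms)
    if not terms:
        raise ValueError("both key-term vectors are empty")
    va = np.array([a.freq.get(t, 0.0) for t in terms])
    vb = np.array([b.freq.get(t, 0.0) for t in terms])
    na, nb = np.linalg.norm(va), np.linalg.norm(vb)
    if na == 0 or nb == 0:
        raise ValueError("zero-norm key-term vector")
    return float(abs(va @ vb) / (na * nb))


def similarity_to_corpus(
    doc: Document | KeyTermVector,
    positives: Sequence[KeyTermVector],
    aggregate: str = "mean",
    index: TermIndex | None = None,
    k: int = 30,
) -> float:
    """Aggregate cosine similarity of one document to the positive corpus.

    ``positives`` are the key-term vectors of the labelled DDI-relevant
    abstracts; the higher the value, the more likely the document is
    DDI-relevant.
    """
    if not positives:
        raise ValueError("no positive key-term vectors supplied")
    if isinstance(doc, Document):
        if index is None:
            raise ValueError("a TermIndex is required to vectorise a Document")
        doc = key_term_vector(doc, index, k=k)
    sims = [cosine_similarity(doc, p) for p in positives]
    if aggregate == "mean":
        return float(np.mean(sims))
    if aggregate == "max":
        return float(np.max(sims))
    raise ValueError(f"unknown aggregate {aggregate!r}")


def build_tdm(
    corpus: Corpus | Iterable[Document], vocabulary: Sequence[str] | None = None
) -> TermDocumentMatrix:
    """Term x document count matrix over a tokenized collection."""
    docs = list(corpus)
    if vocabulary is None:
        vocab: dict[str, int] = {}
        for d in docs:
            for t in d.tokens:
                if t not in vocab:
                    vocab[t] = len(vocab)
    else:
        vocab = {t: i for i, t in enumerate(vocabulary)}
    rows, cols, vals = [], [], []
    lengths = np.zeros(len(docs), dtype=int)
    for j, d in enumerate(docs):
        lengths[j] = len(d.tokens)
        for t, c in d.token_counts().items():
            i = vocab.get(t)
            if i is not None:
                rows.append(i)
                cols.append(j)
                vals.append(c)
    counts = sp.csr_matrix(
        (vals, (rows, cols)), shape=(len(vocab), len(docs)), dtype=np.int64
    )
    return TermDocumentMatrix(
        terms=list(vocab), docs=[d.doc_id for d in docs], counts=counts,
        doc_lengths=lengths,
    )


def sd_feature_filter(tdm: TermDocumentMatrix, threshold: float = 0.03) -> list[str]:
    """Terms whose across-document relative-frequency SD strictly exceeds
    ``threshold``.

    SD is the population standard deviation of count/doc_length across
    documents (documents where the term is absent contribute frequency 0).
    """
    if len(tdm.docs) < 2:
        raise ValueError("SD filter needs at least 2 documents")
    lengths = np.maximum(tdm.doc_lengths, 1).astype(float)
    freq = tdm.counts.multiply(1.0 / lengths[None, :]).tocsr()
    n = freq.shape[1]
    mean = np.asarray(freq.mean(axis=1)).ravel()
    mean_sq = np.asarray(freq.multiply(freq).mean(axis=1)).ravel()
    var = np.maximum(mean_sq - mean**2, 0.0)
    sd = np.sqrt(var)
    return [t for t, s in zip(tdm.terms, sd) if s > threshold]


def export_key_terms(vectors: Sequence[KeyTermVector], index: TermIndex,
                     path: str | Path) -> None:
    """Headered CSV (doc_id,term,tfidf,freq,rank) for a set of key-term vectors."""
    import csv

    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["doc_id", "term", "tfidf", "freq", "rank"])
        for v in vectors:
            for rank, t in enumerate(v.key_terms, 1):
                w.writerow([v.doc_id, t, v.freq[t] * index.idf(t), v.freq[t], rank])
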