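"""Reading, normalising and tokenising abstract collections.

A :class:`Document` is one abstract (title + body) tagged with the pool it
came from — *screened* (matched the drug-interaction keyword queries) or
*unscreened* (everything else) — together with its label state.  Labels
carry provenance: a human-reviewed label versus an *assumed negative*, i.e.
a random draw from the unscreened pool pseudo-labelled negative without
review.

Two on-disk dialects are supported: a plain-text directory layout (one
abstract per ``.txt`` file, first line title, remainder body) and the
MEDLINE tagged format (``PMID-``, ``TI  -``, ``AB  -`` fields), parsed with
:mod:`Bio.Medline`.
"""

from __future__ import annotations

import csv
import hashlib
import logging
import string
from dataclasses import dataclass, field, replace
from collections import Counter
from pathlib import Path
from typing import Iterable, Iterator, Sequence

from Bio import Medline

logger = logging.getLogger(__name__)

POOLS = ("screened", "unscreened")
LABELS = ("positive", "negative", "unlabeled")
LABEL_SOURCES = ("human", "assumed_negative", "none")

_STOPWORDS_PATH = Path(__file__).parent / "data" / "stopwords.txt"


def default_stoplist() -> frozenset[str]:
    """The fixed English stop-list shipped with the package."""
    words = []
    for line in _STOPWORDS_PATH.read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            words.append(line)
    return frozenset(words)


def stoplist_hash() -> str:
    """SHA-256 of the shipped stop-list file, for run-log reproducibility."""
    return hashlib.sha256(_STOPWORDS_PATH.read_bytes()).hexdigest()


@dataclass
class Document:
    """One abstract with identity, text, tokens, pool tag and label state."""

    doc_id: str
    title: str = ""
    abstract: str = ""
    tokens: tuple[str, ...] = ()
    pool: str = "screened"
    label: str = "unlabeled"
    label_source: str = "none"

    def __post_init__(self) -> None:
        if self.pool not in POOLS:
            raise ValueError(f"unknown pool {self.pool!r}")
        if self.label not in LABELS:
            raise ValueError(f"unknown label {self.label!r}")
        if self.label_source not in LABEL_SOURCES:
            raise ValueError(f"unknown label_source {self.label_source!r}")
        if self.label_source == "assumed_negative" and self.label != "negative":
            raise ValueError("assumed_negative provenance implies a negative label")
        if self.label == "unlabeled" and self.label_source != "none":
            raise ValueError("an unlabeled document cannot have a label source")

    @property
    def text(self) -> str:
        return f"{self.title} {self.abstract}".strip()

    def token_counts(self) -> Counter:
        return Counter(self.tokens)


@dataclass
class Corpus:
    """A collection of documents with unique ids."""

    documents: list[Document] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [d.doc_id for d in self.documents]
        if len(ids) != len(set(ids)):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate doc_ids: {dupes[:5]}")

    def __len__(self) -> int:
        return len(self.documents)

    def __iter__(self) -> Iterator[Document]:
        return iter(self.documents)

    def __getitem__(self, doc_id: str) -> Document:
        for d in self.documents:
            if d.doc_id == doc_id:
                return d
        raise KeyError(doc_id)

    @property
    def pool_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for d in self.documents:
            counts[d.pool] = counts.get(d.pool, 0) + 1
        return counts

    @property
    def label_counts(self) -> dict[tuple[str, str], int]:
        counts: dict[tuple[str, str], int] = {}
        for d in self.documents:
            key = (d.pool, d.label)
            counts[key] = counts.get(key, 0) + 1
        return counts

    def subset(self, doc_ids: Iterable[str]) -> "Corpus":
        wanted = set(doc_ids)
        return Corpus([d for d in self.documents if d.doc_id in wanted])

    def with_label(self, label: str) -> "Corpus":
        return Corpus([d for d in self.documents if d.label == label])


def tokenize(doc: Document, stoplist: frozenset[str] | set[str] | None = None) -> Document:
    """Lowercase, whitespace-split, edge-punctuation-strip, de-stop a document.

    Title and abstract are concatenated before tokenisation; token-internal
    hyphens are kept (``co-administration`` stays one token).  Idempotent.
    """
    if stoplist is None:
        stoplist = default_stoplist()
    raw = f"{doc.title} {doc.abstract}".lower().split()
    tokens = []
    for tok in raw:
        tok = tok.strip(string.punctuation)
        if tok and tok not in stoplist:
            tokens.append(tok)
    return replace(doc, tokens=tuple(tokens))


def tokenize_corpus(corpus: Corpus, stoplist: frozenset[str] | None = None) -> Corpus:
    if stoplist is None:
        stoplist = default_stoplist()
    return Corpus([tokenize(d, stoplist) for d in corpus])


def read_plain_text_dir(path: str | Path, pool: str) -> Corpus:
    """Read a flat directory of one-abstract-per-file ``.txt`` documents.

    First line of each file is the title, the remainder the abstract.
    ``doc_id`` is the filename stem.  Unreadable files are skipped with a
    warning; an empty directory is an error.
    """
    path = Path(path)
    if not path.is_dir():
        raise FileNotFoundError(f"not a directory: {path}")
    docs = []
    for fp in sorted(path.glob("*.txt")):
        try:
            text = fp.read_text(encoding="utf-8")
        except OSError as exc:  # pragma: no cover - filesystem dependent
            logger.warning("skipping unreadable file %s: %s", fp, exc)
            continue
        lines = text.splitlines()
        title = lines[0].strip() if lines else ""
        abstract = " ".join(l.strip() for l in lines[1:] if l.strip())
        if not abstract and not title:
            logger.warning("empty document %s retained", fp.stem)
        docs.append(Document(doc_id=fp.stem, title=title, abstract=abstract, pool=pool))
    if not docs:
        raise ValueError(f"no .txt documents found under {path}")
    return Corpus(docs)


def read_medline(path: str | Path) -> Corpus:
    """Parse a MEDLINE tagged-format file into a screened-pool corpus.

    ``doc_id`` is the PMID; records without an AB field are skipped with a
    warning.  Parsing zero records is an error.
    """
    path = Path(path)
    docs = []
    with open(path, encoding="utf-8") as handle:
        for record in Medline.parse(handle):
            pmid = record.get("PMID")
            if pmid is None:
                logger.warning("skipping malformed MEDLINE record (no PMID)")
                continue
            abstract = record.get("AB")
            if abstract is None:
                logger.warning("skipping PMID %s: no abstract (AB) field", pmid)
                continue
            docs.append(
                Document(
                    doc_id=str(pmid),
                    title=record.get("TI", ""),
                    abstract=abstract,
                    pool="screened",
                )
            )
    if not docs:
        raise ValueError(f"no usable MEDLINE records in {path}")
    return Corpus(docs)


def write_corpus(corpus: Corpus, root: str | Path) -> None:
    """Persist a corpus to ``<root>/<pool>/<label>/<doc_id>.txt``."""
    root = Path(root)
    for d in corpus:
        dest = root / d.pool / d.label
        dest.mkdir(parents=True, exist_ok=True)
        (dest / f"{d.doc_id}.txt").write_text(
            f"{d.title}\n{d.abstract}\n", encoding="utf-8"
        )


def read_corpus(root: str | Path) -> Corpus:
    """Re-read the ``<root>/<pool>/<label>/`` layout written by write_corpus."""
    root = Path(root)
    docs: list[Document] = []
    for pool in POOLS:
        for label in LABELS:
            d = root / pool / label
            if not d.is_dir():
                continue
            source = "none"
            if label != "unlabeled":
                source = "human"
            sub = read_plain_text_dir(d, pool) if any(d.glob("*.txt")) else Corpus([])
            for doc in sub:
                docs.append(replace(doc, label=label, label_source=source))
    if not docs:
        raise ValueError(f"no documents under {root}")
    return Corpus(docs)


def write_label_sidecar(
    assignments: Sequence[tuple[str, str, str, int]], path: str | Path
) -> None:
    """Write label assignments as headered CSV (doc_id,label,label_source,round)."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["doc_id", "label", "label_source", "round"])
        w.writerows(assignments)


def read_label_sidecar(path: str | Path) -> list[tuple[str, str, str, int]]:
    with open(path, newline="") as fh:
        r = csv.DictReader(fh)
        return [
            (row["doc_id"], row["label"], row["label_source"], int(row["round"]))
            for row in r
        ]
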