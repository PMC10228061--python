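"""Synthetic two-pool abstract corpora with the screening problem's class structure.

Real screening corpora cannot be redistributed, so every pipeline stage is
exercised on generated bag-of-words corpora that reproduce the statistical
facts the active-learning design relies on:

* a *screened* pool (keyword-matched) with positive prevalence ~2.5% and an
  *unscreened* pool (everything else) with prevalence ~0.1%;
* pool-specific negative-class term distributions (the screened negatives
  are keyword-adjacent and differ from unscreened negatives by a
  ``pool_shift`` divergence knob);
* a labelled seed stock of 150 positives and 799 negatives, matching the
  corpus the loop is initialised from;
* a planted set of DDI-like key terms enriched in positives, so TF-IDF
  key-term similarity carries real signal.

Documents are multinomial bags of words: length ~ Poisson(doc_length_mean),
tokens drawn i.i.d. from the class/pool term distribution.  Class and pool
distributions are log-normal tilts of a shared Zipf base, scaled by
``topic_separation`` and ``pool_shift``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .corpus_io import Corpus, Document


@dataclass
class GeneratorConfig:
    """Knobs of the two-pool generator.

    Defaults mirror the reference screening conditions: pool sizes and
    labelled stock of the canonical corpus layout (150/799 labelled, 3,169 unlabeled screened, 9,999
    unscreened) and prevalences of 2.5% / 0.1%.
    """

    vocab_size: int = 2000
    doc_length_mean: float = 60.0
    n_screened: int = 3169
    n_unscreened: int = 9999
    n_labeled_pos: int = 150
    n_labeled_neg: int = 799
    prevalence_screened: float = 0.025
    prevalence_unscreened: float = 0.001
    topic_separation: float = 1.0
    pool_shift: float = 0.5
    n_planted_key_terms: int = 30
    key_term_mass: float = 0.3
    screened_negative_key_overlap: float = 0.35
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.prevalence_screened <= 1 and 0 <= self.prevalence_unscreened <= 1):
            raise ValueError("prevalences must lie in [0, 1]")
        if min(self.vocab_size, self.n_screened, self.n_unscreened) < 1:
            raise ValueError("counts must be >= 1")
        if self.topic_separation < 0 or self.pool_shift < 0:
            raise ValueError("divergence knobs must be >= 0")
        for n, prev in (
            (self.n_screened, self.prevalence_screened),
            (self.n_unscreened, self.prevalence_unscreened),
        ):
            if 0 < prev and n * prev < 1:
                warnings.warn(
                    "expected positives per pool < 1; a pool may contain none",
                    stacklevel=2,
                )


@dataclass
class SyntheticTruth:
    """Hidden truth backing the simulated oracle."""

    labels: dict[str, str]
    distribution: dict[str, str] = field(default_factory=dict)

    def __getitem__(self, doc_id: str) -> str:
        return self.labels[doc_id]


def _tilt(base: np.ndarray, scale: float, rng: np.random.Generator) -> np.ndarray:
    """Log-normal tilt of a distribution; scale 0 returns base unchanged."""
    if scale == 0:
        return base.copy()
    w = base * np.exp(scale * rng.standard_normal(base.size))
    return w / w.sum()


def _class_distributions(cfg: GeneratorConfig, rng: np.random.Generator):
    ranks = np.arange(1, cfg.vocab_size + 1)
    base = (1.0 / ranks) / (1.0 / ranks).sum()  # Zipf base

    # Positives mix the (tilted) background with a concentrated topic over
    # planted DDI-like key terms: frequent within positives (the way
    # "interaction"-type words dominate relevant abstracts, so they carry
    # frequency-SD signal) but drawn from mid-rank vocabulary so they stay
    # rare corpus-wide (high TFIDF in positives).
    if cfg.topic_separation > 0 and cfg.n_planted_key_terms > 0:
        key_ids = rng.choice(
            np.arange(cfg.vocab_size // 4, cfg.vocab_size),
            size=min(cfg.n_planted_key_terms, cfg.vocab_size - cfg.vocab_size // 4),
            replace=False,
        )
        key_dist = np.zeros(cfg.vocab_size)
        key_weights = 1.0 / np.arange(1, key_ids.size + 1)
        key_dist[key_ids] = key_weights / key_weights.sum()
        kappa = min(0.9, cfg.key_term_mass * cfg.topic_separation)
        positive = (1 - kappa) * _tilt(base, cfg.topic_separation, rng) \
            + kappa * key_dist
        # screened negatives matched the keyword query, so they carry the
        # key terms too, at a reduced rate — this is what makes the
        # screened pool a genuinely hard discrimination task
        kappa_neg = kappa * cfg.screened_negative_key_overlap
        neg_screened = (1 - kappa_neg) * _tilt(base, cfg.pool_shift, rng) \
            + kappa_neg * key_dist
    else:
        key_ids = np.array([], dtype=int)
        positive = base.copy()
        neg_screened = base.copy() if cfg.topic_separation == 0 \
            else _tilt(base, cfg.pool_shift, rng)
    neg_unscreened = base.copy()
    return positive, neg_screened, neg_unscreened, key_ids


def _make_doc(
    doc_id: str,
    dist: np.ndarray,
    vocab: np.ndarray,
    cfg: GeneratorConfig,
    rng: np.random.Generator,
    pool: str,
    label: str = "unlabeled",
    label_source: str = "none",
) -> Document:
    length = max(1, int(rng.poisson(cfg.doc_length_mean)))
    counts = rng.multinomial(length, dist)
    tokens = tuple(np.repeat(vocab, counts).tolist())
    title = " ".join(tokens[:5])
    abstract = " ".join(tokens[5:])
    return Document(
        doc_id=doc_id,
        title=title,
        abstract=abstract,
        tokens=tokens,
        pool=pool,
        label=label,
        label_source=label_source,
    )


def make_two_pool_corpus(cfg: GeneratorConfig) -> tuple[Corpus, SyntheticTruth]:
    """Generate the labelled stock plus the two unlabeled pools.

    Returns the full corpus (labelled stock carries visible labels; pool
    documents are unlabeled) and the hidden truth for every document.
    """
    rng = np.random.default_rng(cfg.seed)
    positive, neg_screened, neg_unscreened, key_ids = _class_distributions(cfg, rng)
    vocab = np.array([f"w{i:04d}" for i in range(cfg.vocab_size)])

    docs: list[Document] = []
    labels: dict[str, str] = {}
    dist_id: dict[str, str] = {}

    def add(doc_id, dist, name, pool, truth, label="unlabeled", source="none"):
        docs.append(_make_doc(doc_id, dist, vocab, cfg, rng, pool, label, source))
        labels[doc_id] = truth
        dist_id[doc_id] = name

    for i in range(cfg.n_labeled_pos):
        add(f"lab_pos_{i:04d}", positive, "positive", "screened",
            "positive", "positive", "human")
    for i in range(cfg.n_labeled_neg):
        add(f"lab_neg_{i:04d}", neg_screened, "neg_screened", "screened",
            "negative", "negative", "human")

    is_pos = rng.random(cfg.n_screened) < cfg.prevalence_screened
    for i in range(cfg.n_screened):
        if is_pos[i]:
            add(f"scr_{i:05d}", positive, "positive", "screened", "positive")
        else:
            add(f"scr_{i:05d}", neg_screened, "neg_screened", "screened", "negative")

    is_pos = rng.random(cfg.n_unscreened) < cfg.prevalence_unscreened
    for i in range(cfg.n_unscreened):
        if is_pos[i]:
            add(f"uns_{i:05d}", positive, "positive", "unscreened", "positive")
        else:
            add(f"uns_{i:05d}", neg_unscreened, "neg_unscreened", "unscreened",
                "negative")

    return Corpus(docs), SyntheticTruth(labels=labels, distribution=dist_id)


def split_corpus(corpus: Corpus) -> tuple[Corpus, Corpus, Corpus]:
    """(labelled stock, screened unlabeled pool, unscreened unlabeled pool)."""
    labeled = Corpus([d for d in corpus if d.label != "unlabeled"])
    screened = Corpus(
        [d for d in corpus if d.label == "unlabeled" and d.pool == "screened"]
    )
    unscreened = Corpus(
        [d for d in corpus if d.label == "unlabeled" and d.pool == "unscreened"]
    )
    return labeled, screened, unscreened


def make_benchmark_suite(
    seed: int = 0, n_corpora: int = 5, cfg: GeneratorConfig | None = None
) -> list[tuple[Corpus, SyntheticTruth]]:
    """A deterministic bundle of seeded two-pool corpora for end-to-end
    property checks; corpus i uses seed ``(seed * 101 + i) % 2**31``."""
    out = []
    for i in range(n_corpora):
        sub_seed = (seed * 101 + i) % (2**31)
        base = cfg or GeneratorConfig()
        from dataclasses import replace

        out.append(make_two_pool_corpus(replace(base, seed=sub_seed)))
    return out
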