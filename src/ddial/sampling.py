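"""The four sampling strategies and their composite schemes.

Five named schemes compose the strategies (Un = uncertainty, S = similarity,
R = random negatives, P = positive sampling):

========  ====================================================================
Un        top-``subset_budget`` most uncertain documents, all reviewed.
UnS       the uncertainty subset, narrowed to the ``similarity_top_k`` most
          similar to the labelled positives before review.
UnR       Un plus pseudo-labelled random negatives added straight to
          training without review.
UnRP      UnR with the uncertainty subset split between least-confident and
          most-confidently-positive candidates.
UnRPS     UnRP narrowed by the similarity filter before review.
========  ====================================================================

Uncertainty can be measured by least confidence, margin, or entropy; for a
binary classifier all three rank documents identically (each is a monotone
function of |p - 0.5|), so the variants matter for interface parity rather
than behaviour.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .corpus_io import Corpus, Document
from .features import KeyTermVector, TermIndex, similarity_to_corpus

SCHEMES = ("Un", "UnS", "UnR", "UnRP", "UnRPS")
UNCERTAINTY_RULES = ("least_confidence", "margin", "entropy")

#: schemes that operate on the unscreened pool (use random negatives)
UNSCREENED_SCHEMES = ("UnR", "UnRP", "UnRPS")
SCREENED_SCHEMES = ("Un", "UnS")


@dataclass
class ScoredPool:
    """Unlabeled documents with model probabilities (and similarity scores)."""

    docs: dict[str, Document]
    p: dict[str, float]
    similarity: dict[str, float] = field(default_factory=dict)
    pool: str = "screened"

    def __post_init__(self) -> None:
        for d in self.docs.values():
            if d.label != "unlabeled" and d.label_source != "assumed_negative":
                raise ValueError(
                    f"doc {d.doc_id} is human-labelled; it cannot enter a scored pool"
                )

    def __len__(self) -> int:
        return len(self.docs)


@dataclass
class SchemeSpec:
    """Declarative description of a composite sampling scheme."""

    name: str = "Un"
    uncertainty_rule: str = "least_confidence"
    subset_budget: int = 100
    similarity_top_k: int = 20
    positive_fraction: float = 0.5  # share of the subset given to positive picks
    random_negative_n: int = 100
    randomized_low_confidence: bool = False

    def __post_init__(self) -> None:
        if self.name not in SCHEMES:
            raise ValueError(f"unknown scheme {self.name!r}")
        if self.uncertainty_rule not in UNCERTAINTY_RULES:
            raise ValueError(f"unknown uncertainty rule {self.uncertainty_rule!r}")
        if not 0 < self.positive_fraction <= 1:
            raise ValueError("positive_fraction must lie in (0, 1]")

    @property
    def uses_similarity(self) -> bool:
        return self.name in ("UnS", "UnRPS")

    @property
    def uses_positive(self) -> bool:
        return self.name in ("UnRP", "UnRPS")

    @property
    def uses_random_negatives(self) -> bool:
        return self.name in UNSCREENED_SCHEMES


def uncertainty_scores(pool: ScoredPool, rule: str = "least_confidence") -> dict[str, float]:
    """Per-document uncertainty in [0, 1]; higher = less confident.

    least_confidence: 1 - |2p - 1|; margin: 1 - |p - (1-p)| (identical in the
    binary case); entropy: -p ln p - (1-p) ln(1-p), normalised by ln 2.
    """
    out = {}
    for doc_id in pool.docs:
        if doc_id not in pool.p:
            raise ValueError(f"no probability for doc {doc_id}")
        p = pool.p[doc_id]
        if rule == "least_confidence":
            u = 1.0 - abs(2 * p - 1)
        elif rule == "margin":
            u = 1.0 - abs(p - (1 - p))
        elif rule == "entropy":
            if p in (0.0, 1.0):
                u = 0.0
            else:
                u = (-p * math.log(p) - (1 - p) * math.log(1 - p)) / math.log(2)
        else:
            raise ValueError(f"unknown uncertainty rule {rule!r}")
        out[doc_id] = u
    return out


def _seeded_top(ids: Sequence[str], score: dict[str, float], n: int, seed: int) -> list[str]:
    """Top-n ids by descending score; ties broken by a seeded uniform draw
    applied after lexicographic ordering (deterministic per seed)."""
    ids = sorted(ids)
    rng = np.random.default_rng(seed)
    jitter = {i: rng.random() for i in ids}
    return sorted(ids, key=lambda i: (-score[i], jitter[i]))[:n]


def uncertainty_sample(
    pool: ScoredPool,
    rule: str = "least_confidence",
    n: int = 100,
    seed: int = 0,
    randomized_band: bool = False,
) -> list[str]:
    """The n most uncertain documents (ties seeded).

    With ``randomized_band`` the subset is instead a seeded uniform draw of
    n documents from the low-confidence band (the 2n most uncertain) — a
    "random subset among the low-confidence samples" reading of the
    protocol rather than a strict top-n.
    """
    if not pool.docs:
        raise ValueError("empty pool")
    u = uncertainty_scores(pool, rule)
    n = min(n, len(pool.docs))
    if not randomized_band:
        return _seeded_top(list(pool.docs), u, n, seed)
    band = _seeded_top(list(pool.docs), u, min(2 * n, len(pool.docs)), seed)
    rng = np.random.default_rng(seed + 17)
    picks = rng.choice(len(band), size=n, replace=False)
    return [band[i] for i in sorted(picks)]


def positive_sample(pool: ScoredPool, alpha: float, seed: int = 0) -> list[str]:
    """The ceil(alpha * |pool|) documents with highest positive probability."""
    if not pool.docs:
        raise ValueError("empty pool")
    if not 0 < alpha <= 1:
        raise ValueError("alpha must lie in (0, 1]")
    n = math.ceil(alpha * len(pool.docs))
    return _seeded_top(list(pool.docs), pool.p, n, seed)


def positive_sample_top_n(pool: ScoredPool, n: int, seed: int = 0) -> list[str]:
    """Fixed-count variant of positive sampling used inside composite schemes."""
    if not pool.docs:
        raise ValueError("empty pool")
    return _seeded_top(list(pool.docs), pool.p, min(n, len(pool.docs)), seed)


def random_negative_sample(unscreened_pool: Corpus, n: int, seed: int = 0) -> list[Document]:
    """Uniform draw (without replacement) pseudo-labelled negative.

    The draw tolerates a tiny fraction of hidden positives; those labels are
    calibrated later if the documents surface in a review batch.
    """
    candidates = sorted(
        (d for d in unscreened_pool if d.label == "unlabeled"), key=lambda d: d.doc_id
    )
    if n > len(candidates):
        raise ValueError(
            f"requested {n} random negatives but only {len(candidates)} unlabeled "
            "documents remain in the unscreened pool"
        )
    rng = np.random.default_rng(seed)
    picks = rng.choice(len(candidates), size=n, replace=False)
    from dataclasses import replace as _replace

    return [
        _replace(candidates[i], label="negative", label_source="assumed_negative")
        for i in sorted(picks)
    ]


def similarity_filter(
    candidates: Sequence[str],
    pool: ScoredPool,
    positives: Sequence[KeyTermVector],
    index: TermIndex,
    k: int = 20,
    seed: int = 0,
    aggregate: str = "mean",
) -> list[str]:
    """Keep the k candidates most similar to the labelled positive abstracts."""
    if not candidates:
        raise ValueError("no candidates to filter")
    if not positives:
        raise ValueError("no positive key-term vectors")
    sims = {}
    for doc_id in candidates:
        doc = pool.docs[doc_id]
        if not doc.tokens:
            sims[doc_id] = 0.0
        else:
            sims[doc_id] = similarity_to_corpus(
                doc, positives, aggregate=aggregate, index=index
            )
    pool.similarity.update(sims)
    return _seeded_top(list(candidates), sims, min(k, len(candidates)), seed)


@dataclass
class SchemeResult:
    """What a composition round produced: the batch to review, the components
    each reviewed doc came from, and any unreviewed pseudo-negatives."""

    review_batch: list[str]
    components: dict[str, str]
    random_negatives: list[Document] = field(default_factory=list)


def compose_scheme(
    spec: SchemeSpec,
    pool: ScoredPool,
    positives: Sequence[KeyTermVector],
    index: TermIndex | None = None,
    unscreened_corpus: Corpus | None = None,
    seed: int = 0,
    draw_random_negatives: bool = False,
) -> SchemeResult:
    """Run one composite sampling round and return the review batch.

    Random negatives are drawn only when ``draw_random_negatives`` is set
    (initialisation handles the canonical 100-draw; per-round redraws are a
    config choice of the caller).
    """
    if spec.name in UNSCREENED_SCHEMES and pool.pool != "unscreened":
        raise ValueError(f"scheme {spec.name} requires the unscreened pool")
    if spec.name in SCREENED_SCHEMES and pool.pool != "screened":
        raise ValueError(f"scheme {spec.name} requires the screened pool")

    components: dict[str, str] = {}
    if spec.uses_positive:
        n_pos = round(spec.subset_budget * spec.positive_fraction)
        n_unc = spec.subset_budget - n_pos
        unc = uncertainty_sample(
            pool, spec.uncertainty_rule, n_unc, seed,
            randomized_band=spec.randomized_low_confidence,
        )
        pos = positive_sample_top_n(pool, n_pos, seed + 1)
        subset = list(dict.fromkeys(unc + pos))
        for i in unc:
            components[i] = "uncertainty"
        for i in pos:
            components.setdefault(i, "positive")
    else:
        subset = uncertainty_sample(
            pool, spec.uncertainty_rule, spec.subset_budget, seed,
            randomized_band=spec.randomized_low_confidence,
        )
        for i in subset:
            components[i] = "uncertainty"

    if spec.uses_similarity:
        if index is None:
            raise ValueError("similarity filtering needs a TermIndex")
        batch = similarity_filter(
            subset, pool, positives, index, k=spec.similarity_top_k, seed=seed + 2
        )
        for i in batch:
            components[i] = components[i] + "+similarity"
    else:
        batch = subset

    negatives: list[Document] = []
    if spec.uses_random_negatives and draw_random_negatives:
        if unscreened_corpus is None:
            raise ValueError("random negative sampling needs the unscreened corpus")
        negatives = random_negative_sample(
            unscreened_corpus, spec.random_negative_n, seed + 3
        )

    return SchemeResult(
        review_batch=batch,
        components={i: components[i] for i in batch},
        random_negatives=negatives,
    )


def export_review_batch(
    result: SchemeResult, pool: ScoredPool, round_no: int, path
) -> None:
    """Review batch as headered CSV (round,doc_id,p,similarity,component,label)
    for human annotation; the label column is left blank for the annotator."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["round", "doc_id", "p", "similarity", "component", "label"])
        for doc_id in result.review_batch:
            w.writerow(
                [
                    round_no,
                    doc_id,
                    pool.p.get(doc_id, ""),
                    pool.similarity.get(doc_id, ""),
                    result.components.get(doc_id, ""),
                    "",
                ]
            )


def import_review_batch(path) -> dict[str, str]:
    """Read back an annotated review CSV as doc_id -> label."""
    out = {}
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            label = row["label"].strip().lower()
            if label not in ("positive", "negative"):
                raise ValueError(f"doc {row['doc_id']}: label {label!r} not filled in")
            out[row["doc_id"]] = label
    return out
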