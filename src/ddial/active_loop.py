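"""Pool-based active-learning protocols over the two abstract pools.

The unscreened protocol starts from 100 labelled positives plus 100
pseudo-labelled random negatives (training) and a 150-document external
validation set (50 labelled positives, 50 labelled negatives, 50 random
negatives); the screened protocol starts from 100/100 labelled documents
with the same validation layout.  Each of the four rounds re-fits the
classifier from scratch, scores the remaining pool, composes a review
batch under the chosen scheme, has the oracle label it, splits the newly
labelled documents equally between training and validation (odd remainder
to training), and records precision at recall >= 0.95 on the updated
validation set.

Pseudo-labelled (assumed-negative) training documents are re-scored each
round as calibration candidates: when one is drawn into a review batch its
label is corrected to the oracle's answer.  Human labels are never
overwritten.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import joblib
import numpy as np

from .corpus_io import Corpus, Document
from .eval_theory import RetrievalMetrics, precision_at_recall
from .features import build_term_index, key_term_vector
from .sampling import (
    SchemeSpec,
    ScoredPool,
    compose_scheme,
    random_negative_sample,
)
from . import classifiers as clf

logger = logging.getLogger(__name__)

N_ROUNDS_DEFAULT = 4


class SimulatedOracle:
    """Answers label queries from a hidden truth map, consistently."""

    mode = "simulated"

    def __init__(self, truth: dict[str, str]):
        self._truth = dict(truth)

    def label(self, doc_id: str) -> str:
        try:
            return self._truth[doc_id]
        except KeyError:
            raise KeyError(f"oracle has no truth for doc {doc_id}")


class InteractiveOracle:
    """Prompts a human annotator on stdin for each queried document."""

    mode = "interactive"

    def __init__(self, corpus: Corpus):
        self._corpus = corpus

    def label(self, doc_id: str) -> str:  # pragma: no cover - interactive
        doc = self._corpus[doc_id]
        print(f"\n--- {doc_id} ---\n{doc.title}\n\n{doc.abstract}\n")
        while True:
            ans = input("label [p]ositive / [n]egative: ").strip().lower()
            if ans in ("p", "positive"):
                return "positive"
            if ans in ("n", "negative"):
                return "negative"


@dataclass
class ALConfig:
    """Loop-level knobs (scheme-level knobs live on SchemeSpec)."""

    target_recall: float = 0.95
    redraw_random_negatives: bool = False  # beyond the initial 100
    similarity_aggregate: str = "mean"


@dataclass
class ALState:
    round: int
    train: Corpus
    validation: Corpus
    pools: dict[str, Corpus]
    scheme: SchemeSpec
    seed: int
    metrics_history: list[RetrievalMetrics] = field(default_factory=list)
    audit_log: list[tuple[int, str, str]] = field(default_factory=list)

    def log(self, action: str, detail: str) -> None:
        self.audit_log.append((self.round, action, detail))

    def check_disjoint(self) -> None:
        train_ids = {d.doc_id for d in self.train}
        val_ids = {d.doc_id for d in self.validation}
        assert not train_ids & val_ids, "train and validation overlap"
        for pool in self.pools.values():
            pids = {d.doc_id for d in pool}
            assert not pids & (train_ids | val_ids), "pool overlaps labelled sets"


def _draw(docs: list[Document], n: int, rng: np.random.Generator) -> tuple[list[Document], list[Document]]:
    """Seeded uniform draw of n docs (sorted by id first for determinism)."""
    docs = sorted(docs, key=lambda d: d.doc_id)
    if n > len(docs):
        raise ValueError(f"cannot draw {n} from {len(docs)} documents")
    picks = set(rng.choice(len(docs), size=n, replace=False).tolist())
    chosen = [d for i, d in enumerate(docs) if i in picks]
    rest = [d for i, d in enumerate(docs) if i not in picks]
    return chosen, rest


def init_unscreened(
    labeled: Corpus, unscreened: Corpus, seed: int, scheme: SchemeSpec | None = None
) -> ALState:
    """Initial split for the unscreened-pool protocol.

    Training: 100 random negatives from the unscreened pool + 100 labelled
    positives.  Validation: 50 labelled negatives, 50 labelled positives,
    50 random negatives.  Requires 150 labelled positives and 50 labelled
    negatives in stock.
    """
    scheme = scheme or SchemeSpec(name="UnRPS")
    rng = np.random.default_rng(seed)
    pos = [d for d in labeled if d.label == "positive"]
    neg = [d for d in labeled if d.label == "negative"]
    if len(pos) < 150:
        raise ValueError(f"need 150 labelled positives, have {len(pos)}")
    if len(neg) < 50:
        raise ValueError(f"need 50 labelled negatives, have {len(neg)}")

    train_pos, pos = _draw(pos, 100, rng)
    val_pos, pos = _draw(pos, 50, rng)
    val_neg, neg = _draw(neg, 50, rng)

    randoms = random_negative_sample(unscreened, 150, seed=seed)
    train_rand, val_rand = randoms[:100], randoms[100:]
    drawn_ids = {d.doc_id for d in randoms}
    remaining = Corpus([d for d in unscreened if d.doc_id not in drawn_ids])

    state = ALState(
        round=0,
        train=Corpus(train_pos + train_rand),
        validation=Corpus(val_pos + val_neg + val_rand),
        pools={"unscreened": remaining},
        scheme=scheme,
        seed=seed,
    )
    state.log("init", f"train={len(state.train)} validation={len(state.validation)}")
    state.check_disjoint()
    return state


def init_screened(
    labeled: Corpus,
    screened: Corpus,
    unscreened: Corpus,
    seed: int,
    scheme: SchemeSpec | None = None,
) -> ALState:
    """Initial split for the screened-pool protocol.

    Training: 100 labelled positives + 100 labelled negatives.  Validation:
    50 labelled positives, 50 labelled negatives, 50 random negatives drawn
    from the unscreened pool.
    """
    scheme = scheme or SchemeSpec(name="UnS")
    rng = np.random.default_rng(seed)
    pos = [d for d in labeled if d.label == "positive"]
    neg = [d for d in labeled if d.label == "negative"]
    if len(pos) < 150:
        raise ValueError(f"need 150 labelled positives, have {len(pos)}")
    if len(neg) < 150:
        raise ValueError(f"need 150 labelled negatives, have {len(neg)}")

    train_pos, pos = _draw(pos, 100, rng)
    train_neg, neg = _draw(neg, 100, rng)
    val_pos, pos = _draw(pos, 50, rng)
    val_neg, neg = _draw(neg, 50, rng)
    val_rand = random_negative_sample(unscreened, 50, seed=seed)
    drawn_ids = {d.doc_id for d in val_rand}

    state = ALState(
        round=0,
        train=Corpus(train_pos + train_neg),
        validation=Corpus(val_pos + val_neg + val_rand),
        pools={
            "screened": Corpus([d for d in screened if d.label == "unlabeled"]),
            "unscreened": Corpus(
                [d for d in unscreened if d.doc_id not in drawn_ids]
            ),
        },
        scheme=scheme,
        seed=seed,
    )
    state.log("init", f"train={len(state.train)} validation={len(state.validation)}")
    state.check_disjoint()
    return state


def _active_pool_name(scheme: SchemeSpec) -> str:
    return "unscreened" if scheme.uses_random_negatives else "screened"


def run_round(
    state: ALState, model, oracle, config: ALConfig | None = None
) -> ALState:
    """One AL iteration: fit, score, sample, review, redistribute, evaluate."""
    config = config or ALConfig()
    if state.round >= N_ROUNDS_DEFAULT:
        logger.warning("running beyond the canonical %d rounds", N_ROUNDS_DEFAULT)
    round_seed = state.seed * 1000 + state.round
    pool_name = _active_pool_name(state.scheme)
    pool_corpus = state.pools[pool_name]

    clf.fit(model, state.train)

    # review candidates: the remaining pool plus pseudo-labelled training
    # docs (the latter only so their labels can be calibrated)
    assumed = [d for d in state.train if d.label_source == "assumed_negative"]
    candidates = list(pool_corpus) + assumed
    scores = clf.predict_proba(model, candidates)
    scored = ScoredPool(
        docs={d.doc_id: d for d in candidates}, p=scores, pool=pool_name
    )

    train_positives = [d for d in state.train if d.label == "positive"]
    index = build_term_index(state.train)
    positive_vectors = [key_term_vector(d, index) for d in train_positives if d.tokens]

    result = compose_scheme(
        state.scheme,
        scored,
        positive_vectors,
        index=index,
        unscreened_corpus=state.pools.get("unscreened"),
        seed=round_seed,
        draw_random_negatives=(
            state.scheme.uses_random_negatives and config.redraw_random_negatives
        ),
    )

    assumed_ids = {d.doc_id for d in assumed}
    new_train: list[Document] = []
    calibrated: dict[str, str] = {}
    fresh: list[Document] = []
    for doc_id in result.review_batch:
        answer = oracle.label(doc_id)
        if doc_id in assumed_ids:
            calibrated[doc_id] = answer
            state.log("calibrate", f"{doc_id}:{answer}")
        else:
            fresh.append(
                replace(scored.docs[doc_id], label=answer, label_source="human")
            )
            state.log("review", f"{doc_id}:{answer}")

    # calibrated pseudo-negatives stay in training with corrected labels
    train_docs = []
    for d in state.train:
        if d.doc_id in calibrated:
            train_docs.append(
                replace(d, label=calibrated[d.doc_id], label_source="human")
            )
        else:
            train_docs.append(d)

    # newly labelled pool docs are split equally; odd remainder to training
    rng = np.random.default_rng(round_seed + 7)
    order = rng.permutation(len(fresh))
    n_train = (len(fresh) + 1) // 2
    to_train = [fresh[i] for i in order[:n_train]]
    to_val = [fresh[i] for i in order[n_train:]]

    reviewed_ids = {d.doc_id for d in fresh}
    drawn_negative_ids = {d.doc_id for d in result.random_negatives}
    removed = reviewed_ids | drawn_negative_ids

    new_pools = dict(state.pools)
    new_pools[pool_name] = Corpus(
        [d for d in pool_corpus if d.doc_id not in removed]
    )
    if pool_name != "unscreened" and drawn_negative_ids:
        new_pools["unscreened"] = Corpus(
            [d for d in new_pools["unscreened"] if d.doc_id not in drawn_negative_ids]
        )

    new_state = ALState(
        round=state.round + 1,
        train=Corpus(train_docs + to_train + result.random_negatives),
        validation=Corpus(list(state.validation) + to_val),
        pools=new_pools,
        scheme=state.scheme,
        seed=state.seed,
        metrics_history=list(state.metrics_history),
        audit_log=list(state.audit_log),
    )
    new_state.check_disjoint()

    val_docs = list(new_state.validation)
    val_scores = clf.predict_proba(model, val_docs)
    truth = {d.doc_id: d.label for d in val_docs}
    metrics = precision_at_recall(val_scores, truth, config.target_recall)
    new_state.metrics_history.append(metrics)
    new_state.log(
        "metrics",
        f"P={metrics.precision:.3f} R={metrics.recall:.3f} F1={metrics.f1:.3f}",
    )
    return new_state


def run(
    state: ALState,
    model,
    oracle,
    n_rounds: int = N_ROUNDS_DEFAULT,
    config: ALConfig | None = None,
) -> ALState:
    """Run ``n_rounds`` AL iterations (the canonical protocol uses four)."""
    if state.round != 0:
        raise ValueError("run() expects a fresh state (round 0)")
    for _ in range(n_rounds):
        state = run_round(state, model, oracle, config)
    return state


def save_checkpoint(state: ALState, path) -> None:
    joblib.dump(state, path)


def load_checkpoint(path) -> ALState:
    return joblib.load(path)


def mislabeled_fraction(state: ALState, truth: dict[str, str]) -> float:
    """Fraction of training documents whose working label disagrees with the
    hidden truth (pseudo-labelled positives counted as mislabels)."""
    wrong = sum(1 for d in state.train if d.label != truth[d.doc_id])
    return wrong / len(state.train)
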