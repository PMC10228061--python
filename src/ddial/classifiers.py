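"""Two interchangeable relevance-scoring backends.

Both are scikit-learn estimators that accept either :class:`Document`
objects or plain token sequences as samples and output the probability
that an abstract is DDI-relevant:

``LinearMarginTextClassifier``
    A linear max-margin model (LinearSVC) on term-count features restricted
    to terms whose relative-frequency SD across training documents exceeds
    0.03, with a Platt sigmoid fitted on the training decision values to
    turn margins into probabilities.

``FastTextLiteClassifier``
    A fastText-style network: words and character bigrams are hashed into
    an embedding table, embeddings are element-wise averaged over the
    document, and a sigmoid output unit phi(z) = 1/(1+e^-z) is trained by
    SGD on the logistic loss.

The module-level :func:`fit` / :func:`predict_proba` helpers run either
backend on a :class:`~ddial.corpus_io.Corpus` so the active-learning loop
is backend-agnostic.
"""

from __future__ import annotations

import warnings
import zlib
from typing import Iterable, Sequence

import joblib
import numpy as np
import scipy.sparse as sp
from scipy.optimize import minimize_scalar
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.svm import LinearSVC
from sklearn.utils.validation import check_is_fitted

from .corpus_io import Corpus, Document, stoplist_hash
from .features import build_tdm, sd_feature_filter

DEFAULT_SEED = 20230530

MODEL_FORMAT_VERSION = 1


def _as_token_lists(X: Iterable) -> list[tuple[str, ...]]:
    out = []
    for x in X:
        if isinstance(x, Document):
            out.append(tuple(x.tokens))
        else:
            out.append(tuple(x))
    return out


def _validate_binary(y) -> np.ndarray:
    y = np.asarray(y)
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("training set must contain both classes")
    if len(classes) > 2:
        raise ValueError("binary task: got more than two classes")
    return y


class _PlattSigmoid:
    """Platt scaling p = 1/(1+exp(A*f + B)) fitted on decision values."""

    def fit(self, f: np.ndarray, y01: np.ndarray) -> "_PlattSigmoid":
        n_pos, n_neg = int(y01.sum()), int((1 - y01).sum())
        # Platt's smoothed targets guard against overconfident separable fits
        t = np.where(y01 == 1, (n_pos + 1.0) / (n_pos + 2.0), 1.0 / (n_neg + 2.0))

        def nll(a: float) -> float:
            # B fixed by symmetry around the margin midpoint; optimise the
            # slope only, which keeps the map strictly decreasing in A*f and
            # guarantees rank preservation for A < 0.
            z = a * f + self._b
            p = 1.0 / (1.0 + np.exp(z))
            p = np.clip(p, 1e-12, 1 - 1e-12)
            return float(-(t * np.log(p) + (1 - t) * np.log(1 - p)).sum())

        self._b = 0.0
        res = minimize_scalar(nll, bounds=(-20.0, -1e-3), method="bounded")
        self.a_ = float(res.x)
        return self

    def transform(self, f: np.ndarray) -> np.ndarray:
        return 1.0 / (1.0 + np.exp(self.a_ * f + self._b))


class LinearMarginTextClassifier(BaseEstimator, ClassifierMixin):
    """Linear max-margin text classifier on SD-filtered term counts.

    Parameters
    ----------
    sd_threshold : float, default=0.03
        Relative-frequency SD cut-off for feature selection.
    C : float, default=1.0
        LinearSVC regularisation strength.
    random_state : int, default=20230530
    """

    backend = "linear_margin"

    def __init__(self, sd_threshold: float = 0.03, C: float = 1.0,
                 random_state: int = DEFAULT_SEED):
        self.sd_threshold = sd_threshold
        self.C = C
        self.random_state = random_state

    def _vectorize(self, token_lists: Sequence[tuple[str, ...]]) -> sp.csr_matrix:
        vocab = self.vocabulary_
        rows, cols, vals = [], [], []
        for i, toks in enumerate(token_lists):
            for t in toks:
                j = vocab.get(t)
                if j is not None:
                    rows.append(i)
                    cols.append(j)
                    vals.append(1)
        return sp.csr_matrix(
            (vals, (rows, cols)), shape=(len(token_lists), len(vocab)),
            dtype=np.float64,
        )

    def fit(self, X, y):
        token_lists = _as_token_lists(X)
        y = _validate_binary(y)
        self.classes_ = np.unique(y)
        y01 = (y == self.classes_[1]).astype(int)
        docs = [Document(doc_id=str(i), tokens=t) for i, t in enumerate(token_lists)]
        tdm = build_tdm(docs)
        selected = sd_feature_filter(tdm, self.sd_threshold)
        if not selected:
            raise ValueError(
                "no terms survive the SD filter; lower sd_threshold "
                f"(currently {self.sd_threshold})"
            )
        self.vocabulary_ = {t: i for i, t in enumerate(sorted(selected))}
        Xm = self._vectorize(token_lists)
        self.svm_ = LinearSVC(C=self.C, random_state=self.random_state)
        self.svm_.fit(Xm, y01)
        f = self.svm_.decision_function(Xm)
        self.platt_ = _PlattSigmoid().fit(f, y01)
        return self

    def decision_function(self, X) -> np.ndarray:
        check_is_fitted(self, "svm_")
        return self.svm_.decision_function(self._vectorize(_as_token_lists(X)))

    def predict_proba(self, X) -> np.ndarray:
        check_is_fitted(self, "svm_")
        token_lists = _as_token_lists(X)
        p = self.platt_.transform(
            self.svm_.decision_function(self._vectorize(token_lists))
        )
        empty = [i for i, t in enumerate(token_lists) if not t]
        if empty:
            warnings.warn(
                f"{len(empty)} empty-token document(s) scored at the 0.5 prior",
                stacklevel=2,
            )
            p[empty] = 0.5
        return np.column_stack([1 - p, p])

    def predict(self, X) -> np.ndarray:
        return self.classes_[(self.predict_proba(X)[:, 1] >= 0.5).astype(int)]


def _hash_units(tokens: Sequence[str], n_buckets: int, ngram_order: int) -> np.ndarray:
    """Hashed ids of word units plus order-n character sub-units."""
    ids = []
    for tok in tokens:
        ids.append(zlib.crc32(tok.encode("utf-8")) % n_buckets)
        if len(tok) >= ngram_order:
            for i in range(len(tok) - ngram_order + 1):
                sub = tok[i : i + ngram_order]
                ids.append(zlib.crc32(b"#" + sub.encode("utf-8")) % n_buckets)
    return np.asarray(ids, dtype=np.int64)


class FastTextLiteClassifier(BaseEstimator, ClassifierMixin):
    """Hashed n-gram averaged-embedding classifier with a sigmoid output.

    Each document is the bag of its word units and order-``ngram_order``
    character sub-units, hashed into ``hash_buckets`` embedding rows.  The
    document representation is the element-wise average of those
    embeddings; a single sigmoid unit on top is trained end-to-end by SGD
    with a linearly decaying learning rate.  Pooling by averaging makes the
    score invariant to token order.
    """

    backend = "fasttext_lite"

    def __init__(self, embed_dim: int = 32, ngram_order: int = 2,
                 hash_buckets: int = 1 << 16, epochs: int = 25,
                 learning_rate: float = 0.5, random_state: int = DEFAULT_SEED):
        self.embed_dim = embed_dim
        self.ngram_order = ngram_order
        self.hash_buckets = hash_buckets
        self.epochs = epochs
        self.learning_rate = learning_rate
        self.random_state = random_state

    def fit(self, X, y):
        if self.embed_dim < 1 or self.epochs < 1:
            raise ValueError("embed_dim and epochs must be >= 1")
        token_lists = _as_token_lists(X)
        y = _validate_binary(y)
        self.classes_ = np.unique(y)
        y01 = (y == self.classes_[1]).astype(float)
        units = [
            _hash_units(t, self.hash_buckets, self.ngram_order) for t in token_lists
        ]
        rng = np.random.default_rng(self.random_state)
        E = rng.uniform(-0.5, 0.5, size=(self.hash_buckets, self.embed_dim))
        E /= self.embed_dim
        w = np.zeros(self.embed_dim)
        b = 0.0
        n = len(units)
        total = self.epochs * n
        step = 0
        for _ in range(self.epochs):
            for i in rng.permutation(n):
                lr = self.learning_rate * (1.0 - step / total)
                step += 1
                ids = units[i]
                if ids.size == 0:
                    continue
                h = E[ids].mean(axis=0)
                z = w @ h + b
                p = 1.0 / (1.0 + np.exp(-z))
                g = p - y01[i]
                np.add.at(E, ids, (-lr * g / ids.size) * w)
                w -= lr * g * h
                b -= lr * g
        self.embeddings_ = E
        self.output_weights_ = w
        self.output_bias_ = b
        return self

    def decision_function(self, X) -> np.ndarray:
        check_is_fitted(self, "embeddings_")
        token_lists = _as_token_lists(X)
        z = np.zeros(len(token_lists))
        empty = []
        for i, toks in enumerate(token_lists):
            ids = _hash_units(toks, self.hash_buckets, self.ngram_order)
            if ids.size == 0:
                empty.append(i)
                continue
            h = self.embeddings_[ids].mean(axis=0)
            z[i] = self.output_weights_ @ h + self.output_bias_
        if empty:
            warnings.warn(
                f"{len(empty)} empty-token document(s) scored at the 0.5 prior",
                stacklevel=2,
            )
        return z

    def predict_proba(self, X) -> np.ndarray:
        z = self.decision_function(X)
        p = 1.0 / (1.0 + np.exp(-z))
        return np.column_stack([1 - p, p])

    def predict(self, X) -> np.ndarray:
        return self.classes_[(self.predict_proba(X)[:, 1] >= 0.5).astype(int)]


BACKENDS = {
    "linear_margin": LinearMarginTextClassifier,
    "linear": LinearMarginTextClassifier,
    "fasttext_lite": FastTextLiteClassifier,
    "fasttext": FastTextLiteClassifier,
}


def make_classifier(backend: str, **kwargs):
    try:
        cls = BACKENDS[backend]
    except KeyError:
        raise ValueError(f"unknown backend {backend!r}; choose from {sorted(BACKENDS)}")
    return cls(**kwargs)


def fit(model, train: Corpus):
    """Fit a backend on the labelled documents of a corpus (positive=1)."""
    docs = [d for d in train if d.label in ("positive", "negative")]
    if not docs:
        raise ValueError("corpus has no labelled documents")
    y = np.array([1 if d.label == "positive" else 0 for d in docs])
    return model.fit(docs, y)


def predict_proba(model, docs: Iterable[Document]) -> dict[str, float]:
    """Positive-class probability per doc_id; empty input gives an empty map."""
    docs = list(docs)
    if not docs:
        return {}
    p = model.predict_proba(docs)[:, 1]
    return {d.doc_id: float(pi) for d, pi in zip(docs, p)}


def save_model(model, path) -> None:
    """Persist a fitted backend as a single versioned archive."""
    joblib.dump(
        {
            "format_version": MODEL_FORMAT_VERSION,
            "backend": model.backend,
            "params": model.get_params(),
            "stoplist_sha256": stoplist_hash(),
            "model": model,
        },
        path,
    )


def load_model(path):
    payload = joblib.load(path)
    if payload.get("format_version") != MODEL_FORMAT_VERSION:
        raise ValueError("unsupported model archive version")
    return payload["model"]
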